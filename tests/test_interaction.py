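import numpy as np
import pandas as pd
import pytest

from heatptb.interaction import (
    bootstrap_reri,
    compute_reri,
    expand_strata,
    fit_interaction_model,
    reri_from_rrs,
    resample_date_blocks,
    _coef_series,
)
from heatptb.synthetic import MODIFIERS, generate_dataset, scenario_config
from heatptb.total_effects import ModelSpec
from tests.conftest import make_analysis

SPEC = ModelSpec(covariates=())


@pytest.fixture(scope="module")
def interaction_data():
    ds = generate_dataset(scenario_config("interaction", seed=3, n_years=3, beta0=2.0))
    analysis, _ = make_analysis(ds)
    strata = expand_strata(ds.births[ds.births["date"].isin(analysis.index)])
    return ds, analysis, strata


class TestExpand:
    def test_materializes_all_48_combinations(self):
        rows = []
        for combo, n in (((1, 0, 0, 0, 0, 0), 2), ((0, 0, 1, 1, 0, 0), 5)):
            rows.append(dict(zip(MODIFIERS, combo), date=pd.Timestamp("1995-06-01"), count=n))
        out = expand_strata(pd.DataFrame(rows))
        assert len(out) == 48
        assert (out["count"] == 0).sum() == 46
        assert out["count"].sum() == 7

    def test_per_birth_records_accepted(self):
        rows = [dict(zip(MODIFIERS, (0, 0, 0, 0, 1, 0)), date=pd.Timestamp("1995-06-01"))
                for _ in range(3)]
        out = expand_strata(pd.DataFrame(rows))
        smoker_row = out[(out["smoker"] == 1) & (out[[m for m in MODIFIERS if m != "smoker"]].sum(axis=1) == 0)]
        assert int(smoker_row["count"].iloc[0]) == 3

    def test_daily_totals_conserved(self, interaction_data):
        ds, analysis, strata = interaction_data
        got = strata.groupby("date")["count"].sum()
        want = ds.births[ds.births["date"].isin(analysis.index)].groupby("date")["count"].sum()
        pd.testing.assert_series_equal(got, want, check_names=False)

    def test_contradictory_age_raises(self):
        row = dict(zip(MODIFIERS, (0, 1, 1, 0, 0, 0)), date=pd.Timestamp("1995-06-01"))
        with pytest.raises(ValueError, match="mutually exclusive"):
            expand_strata(pd.DataFrame([row]))

    def test_smoker_share_tracks_prevalence(self):
        cfg = scenario_config("null", seed=41, n_years=3, beta0=3.0,
                              modifier_prevalences={
                                  "black": 0.5, "age16_19": 0.2, "age30plus": 0.25,
                                  "low_prenatal": 0.3, "smoker": 0.25, "no_hs": 0.4,
                              })
        ds = generate_dataset(cfg)
        strata = expand_strata(ds.births)
        total = strata["count"].sum()
        share = strata.loc[strata["smoker"] == 1, "count"].sum() / total
        sd = np.sqrt(0.25 * 0.75 / total)
        assert abs(share - 0.25) < 4 * sd


class TestFit:
    def test_no_modifier_effects_interactions_near_zero(self):
        ds = generate_dataset(scenario_config("no_mediation", seed=2, n_years=3))
        analysis, _ = make_analysis(ds)
        strata = expand_strata(ds.births[ds.births["date"].isin(analysis.index)])
        fit = fit_interaction_model(strata, analysis, SPEC, family="poisson")
        res = fit.result
        for m in MODIFIERS:
            name = f"em_{m}_x_at_hinge"
            assert abs(res.params[name]) < 3.5 * res.bse[name]

    def test_poisson_boundary_fallback_on_equidispersed_data(self, interaction_data):
        _, analysis, strata = interaction_data
        fit = fit_interaction_model(strata, analysis, SPEC)
        assert fit.family == "poisson" and fit.alpha == 0.0

    def test_nb_matches_poisson_when_dispersion_zero(self):
        ds = generate_dataset(scenario_config("interaction", seed=0, n_years=2, beta0=2.5))
        analysis, _ = make_analysis(ds)
        strata = expand_strata(ds.births[ds.births["date"].isin(analysis.index)])
        fp = fit_interaction_model(strata, analysis, SPEC, family="poisson")
        fn = fit_interaction_model(strata, analysis, SPEC, family="negative_binomial")
        assert fn.alpha < 0.01
        diff = np.max(np.abs(_coef_series(fn).to_numpy() - _coef_series(fp).to_numpy()))
        assert diff < 1e-3

    def test_overdispersed_data_selects_nb(self):
        ds = generate_dataset(
            scenario_config("interaction", seed=5, n_years=2, beta0=2.5, dispersion=0.5)
        )
        analysis, _ = make_analysis(ds)
        strata = expand_strata(ds.births[ds.births["date"].isin(analysis.index)])
        fit = fit_interaction_model(strata, analysis, SPEC)
        assert fit.family == "negative_binomial"
        assert fit.alpha > 0.1

    def test_targeted_interaction_detected(self):
        # power check, scaled down from the full design
        hits = 0
        for seed in range(8):
            cfg = scenario_config("null", seed=seed, n_years=3, beta0=2.5,
                                  beta_at=0.03, reri_targets={"smoker": 0.6})
            ds = generate_dataset(cfg)
            analysis, _ = make_analysis(ds)
            strata = expand_strata(ds.births[ds.births["date"].isin(analysis.index)])
            fit = fit_interaction_model(strata, analysis, SPEC, family="poisson")
            res = fit.result
            z = res.params["em_smoker_x_at_hinge"] / res.bse["em_smoker_x_at_hinge"]
            hits += abs(z) > 1.96
        assert hits >= 6


class TestReri:
    def test_all_unity_rrs(self):
        assert reri_from_rrs(1.0, 1.0, 1.0) == 0.0

    def test_worked_arithmetic(self):
        assert reri_from_rrs(2.0, 1.5, 1.2) == pytest.approx(0.3)

    def test_missing_modifier_raises(self, interaction_data):
        _, analysis, strata = interaction_data
        fit = fit_interaction_model(strata, analysis, SPEC, family="poisson")
        with pytest.raises(KeyError):
            compute_reri(fit, "left_handed", 25.0, 18.0)

    def test_sign_logic_matches_calibration(self):
        # risk-enhancing and protective modifiers recover their signs
        ds = generate_dataset(
            scenario_config("interaction", seed=1, n_years=3, beta0=2.5,
                            reri_targets={"smoker": 0.8, "black": -0.8},
                            modifier_log_rr={"smoker": 0.2, "black": 0.3})
        )
        analysis, _ = make_analysis(ds)
        strata = expand_strata(ds.births[ds.births["date"].isin(analysis.index)])
        fit = fit_interaction_model(strata, analysis, SPEC, family="poisson")
        p50, p95 = np.percentile(analysis["at2_c"], [50, 95])
        assert compute_reri(fit, "smoker", p95, p50).reri > 0
        assert compute_reri(fit, "black", p95, p50).reri < 0


def test_null_modifier_reri_mean_near_zero():
    # zero main effect, zero interaction, zero exposure effect: the RERI
    # estimator is centred on 0
    vals = []
    for seed in range(25):
        ds = generate_dataset(scenario_config("null", seed=seed, n_years=2, beta0=2.0))
        analysis, _ = make_analysis(ds)
        strata = expand_strata(ds.births[ds.births["date"].isin(analysis.index)])
        fit = fit_interaction_model(strata, analysis, SPEC, family="poisson")
        p50, p95 = np.percentile(analysis["at2_c"], [50, 95])
        vals.append(compute_reri(fit, "low_prenatal", p95, p50).reri)
    assert abs(np.mean(vals)) < 0.1


class TestBootstrap:
    def test_deterministic_and_brackets_point(self, interaction_data):
        _, analysis, strata = interaction_data
        a = bootstrap_reri(strata, analysis, SPEC, n_boot=30, seed=11,
                           modifiers=("smoker",))
        b = bootstrap_reri(strata, analysis, SPEC, n_boot=30, seed=11,
                           modifiers=("smoker",))
        assert a["smoker"].ci == b["smoker"].ci
        assert a["smoker"].n_boot == 30

    def test_recovery_within_ci(self, interaction_data):
        ds, analysis, strata = interaction_data
        res = bootstrap_reri(strata, analysis, SPEC, n_boot=120, seed=2,
                             modifiers=("smoker",))
        lo, hi = res["smoker"].ci
        assert lo <= ds.truth["true_reri_model_scale"]["smoker"] <= hi

    def test_date_blocks_move_together(self, interaction_data):
        _, _, strata = interaction_data
        srt = strata.sort_values("date", kind="stable").reset_index(drop=True)
        codes, dates = pd.factorize(srt["date"], sort=True)
        row_blocks = [np.flatnonzero(codes == i) for i in range(len(dates))]
        rng = np.random.default_rng(0)
        idx, pick = resample_date_blocks(row_blocks, rng)
        assert len(idx) == len(srt)
        # every sampled block carries its complete 48-stratum day
        resampled = srt.iloc[idx]
        per_day = np.array_split(np.arange(len(idx)), len(pick))
        for rows, block in zip(per_day, pick):
            chunk = resampled.iloc[rows]
            assert chunk["date"].nunique() == 1
            assert chunk["date"].iloc[0] == dates[block]
            assert chunk["count"].sum() == srt.iloc[row_blocks[block]]["count"].sum()

    def test_null_interaction_ci_covers_zero(self):
        # with no exposure effect (rr10 = 1) the model-scale RERI of an
        # untargeted modifier is exactly 0; with an exposure effect it is
        # (rr10-1)(rr01-1) because the expanded-strata design has no at-risk
        # denominator, so the null scenario is the correct zero reference
        covered = 0
        for seed in range(6):
            ds = generate_dataset(scenario_config("null", seed=seed, n_years=2, beta0=2.0))
            analysis, _ = make_analysis(ds)
            strata = expand_strata(ds.births[ds.births["date"].isin(analysis.index)])
            res = bootstrap_reri(strata, analysis, SPEC, n_boot=60, seed=seed,
                                 modifiers=("smoker",))
            lo, hi = res["smoker"].ci
            covered += lo <= 0.0 <= hi
        assert covered >= 5
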