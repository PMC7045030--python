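import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatptb.synthetic import generate_dataset, scenario_config
from heatptb.total_effects import (
    DesignError,
    ModelSpec,
    attributable_fraction,
    bootstrap_effect,
    bspline_basis,
    build_design,
    fit_count_model,
    relative_risk,
)
from tests.conftest import make_analysis


class TestSplineBasis:
    def test_partition_of_unity(self, rng):
        x = rng.uniform(0, 100, size=400)
        basis = bspline_basis(x, n_interior=5)
        assert np.allclose(basis.sum(axis=1), 1.0)

    def test_dimension_arithmetic(self, rng):
        x = rng.uniform(0, 365, size=300)
        b5 = bspline_basis(x, n_interior=5)
        b8 = bspline_basis(x, n_interior=8)
        assert b8.shape[1] - b5.shape[1] == 3


class TestDesign:
    def test_hinge_zero_at_knot(self, no_mediation_analysis):
        analysis, _ = no_mediation_analysis
        X, colmap, knot = build_design(analysis, ModelSpec())
        at = analysis["at2_c"].to_numpy()
        at_knot_rows = np.isclose(at, knot)
        assert np.all(X["at_hinge"].to_numpy()[at <= knot] == 0.0)
        assert colmap["at"] == ["at_lin", "at_hinge"]

    def test_knot_count_changes_columns_by_three(self, no_mediation_analysis):
        analysis, _ = no_mediation_analysis
        X5, _, _ = build_design(analysis, ModelSpec(doy_knots=5))
        X8, _, _ = build_design(analysis, ModelSpec(doy_knots=8))
        assert X8.shape[1] - X5.shape[1] == 3

    def test_collinear_covariate_raises(self, no_mediation_analysis):
        analysis, _ = no_mediation_analysis
        broken = analysis.copy()
        broken["dup"] = broken["solar_wm2"]
        with pytest.raises(DesignError, match="collinear"):
            build_design(broken, ModelSpec(covariates=("solar", "wind", "ln_precip", "dup")))

    def test_knot_outside_range_raises(self, no_mediation_analysis):
        analysis, _ = no_mediation_analysis
        with pytest.raises(DesignError, match="outside"):
            build_design(analysis, ModelSpec(at_knot_c=99.0))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(doy_knots=0)
        with pytest.raises(ValueError):
            ModelSpec(family="gaussian")


class TestFit:
    def test_intercept_only_closed_form(self):
        counts = np.array([4.0] * 50 + [2.0] * 50)
        X = pd.DataFrame({"const": np.ones(100)})
        fit = fit_count_model(counts, X, ModelSpec(), {"intercept": ["const"]}, 0.0)
        assert fit.params["const"] == pytest.approx(np.log(counts.mean()), abs=1e-8)

    def test_null_scenario_hinge_near_zero(self, null_analysis):
        analysis, counts = null_analysis
        X, colmap, knot = build_design(analysis, ModelSpec())
        fit = fit_count_model(counts, X, ModelSpec(), colmap, knot)
        se = fit.result.bse["at_hinge"]
        assert abs(fit.params["at_hinge"]) < 3 * se

    def test_parameter_recovery(self, no_mediation_analysis, no_mediation_ds):
        analysis, counts = no_mediation_analysis
        spec = ModelSpec(at_knot_c=no_mediation_ds.truth["at_threshold_c"])
        X, colmap, knot = build_design(analysis, spec)
        fit = fit_count_model(counts, X, spec, colmap, knot)
        se = fit.result.bse["at_hinge"]
        assert abs(fit.params["at_hinge"] - 0.03) < 3 * se

    def test_negative_counts_rejected(self, no_mediation_analysis):
        analysis, counts = no_mediation_analysis
        X, colmap, knot = build_design(analysis, ModelSpec())
        bad = counts.copy()
        bad[0] = -1
        with pytest.raises(ValueError):
            fit_count_model(bad, X, ModelSpec(), colmap, knot)

    def test_constant_weights_match_unweighted(self, no_mediation_analysis):
        analysis, counts = no_mediation_analysis
        spec = ModelSpec()
        X, colmap, knot = build_design(analysis, spec)
        fit1 = fit_count_model(counts, X, spec, colmap, knot)
        fit2 = fit_count_model(counts, X, spec, colmap, knot,
                               weights=np.full(len(counts), 3.7))
        assert np.allclose(fit1.params, fit2.params, atol=1e-8)

    def test_dispersion_statistic_recorded(self, no_mediation_analysis):
        analysis, counts = no_mediation_analysis
        spec = ModelSpec()
        X, colmap, knot = build_design(analysis, spec)
        fit = fit_count_model(counts, X, spec, colmap, knot)
        assert 0.5 < fit.dispersion < 2.0  # Poisson data: near 1


class TestRelativeRisk:
    def test_identity_contrast(self, no_mediation_analysis):
        analysis, counts = no_mediation_analysis
        spec = ModelSpec()
        X, colmap, knot = build_design(analysis, spec)
        fit = fit_count_model(counts, X, spec, colmap, knot)
        assert relative_risk(fit, 22.0, 22.0) == pytest.approx(1.0)

    def test_closed_form_above_knot(self, no_mediation_analysis):
        analysis, counts = no_mediation_analysis
        spec = ModelSpec()
        X, colmap, knot = build_design(analysis, spec)
        fit = fit_count_model(counts, X, spec, colmap, knot)
        delta = 3.0
        expected = np.exp((fit.params["at_lin"] + fit.params["at_hinge"]) * delta)
        assert relative_risk(fit, knot + delta, knot) == pytest.approx(expected, rel=1e-12)


class TestAttributableFraction:
    def test_unity_rr(self):
        assert attributable_fraction(1.0) == 0.0

    def test_published_pair(self):
        assert round(attributable_fraction(1.11), 1) == 9.9

    def test_rr_two(self):
        assert attributable_fraction(2.0) == pytest.approx(50.0)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            attributable_fraction(0.0)

    def test_literal_formula_is_negative_above_one(self):
        assert attributable_fraction(1.11, literal=True) < 0

    @given(st.floats(0.1, 50.0), st.floats(0.1, 50.0))
    @settings(max_examples=80, deadline=None)
    def test_strictly_increasing_in_rr(self, a, b):
        lo, hi = sorted((a, b))
        if hi - lo > 1e-9:
            assert attributable_fraction(hi) > attributable_fraction(lo)

    def test_approaches_100_for_large_rr(self):
        grid = np.logspace(0, 4, 30)
        afs = np.array([attributable_fraction(r) for r in grid])
        assert np.all(np.diff(afs) > 0)
        assert afs[-1] > 99.9
        assert np.all(afs < 100)


class TestBootstrap:
    def test_point_only_when_nboot_zero(self, no_mediation_analysis):
        analysis, counts = no_mediation_analysis
        est = bootstrap_effect(analysis, counts, ModelSpec(), n_boot=0)
        assert est.rr_ci is None and est.af_ci is None
        assert est.rr > 0

    def test_seed_determinism(self, no_mediation_analysis):
        analysis, counts = no_mediation_analysis
        a = bootstrap_effect(analysis, counts, ModelSpec(), n_boot=25, seed=8)
        b = bootstrap_effect(analysis, counts, ModelSpec(), n_boot=25, seed=8)
        assert a.rr_ci == b.rr_ci and a.af_ci == b.af_ci

    def test_ci_brackets_point(self, no_mediation_analysis):
        analysis, counts = no_mediation_analysis
        est = bootstrap_effect(analysis, counts, ModelSpec(), n_boot=60, seed=3)
        assert est.rr_ci[0] <= est.rr <= est.rr_ci[1]
        assert est.af_ci[0] <= est.af_percent <= est.af_ci[1]

    def test_block_bootstrap_runs(self, no_mediation_analysis):
        analysis, counts = no_mediation_analysis
        est = bootstrap_effect(analysis, counts, ModelSpec(), n_boot=10, seed=1,
                               block_length=7)
        assert est.rr_ci is not None

    def test_null_scenario_af_ci_covers_zero(self, null_analysis):
        # single-fixture check; the multi-seed coverage experiment lives in
        # the acceptance suite
        analysis, counts = null_analysis
        est = bootstrap_effect(analysis, counts, ModelSpec(), n_boot=80, seed=2)
        assert est.af_ci[0] <= 0.0 <= est.af_ci[1]


def test_knot_sensitivity_pattern(no_mediation_analysis):
    analysis, counts = no_mediation_analysis
    p50, p95 = np.percentile(analysis["at2_c"], [50, 95])
    afs = []
    for k in (2, 5, 8):
        spec = ModelSpec(doy_knots=k, covariates=())
        X, colmap, knot = build_design(analysis, spec)
        fit = fit_count_model(counts, X, spec, colmap, knot)
        afs.append(attributable_fraction(relative_risk(fit, p95, p50)))
    assert max(afs) - min(afs) < 3.0
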