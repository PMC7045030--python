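"""Seeded synthetic daily weather, pollutants and stratified birth counts.

Every downstream stage of the pipeline can be exercised against data whose
generating parameters — and hence true relative risks, attributable fractions
and additive-interaction magnitudes — are known exactly.

The generator produces, for each simulated year, a warm-season block of
consecutive days (default day-of-year 121-273, May through September) plus a
few warm-up days so that lagged exposures are defined on the first season day.
Daily temperature is a seasonal sinusoid plus AR(1) noise; dew point is
temperature minus a gamma-distributed depression (so dew point never exceeds
temperature); pollutants are linear in the 2-day-mean apparent temperature
plus meteorology terms and Gaussian noise; and births are Poisson or
negative-binomial counts per (date x maternal-stratum) cell whose log mean
contains a smooth seasonal term, a hinge (piecewise-linear) term in apparent
temperature above a threshold, optional pollutant-mediated terms and optional
modifier interactions calibrated to requested additive-interaction targets.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import compute_apparent_temperature, lag_mean

__all__ = [
    "ScenarioConfig",
    "SyntheticDataset",
    "MODIFIERS",
    "generate_weather",
    "generate_pollutants",
    "generate_births",
    "generate_dataset",
    "scenario_config",
]

#: Binary maternal indicators, in canonical column order. The two age
#: indicators are mutually exclusive by construction.
MODIFIERS = ("black", "age16_19", "age30plus", "low_prenatal", "smoker", "no_hs")

POLLUTANTS = ("o3_ppb", "pm10_ugm3", "no2_ppb")


class ConfigError(ValueError):
    """A scenario configuration field is out of its legal range."""


@dataclass
class ScenarioConfig:
    """Ground-truth parameters for one synthetic scenario.

    Attributes
    ----------
    n_years : int
        Number of simulated warm seasons.
    season_start_doy, season_end_doy : int
        Day-of-year window of the season (default 121-273, i.e. May-Sep in
        non-leap years).
    beta0 : float
        Baseline log daily count of events summed over all strata.
    beta_at : float
        Log rate ratio per deg C of 2-day-mean apparent temperature above
        ``at_threshold_c`` (hinge term).
    at_threshold_c : float or None
        Hinge location; ``None`` means the realized median of the simulated
        warm-season 2-day-mean apparent temperature.
    gamma_o3, gamma_pm10, gamma_no2 : float
        Log rate per unit pollutant (mediated pathway).
    alpha_at_to_pollutant : dict
        Per-pollutant slope of the pollutant on 2-day-mean apparent
        temperature.
    seasonal_amplitude : float
        Peak-to-trough amplitude of the seasonal term in the birth log rate.
    modifier_prevalences : dict
        Marginal probability of each maternal indicator.
    modifier_log_rr : dict
        Main-effect log rate ratio per indicator.
    reri_targets : dict
        Target additive-interaction magnitude per indicator at the
        p95-vs-p50 exposure contrast (see ``generate_births``).
    missing_frac : float
        Fraction of pollutant days masked missing, completely at random.
    dispersion : float
        Negative-binomial overdispersion (variance = mu + dispersion*mu^2);
        0 means Poisson.
    """

    n_years: int = 11
    start_year: int = 1991
    season_start_doy: int = 121
    season_end_doy: int = 273
    warmup_days: int = 3

    beta0: float = 1.0
    beta_at: float = 0.0
    at_threshold_c: float | None = None
    gamma_o3: float = 0.0
    gamma_pm10: float = 0.0
    gamma_no2: float = 0.0
    alpha_at_to_pollutant: dict = field(
        default_factory=lambda: {"o3_ppb": 1.5, "pm10_ugm3": 1.0, "no2_ppb": 0.4}
    )
    seasonal_amplitude: float = 0.2
    modifier_prevalences: dict = field(
        default_factory=lambda: {
            "black": 0.71,
            "age16_19": 0.20,
            "age30plus": 0.27,
            "low_prenatal": 0.33,
            "smoker": 0.26,
            "no_hs": 0.39,
        }
    )
    modifier_log_rr: dict = field(default_factory=dict)
    reri_targets: dict = field(default_factory=dict)
    missing_frac: float = 0.0
    dispersion: float = 0.0
    seed: int = 0

    # weather sub-model (documented defaults; AR(1) coefficient 0.7 mimics
    # multi-day synoptic persistence)
    temp_mean_c: float = 13.0
    temp_seasonal_amplitude: float = 7.0
    temp_ar_coef: float = 0.7
    temp_ar_sd: float = 2.0
    dewpoint_depression_shape: float = 2.0
    dewpoint_depression_scale: float = 2.0
    pollutant_noise_sd: dict = field(
        default_factory=lambda: {"o3_ppb": 8.0, "pm10_ugm3": 8.0, "no2_ppb": 4.0}
    )

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_years < 1:
            raise ConfigError("n_years must be >= 1")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ConfigError("missing_frac must lie in [0, 1)")
        for name, p in self.modifier_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"modifier_prevalences[{name!r}] must lie in [0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not 1 <= self.season_start_doy < self.season_end_doy <= 365:
            raise ConfigError("season_start_doy/season_end_doy out of order")
        if self.temp_ar_sd < 0 or self.temp_seasonal_amplitude < 0:
            raise ConfigError("temp_ar_sd and temp_seasonal_amplitude must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticDataset:
    """One complete scenario realization plus its ground truth block."""

    weather: pd.DataFrame
    pollutants: pd.DataFrame  # observed values, NaN where masked
    pollutants_true: pd.DataFrame  # pre-masking values
    missing_mask: pd.DataFrame  # True where masked
    births: pd.DataFrame  # date x stratum counts (long form)
    truth: dict

    def daily_counts(self) -> pd.Series:
        """Total events per day, summed over strata."""
        return self.births.groupby("date")["count"].sum()

    def write(self, out_dir):
        """Write the three tables as CSV (ISO dates) plus truth.json."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.weather.to_csv(out / "weather.csv", index_label="date", date_format="%Y-%m-%d")
        self.pollutants.to_csv(out / "pollutants.csv", index_label="date", date_format="%Y-%m-%d")
        self.births.to_csv(out / "births.csv", index=False, date_format="%Y-%m-%d")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


def _season_dates(config: ScenarioConfig, include_warmup: bool) -> pd.DatetimeIndex:
    blocks = []
    for year in range(config.start_year, config.start_year + config.n_years):
        origin = pd.Timestamp(year=year, month=1, day=1)
        start = config.season_start_doy - (config.warmup_days if include_warmup else 0)
        days = np.arange(start, config.season_end_doy + 1)
        blocks.append(origin + pd.to_timedelta(days - 1, unit="D"))
    return pd.DatetimeIndex(np.concatenate([b.values for b in blocks]))


def generate_weather(config: ScenarioConfig) -> pd.DataFrame:
    """Simulate daily meteorology for every season block (plus warm-up days).

    Temperature is a mid-July-peaking sinusoid plus AR(1) noise; dew point is
    temperature minus a positive gamma-distributed depression; precipitation
    is zero-inflated gamma; solar radiation follows a clipped seasonal curve.
    Byte-identical output for identical (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dates = _season_dates(config, include_warmup=True)
    doy = dates.dayofyear.values.astype(float)

    seasonal = config.temp_seasonal_amplitude * np.cos(2 * np.pi * (doy - 199.0) / 365.25)
    ar = np.zeros(len(dates))
    innov = rng.normal(0.0, config.temp_ar_sd, size=len(dates))
    # restart the AR chain at each season block boundary
    new_block = np.r_[True, np.diff(dates.values).astype("timedelta64[D]") != np.timedelta64(1, "D")]
    for i in range(len(dates)):
        ar[i] = innov[i] if new_block[i] else config.temp_ar_coef * ar[i - 1] + innov[i]
    temp = config.temp_mean_c + seasonal + ar

    depression = rng.gamma(
        config.dewpoint_depression_shape, config.dewpoint_depression_scale, size=len(dates)
    )
    dewpoint = temp - depression

    wind = np.clip(rng.gamma(6.0, 0.6, size=len(dates)), 0.1, None)
    solar = np.clip(
        170.0
        + 60.0 * np.cos(2 * np.pi * (doy - 172.0) / 365.25)
        + rng.normal(0, 35.0, size=len(dates)),
        5.0,
        None,
    )
    wet = rng.random(len(dates)) > 0.53
    precip = np.where(wet, rng.gamma(0.9, 6.0, size=len(dates)), 0.0)

    return pd.DataFrame(
        {
            "temp_c": temp,
            "dewpoint_c": dewpoint,
            "wind_ms": wind,
            "solar_wm2": solar,
            "precip_mm": precip,
        },
        index=dates,
    )


def _at2_from_weather(weather: pd.DataFrame) -> pd.Series:
    at = compute_apparent_temperature(weather["temp_c"], weather["dewpoint_c"])
    return lag_mean(at, (0, 1))


def generate_pollutants(weather: pd.DataFrame, config: ScenarioConfig):
    """Simulate daily pollutants driven by 2-day-mean apparent temperature.

    Each pollutant is ``intercept + alpha * AT2 + meteorology terms + noise``,
    floored at a small positive value. Returns ``(observed, true, mask)``:
    ``observed`` has NaN on days masked missing completely at random with
    probability ``missing_frac`` per pollutant.

    Raises ``ValueError`` if weather does not cover the configured dates.
    """
    expected = _season_dates(config, include_warmup=True)
    if not expected.isin(weather.index).all():
        raise ValueError("weather table does not cover the configured scenario dates")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    at2 = _at2_from_weather(weather)
    # warm-up day 1 of each block has no lag-1 AT; use same-day AT there
    at2 = at2.fillna(compute_apparent_temperature(weather["temp_c"], weather["dewpoint_c"]))

    intercepts = {"o3_ppb": 18.0, "pm10_ugm3": 22.0, "no2_ppb": 12.0}
    met = 0.02 * weather["solar_wm2"] - 0.8 * weather["wind_ms"]
    true = {}
    for pol in POLLUTANTS:
        alpha = config.alpha_at_to_pollutant.get(pol, 0.0)
        noise = rng.normal(0.0, config.pollutant_noise_sd.get(pol, 5.0), size=len(weather))
        true[pol] = np.clip(intercepts[pol] + alpha * at2.values + met.values + noise, 0.5, None)
    true_df = pd.DataFrame(true, index=weather.index)

    mask = pd.DataFrame(
        rng.random((len(weather), len(POLLUTANTS))) < config.missing_frac,
        index=weather.index,
        columns=list(POLLUTANTS),
    )
    observed = true_df.mask(mask)
    return observed, true_df, mask


def _stratum_table(config: ScenarioConfig) -> pd.DataFrame:
    """All 48 legal indicator combinations with their joint probabilities.

    Indicators are independent except the two age groups, which form a
    three-level category (16-19 / 20-29 / >=30) and never co-occur.
    """
    prev = config.modifier_prevalences
    rows = []
    for combo in itertools.product((0, 1), repeat=len(MODIFIERS)):
        s = dict(zip(MODIFIERS, combo))
        if s["age16_19"] and s["age30plus"]:
            continue
        p = 1.0
        for m in ("black", "low_prenatal", "smoker", "no_hs"):
            p *= prev[m] if s[m] else 1.0 - prev[m]
        if s["age16_19"]:
            p *= prev["age16_19"]
        elif s["age30plus"]:
            p *= prev["age30plus"]
        else:
            p *= 1.0 - prev["age16_19"] - prev["age30plus"]
        rows.append({**s, "p_stratum": p})
    df = pd.DataFrame(rows)
    assert abs(df["p_stratum"].sum() - 1.0) < 1e-12
    return df


def _modifier_composition_log_odds(config: ScenarioConfig, modifier: str) -> float:
    """Log ratio of the stratum-probability factor at indicator 1 vs 0.

    In a count model on stratum-expanded data without an at-risk offset, the
    fitted indicator main effect converges to the biological log rate ratio
    PLUS this composition term (more prevalent strata simply contain more
    births). The additive-interaction calibration must therefore work on the
    model scale, composition included.
    """
    prev = config.modifier_prevalences
    if modifier == "age16_19":
        return float(np.log(prev["age16_19"] / (1.0 - prev["age16_19"] - prev["age30plus"])))
    if modifier == "age30plus":
        return float(np.log(prev["age30plus"] / (1.0 - prev["age16_19"] - prev["age30plus"])))
    p = prev[modifier]
    return float(np.log(p / (1.0 - p)))


def _interaction_excess(config: ScenarioConfig, modifier: str, delta_c: float) -> float:
    """Excess log rate for a modifier's high-exposure stratum that achieves
    the requested additive-interaction target at contrast ``delta_c`` deg C.

    The target is defined on the scale a stratum-expanded count model
    estimates: RERI = rr11 - rr10 - rr01 + 1 with
    rr10 = exp(beta_at * delta), rr01 = exp(main + composition), and
    rr11 = exp(main + composition + beta_at * delta + excess); solving for
    ``excess`` is closed-form. Modifiers without an entry in
    ``reri_targets`` get no injected interaction (excess 0). Raises if the
    target is infeasible (implied rr11 <= 0).
    """
    if modifier not in config.reri_targets:
        return 0.0
    target = config.reri_targets[modifier]
    main = config.modifier_log_rr.get(modifier, 0.0) + _modifier_composition_log_odds(
        config, modifier
    )
    rr10 = np.exp(config.beta_at * delta_c)
    rr01 = np.exp(main)
    rr11 = target + rr10 + rr01 - 1.0
    if rr11 <= 0:
        raise ConfigError(f"reri_targets[{modifier!r}]={target} infeasible")
    return float(np.log(rr11) - main - config.beta_at * delta_c)


def generate_births(
    weather: pd.DataFrame, pollutants_true: pd.DataFrame, config: ScenarioConfig
):
    """Simulate daily event counts per (date x maternal stratum).

    The log mean for stratum ``s`` on day ``d`` is::

        beta0 + ln p_s + seasonal(d) + beta_at * max(0, AT2_d - thr)
        + sum_p gamma_p * pollutant_pd
        + sum_m main_m * I_m(s) + sum_m (excess_m / delta) * hinge_d * I_m(s)

    where ``excess_m`` is calibrated so that each modifier attains its
    ``reri_targets`` value at the p95-vs-p50 contrast of the simulated
    season. Counts are Poisson, or gamma-Poisson (negative binomial) when
    ``dispersion > 0``. Returns ``(births, truth)``.
    """
    if not weather.index.equals(pollutants_true.index):
        raise ValueError("weather and pollutant tables are not date-aligned")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    season_dates = _season_dates(config, include_warmup=False)
    at2 = _at2_from_weather(weather).loc[season_dates]
    doy = season_dates.dayofyear.values.astype(float)

    at2_season = at2.values
    p50, p95 = np.percentile(at2_season, [50, 95])
    thr = float(p50 if config.at_threshold_c is None else config.at_threshold_c)
    hinge = np.maximum(0.0, at2_season - thr)
    delta = float(max(p95 - thr, 1e-6))

    seasonal = 0.5 * config.seasonal_amplitude * np.cos(2 * np.pi * (doy - 197.0) / 365.25)
    gammas = {"o3_ppb": config.gamma_o3, "pm10_ugm3": config.gamma_pm10, "no2_ppb": config.gamma_no2}
    med = np.zeros(len(season_dates))
    for pol, g in gammas.items():
        if g != 0.0:
            med = med + g * pollutants_true.loc[season_dates, pol].values

    strata = _stratum_table(config)
    excess = {m: _interaction_excess(config, m, delta) for m in MODIFIERS}
    reri_truth = {}
    for m in MODIFIERS:
        main = config.modifier_log_rr.get(m, 0.0) + _modifier_composition_log_odds(config, m)
        rr10 = float(np.exp(config.beta_at * delta))
        rr01 = float(np.exp(main))
        rr11 = float(np.exp(main + config.beta_at * delta + excess[m]))
        reri_truth[m] = rr11 - rr10 - rr01 + 1.0

    frames = []
    for _, srow in strata.iterrows():
        log_mu = (
            config.beta0
            + np.log(srow["p_stratum"])
            + seasonal
            + config.beta_at * hinge
            + med
        )
        for m in MODIFIERS:
            if srow[m]:
                log_mu = log_mu + config.modifier_log_rr.get(m, 0.0)
                log_mu = log_mu + (excess[m] / delta) * hinge
        mu = np.exp(log_mu)
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            mu = rng.gamma(shape, mu / shape)
        counts = rng.poisson(mu)
        frame = pd.DataFrame({"date": season_dates, "count": counts})
        for m in MODIFIERS:
            frame[m] = int(srow[m])
        frames.append(frame)
    births = pd.concat(frames, ignore_index=True)[["date", *MODIFIERS, "count"]]

    rr_hinge = float(np.exp(config.beta_at * (max(p95 - thr, 0.0) - max(p50 - thr, 0.0))))
    mediated = sum(
        gammas[pol] * config.alpha_at_to_pollutant.get(pol, 0.0) for pol in POLLUTANTS
    ) * (p95 - p50)
    rr_total = float(rr_hinge * np.exp(mediated))
    truth = {
        "config": config.to_dict(),
        "at_p50": float(p50),
        "at_p95": float(p95),
        "at_threshold_c": thr,
        "true_rr_direct": rr_hinge,
        "true_rr_total": rr_total,
        "true_af_direct_pct": (1.0 - 1.0 / rr_hinge) * 100.0,
        "true_af_total_pct": (1.0 - 1.0 / rr_total) * 100.0,
        "interaction_excess_log_rr": excess,
        "true_reri_model_scale": reri_truth,
    }
    return births, truth


def generate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Run the full generator chain for one scenario."""
    weather = generate_weather(config)
    observed, true_df, mask = generate_pollutants(weather, config)
    births, truth = generate_births(weather, true_df, config)
    return SyntheticDataset(
        weather=weather,
        pollutants=observed,
        pollutants_true=true_df,
        missing_mask=mask,
        births=births,
        truth=truth,
    )


def scenario_config(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Preset scenario configurations.

    ``null``          no exposure, mediator or modifier effects;
    ``no_mediation``  a direct hinge effect of heat only;
    ``mediation``     direct effect plus an ozone-mediated pathway;
    ``interaction``   direct effect plus calibrated modifier interactions.
    """
    presets = {
        "null": {},
        # Weak AT->pollutant coupling keeps the inverse-odds weights stable
        # (strong coupling makes the density ratio heavy-tailed), and a higher
        # baseline count sharpens the weighted direct-effect estimate.
        "no_mediation": {
            "beta_at": 0.03,
            "beta0": 2.0,
            "alpha_at_to_pollutant": {"o3_ppb": 0.6, "pm10_ugm3": 0.4, "no2_ppb": 0.15},
            "pollutant_noise_sd": {"o3_ppb": 10.0, "pm10_ugm3": 10.0, "no2_ppb": 5.0},
        },
        "mediation": {"beta_at": 0.03, "beta0": 2.0, "gamma_o3": 0.004, "missing_frac": 0.15},
        "interaction": {
            "beta_at": 0.03,
            "modifier_log_rr": {"smoker": 0.2, "black": 0.3},
            "reri_targets": {"smoker": 0.5, "black": -0.3},
        },
    }
    if name not in presets:
        raise ConfigError(f"unknown scenario {name!r}; choose from {sorted(presets)}")
    kwargs = dict(presets[name])
    kwargs.update(overrides)
    return ScenarioConfig(seed=seed, **kwargs)
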