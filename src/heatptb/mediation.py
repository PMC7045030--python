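"""Natural direct effects via inverse odds weighting.

Stage 1 regresses the exposure (2-day-mean apparent temperature) on the
pollutant mediators (lag 0-1 means of ozone, ln PM10 and ln NO2) plus the
meteorological confounders by ordinary least squares. Stage 2 refits the
total-effects count model with per-day weights derived from stage 1, dropping
the pollutants; the weighted fit estimates the direct effect, and the
indirect effect is the difference total - direct. Estimates are averaged
over the multiply-imputed datasets; the bootstrap re-runs both stages inside
every resample so the interval reflects weight-estimation uncertainty.

Two weighting schemes are available:

``literal``
    ``w_d = 1 / exp(Ahat_d / sigma2)`` where ``Ahat`` is the stage-1 fitted
    exposure and ``sigma2`` the stage-1 mean squared error. Computed in log
    space and normalized to mean 1 (the weighted likelihood is invariant to
    any positive rescaling).
``density_ratio``
    ``w_d = f(A_d | confounders) / f(A_d | mediators + confounders)`` with
    normal densities from the two nested OLS fits — the standard
    inverse-odds construction for a continuous exposure; this is the scheme
    under which parameter-recovery properties are asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exposure import lag_mean
from .total_effects import (
    EffectEstimate,
    ModelSpec,
    attributable_fraction,
    build_design,
    fit_count_model,
    relative_risk,
)

__all__ = [
    "ExposureModel",
    "MediationResult",
    "add_mediator_lag_means",
    "fit_exposure_model",
    "inverse_odds_weights",
    "estimate_direct",
    "decompose_and_pool",
    "run_mediation",
]

MEDIATOR_COLS = ("o3_ppb", "ln_pm10", "ln_no2")
CONFOUNDER_COLS = ("solar_wm2", "wind_ms", "ln_precip")

SIGMA2_FLOOR = 1e-8


@dataclass
class ExposureModel:
    """OLS of exposure on mediators + confounders, plus the nested
    confounders-only fit used by the density-ratio scheme."""

    params: pd.Series
    sigma2: float
    mediators: tuple
    confounders: tuple
    reduced_params: pd.Series
    reduced_sigma2: float

    def design(self, series: pd.DataFrame, reduced: bool = False) -> pd.DataFrame:
        X = _exposure_design(series, self.mediators, self.confounders, reduced=reduced)
        return X

    def predict(self, series: pd.DataFrame, reduced: bool = False) -> np.ndarray:
        X = self.design(series, reduced=reduced)
        beta = self.reduced_params if reduced else self.params
        return X.to_numpy() @ beta.to_numpy()


def _mediator_lag01(series: pd.DataFrame) -> pd.DataFrame:
    """Lag 0-1 means of the mediator columns, matching the exposure window.

    Uses precomputed ``<col>_m01`` columns when present (bootstrap resamples
    have duplicated dates, on which lag means cannot be recomputed).
    """
    out = {}
    for col in MEDIATOR_COLS:
        name = f"{col}_m01"
        if name in series.columns:
            out[name] = series[name]
        else:
            out[name] = lag_mean(series[col], (0, 1))
    return pd.DataFrame(out, index=series.index)


def add_mediator_lag_means(series: pd.DataFrame) -> pd.DataFrame:
    """Attach the ``<mediator>_m01`` columns; call before any resampling."""
    out = series.copy()
    for name, col in _mediator_lag01(series).items():
        out[name] = col
    return out


def _exposure_design(series, mediators, confounders, reduced=False):
    cols = {"const": np.ones(len(series))}
    if not reduced:
        med = _mediator_lag01(series)
        for c in med.columns:
            cols[c] = med[c].to_numpy()
    for c in confounders:
        cols[c] = series[c].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=series.index)
    if X.isna().any().any():
        # lag-0-1 mediator means are undefined on the first day of each
        # seasonal block; fall back to the same-day value there
        med = {f"{c}_m01": series[c] for c in MEDIATOR_COLS}
        for name, s in med.items():
            if name in X.columns:
                X[name] = X[name].fillna(s)
        X = X.fillna(X.mean())
    return X


def fit_exposure_model(series: pd.DataFrame) -> ExposureModel:
    """OLS of ``at2_c`` on lag 0-1 mediator means plus confounders.

    ``sigma2`` is the residual mean squared error (RSS / residual df),
    floored at a small positive value to guard the degenerate perfect-fit
    case. Raises on collinear mediators.
    """
    y = series["at2_c"].to_numpy(dtype=float)
    keep = np.isfinite(y)
    X = _exposure_design(series, MEDIATOR_COLS, CONFOUNDER_COLS)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("exposure model design is collinear")
    res = sm.OLS(y[keep], X.loc[keep]).fit()
    sigma2 = max(float(res.mse_resid), SIGMA2_FLOOR)
    Xr = _exposure_design(series, MEDIATOR_COLS, CONFOUNDER_COLS, reduced=True)
    res_r = sm.OLS(y[keep], Xr.loc[keep]).fit()
    sigma2_r = max(float(res_r.mse_resid), SIGMA2_FLOOR)
    return ExposureModel(
        params=res.params,
        sigma2=sigma2,
        mediators=MEDIATOR_COLS,
        confounders=CONFOUNDER_COLS,
        reduced_params=res_r.params,
        reduced_sigma2=sigma2_r,
    )


def inverse_odds_weights(
    model: ExposureModel, series: pd.DataFrame, scheme: str = "literal"
) -> np.ndarray:
    """Per-day weights, normalized to mean 1, under the chosen scheme.

    Both schemes are computed entirely in log space, so extreme fitted
    exposures never materialize an unnormalized under/overflowing weight.
    """
    if model.sigma2 < SIGMA2_FLOOR:
        raise ValueError("exposure-model sigma2 under the numerical floor")
    a = series["at2_c"].to_numpy(dtype=float)
    ahat = model.predict(series)
    if scheme == "literal":
        logw = -ahat / model.sigma2
    elif scheme == "density_ratio":
        ahat_r = model.predict(series, reduced=True)
        log_f_reduced = -0.5 * np.log(model.reduced_sigma2) - (a - ahat_r) ** 2 / (
            2 * model.reduced_sigma2
        )
        log_f_full = -0.5 * np.log(model.sigma2) - (a - ahat) ** 2 / (2 * model.sigma2)
        logw = log_f_reduced - log_f_full
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    logw = logw - logw.max()
    w = np.exp(logw)
    return w / w.mean()


def estimate_direct(
    series: pd.DataFrame,
    counts,
    weights,
    spec: ModelSpec,
    at_hi_c: float,
    at_ref_c: float,
    at_knot_c: float | None = None,
    start_params=None,
) -> EffectEstimate:
    """Weighted count-model fit (confounders, no pollutants): direct effect."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    X, colmap, knot = build_design(series, spec, at_knot_c=at_knot_c)
    fit = fit_count_model(counts, X, spec, colmap, knot, weights=weights,
                          start_params=start_params)
    rr = relative_risk(fit, at_hi_c, at_ref_c)
    return EffectEstimate(
        rr=rr, af_percent=attributable_fraction(rr), at_hi_c=at_hi_c, at_ref_c=at_ref_c
    )


@dataclass
class MediationResult:
    """Total / direct / indirect attributable fractions pooled over
    imputations; ``indirect = total - direct`` exactly by construction."""

    total_af: float
    direct_af: float
    indirect_af: float
    total_rr: float
    direct_rr: float
    m_pooled: int
    weight_scheme: str
    at_hi_c: float
    at_ref_c: float
    cis: dict = field(default_factory=dict)  # name -> (lo, hi)


def decompose_and_pool(totals, directs, rr_totals=None, rr_directs=None,
                       scheme: str = "literal", at_hi_c=np.nan, at_ref_c=np.nan
                       ) -> MediationResult:
    """Average per-imputation total and direct AFs; indirect = difference.

    Raises ``ValueError`` on mismatched imputation counts.
    """
    totals = list(totals)
    directs = list(directs)
    if len(totals) != len(directs) or not totals:
        raise ValueError("mismatched or empty per-imputation estimate lists")
    total = float(np.mean(totals))
    direct = float(np.mean(directs))
    return MediationResult(
        total_af=total,
        direct_af=direct,
        indirect_af=total - direct,
        total_rr=float(np.mean(rr_totals)) if rr_totals else np.nan,
        direct_rr=float(np.mean(rr_directs)) if rr_directs else np.nan,
        m_pooled=len(totals),
        weight_scheme=scheme,
        at_hi_c=at_hi_c,
        at_ref_c=at_ref_c,
    )


def _one_pass(completed, counts, spec, scheme, at_hi, at_ref, at_knot=None):
    """Totals and directs across the ``m`` completed datasets for one sample."""
    afs_t, afs_d, rrs_t, rrs_d = [], [], [], []
    for series in completed:
        X, colmap, knot = build_design(series, spec, at_knot_c=at_knot)
        fit = fit_count_model(counts, X, spec, colmap, knot)
        rr_t = relative_risk(fit, at_hi, at_ref)
        emod = fit_exposure_model(series)
        w = inverse_odds_weights(emod, series, scheme=scheme)
        est_d = estimate_direct(series, counts, w, spec, at_hi, at_ref, at_knot_c=knot,
                                start_params=np.asarray(fit.params))
        afs_t.append(attributable_fraction(rr_t))
        afs_d.append(est_d.af_percent)
        rrs_t.append(rr_t)
        rrs_d.append(est_d.rr)
    return afs_t, afs_d, rrs_t, rrs_d


def run_mediation(
    completed: list,
    counts,
    spec: ModelSpec,
    scheme: str = "literal",
    n_boot: int = 0,
    seed: int = 0,
    at_hi_c: float | None = None,
    at_ref_c: float | None = None,
) -> MediationResult:
    """Full mediation analysis over ``m`` completed datasets.

    The bootstrap resamples days i.i.d. and, inside each resample, re-runs
    the exposure model, the weights and both count fits for every completed
    dataset before pooling — so the CI carries weight-estimation
    uncertainty. The exposure contrast and the hinge knot are fixed at their
    full-sample values across resamples.
    """
    counts = np.asarray(counts, dtype=float)
    completed = [add_mediator_lag_means(s) for s in completed]
    at2 = completed[0]["at2_c"].to_numpy(dtype=float)
    if at_ref_c is None:
        at_ref_c = float(np.percentile(at2, 50))
    if at_hi_c is None:
        at_hi_c = float(np.percentile(at2, 95))

    afs_t, afs_d, rrs_t, rrs_d = _one_pass(completed, counts, spec, scheme, at_hi_c, at_ref_c)
    result = decompose_and_pool(afs_t, afs_d, rrs_t, rrs_d, scheme, at_hi_c, at_ref_c)
    knot = spec.at_knot_c if spec.at_knot_c is not None else float(np.median(at2))

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(counts)
        boot = {"total_af": [], "direct_af": [], "indirect_af": []}
        failures = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                t, d, _, _ = _one_pass(
                    [s.iloc[idx] for s in completed], counts[idx], spec, scheme,
                    at_hi_c, at_ref_c, at_knot=knot,
                )
            except Exception:
                failures += 1
                continue
            boot["total_af"].append(np.mean(t))
            boot["direct_af"].append(np.mean(d))
            boot["indirect_af"].append(np.mean(t) - np.mean(d))
        if failures > 0.05 * n_boot:
            raise RuntimeError(f"{failures}/{n_boot} mediation bootstrap resamples failed")
        for k, v in boot.items():
            result.cis[k] = tuple(np.percentile(v, [2.5, 97.5]))
    return result
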