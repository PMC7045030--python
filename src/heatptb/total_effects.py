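"""Total-effect estimation: spline Poisson time-series model of daily counts
on 2-day-mean apparent temperature, with relative-risk contrasts,
attributable fractions and bootstrap confidence intervals.

Model
-----
``log E[count_d] = b0 + s_doy(doy_d) + s_year(year_d) + b_lin*(AT2_d - k)
+ b_hinge*max(0, AT2_d - k) + covariates`` where ``s_doy`` and ``s_year`` are
cubic B-spline bases with interior knots at equally spaced quantiles and
``k`` is the hinge knot (default: the median warm-season AT2). The linear
term is centred at the knot so that contrasts against the knot read directly
off the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline

__all__ = [
    "ModelSpec",
    "ModelFit",
    "EffectEstimate",
    "bspline_basis",
    "build_design",
    "fit_count_model",
    "relative_risk",
    "attributable_fraction",
    "bootstrap_effect",
]

COVARIATE_COLS = {"solar": "solar_wm2", "wind": "wind_ms", "ln_precip": "ln_precip"}


class DesignError(ValueError):
    """The design matrix is unusable (rank deficiency, missing columns)."""


class FitError(RuntimeError):
    """The count model failed to converge."""


@dataclass
class ModelSpec:
    """Specification of the count model.

    ``doy_knots`` is the interior-knot count of the day-of-year cubic
    B-spline (2, 5 or 8 in replication mode, any positive integer otherwise);
    ``year_knots`` the interior-knot count of the year spline (over the
    integer year index). ``at_knot_c`` is the hinge location; ``None`` means
    the empirical median of the analysis-day AT2 values.
    """

    doy_knots: int = 5
    year_knots: int = 2
    at_knot_c: float | None = None
    covariates: tuple = ("solar", "wind", "ln_precip")
    family: str = "poisson"

    def __post_init__(self):
        if self.doy_knots < 1 or self.year_knots < 0:
            raise ValueError("knot counts must be positive")
        if self.family not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class ModelFit:
    """A fitted count model plus the metadata needed for contrasts."""

    result: object  # statsmodels results instance
    colmap: dict  # term group -> list of design column names
    at_knot_c: float
    converged: bool
    dispersion: float | None = None

    @property
    def params(self) -> pd.Series:
        return self.result.params


@dataclass
class EffectEstimate:
    """Relative risk and attributable fraction at an exposure contrast."""

    rr: float
    af_percent: float
    at_hi_c: float
    at_ref_c: float
    n_boot: int = 0
    rr_ci: tuple | None = None
    af_ci: tuple | None = None


def bspline_basis(x, n_interior: int, degree: int = 3, bounds=None) -> np.ndarray:
    """Full cubic B-spline basis with interior knots at equal quantiles.

    Rows sum to 1 (partition of unity); the basis has
    ``n_interior + degree + 1`` columns. Callers who include a separate
    intercept should drop the first column.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = (x.min(), x.max()) if bounds is None else bounds
    if hi <= lo:
        hi = lo + 1e-6
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs)
    interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, t, degree).toarray()


def _hinge(at, knot):
    return np.maximum(0.0, np.asarray(at, dtype=float) - knot)


def build_design(series: pd.DataFrame, spec: ModelSpec, at_knot_c: float | None = None):
    """Build the design matrix for the count model.

    Parameters
    ----------
    series : DataFrame
        Daily analysis table restricted to analysis days (warm season),
        with complete ``at2_c`` and covariate columns.
    spec : ModelSpec
    at_knot_c : float, optional
        Overrides ``spec.at_knot_c`` (used by bootstrap refits so the knot
        is held at the original-sample value).

    Returns
    -------
    X : DataFrame
        Design matrix with named columns.
    colmap : dict
        ``{"intercept": [...], "doy": [...], "year": [...], "at": [...],
        "covariates": [...]}``.
    knot : float
        The hinge knot actually used.
    """
    at2 = series["at2_c"].to_numpy(dtype=float)
    if np.isnan(at2).any():
        raise DesignError("at2_c contains missing values on analysis days")
    knot = spec.at_knot_c if at_knot_c is None else at_knot_c
    if knot is None:
        knot = float(np.median(at2))
    if not (at2.min() < knot < at2.max()):
        raise DesignError(f"at_knot_c={knot} lies outside the observed AT2 range")

    cols = {"const": np.ones(len(series))}
    colmap = {"intercept": ["const"], "doy": [], "year": [], "at": [], "covariates": []}

    doy = series.index.dayofyear.to_numpy(dtype=float)
    doy_basis = bspline_basis(doy, spec.doy_knots)[:, 1:]
    for j in range(doy_basis.shape[1]):
        name = f"doy_bs{j}"
        cols[name] = doy_basis[:, j]
        colmap["doy"].append(name)

    year = series.index.year.to_numpy(dtype=float)
    n_years = len(np.unique(year))
    if n_years > 1:
        if n_years >= spec.year_knots + 5:
            ybasis = bspline_basis(year, spec.year_knots)[:, 1:]
            for j in range(ybasis.shape[1]):
                name = f"year_bs{j}"
                cols[name] = ybasis[:, j]
                colmap["year"].append(name)
        else:  # too few distinct years to support a cubic spline: dummies
            for yv in np.unique(year)[1:]:
                name = f"year_{int(yv)}"
                cols[name] = (year == yv).astype(float)
                colmap["year"].append(name)

    cols["at_lin"] = at2 - knot
    cols["at_hinge"] = _hinge(at2, knot)
    colmap["at"] = ["at_lin", "at_hinge"]

    for cov in spec.covariates:
        col = COVARIATE_COLS.get(cov, cov)
        if col not in series.columns:
            raise DesignError(f"covariate column {col!r} missing from series")
        vals = series[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise DesignError(f"covariate {col!r} has missing values on analysis days")
        cols[col] = vals
        colmap["covariates"].append(col)

    X = pd.DataFrame(cols, index=series.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the error message
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8]
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X, colmap, float(knot)


def fit_count_model(
    counts,
    X: pd.DataFrame,
    spec: ModelSpec,
    colmap: dict,
    at_knot_c: float,
    weights=None,
    start_params=None,
) -> ModelFit:
    """Maximum-likelihood fit of the count model.

    ``weights`` are per-observation log-likelihood weights (used by the
    mediation stage); any positive rescaling of them leaves the coefficients
    unchanged. The Pearson dispersion statistic is recorded for an
    overdispersion check.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
    if spec.family == "poisson":
        fam = sm.families.Poisson()
    else:
        fam = sm.families.NegativeBinomial(alpha=1.0)
    model = sm.GLM(y, X, family=fam, freq_weights=weights)
    try:
        res = model.fit(start_params=start_params, maxiter=200)
    except Exception as exc:  # non-convergence and numerical failure paths
        raise FitError(f"count model failed to fit: {exc}") from exc
    converged = bool(getattr(res, "converged", True))
    if not converged:
        raise FitError("count model did not converge within 200 iterations")
    pearson = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else np.nan
    return ModelFit(result=res, colmap=colmap, at_knot_c=at_knot_c, converged=converged,
                    dispersion=pearson)


def _at_contrast_log_rr(fit: ModelFit, at_hi_c: float, at_ref_c: float) -> float:
    knot = fit.at_knot_c
    b = fit.params
    d_lin = (at_hi_c - knot) - (at_ref_c - knot)
    d_hinge = _hinge(at_hi_c, knot) - _hinge(at_ref_c, knot)
    return float(b["at_lin"] * d_lin + b["at_hinge"] * d_hinge)


def relative_risk(fit: ModelFit, at_hi_c: float, at_ref_c: float) -> float:
    """Relative risk for ``at_hi_c`` versus ``at_ref_c``, all else fixed."""
    return float(np.exp(_at_contrast_log_rr(fit, at_hi_c, at_ref_c)))


def attributable_fraction(rr: float, literal: bool = False) -> float:
    """Attributable fraction (%) among the exposed from a relative risk.

    Default: ``(1 - 1/RR) * 100``. The ``literal`` flag computes
    ``1/(1 - RR) * 100`` instead; it is provided for documentation purposes
    only — it is negative for any RR > 1 and is not used anywhere in the
    pipeline.
    """
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    if literal:
        if rr == 1.0:
            raise ZeroDivisionError("literal formula undefined at RR = 1")
        return (1.0 / (1.0 - rr)) * 100.0
    return (1.0 - 1.0 / rr) * 100.0


def _fit_and_contrast(series, counts, spec, weights, at_hi, at_ref, at_knot, start_params=None):
    X, colmap, knot = build_design(series, spec, at_knot_c=at_knot)
    fit = fit_count_model(counts, X, spec, colmap, knot, weights=weights,
                          start_params=start_params)
    rr = relative_risk(fit, at_hi, at_ref)
    return fit, rr


def bootstrap_effect(
    series: pd.DataFrame,
    counts,
    spec: ModelSpec,
    at_hi_c: float | None = None,
    at_ref_c: float | None = None,
    n_boot: int = 500,
    seed: int = 0,
    weights=None,
    block_length: int | None = None,
    max_failure_frac: float = 0.05,
) -> EffectEstimate:
    """Point estimate plus percentile bootstrap CI of the RR and AF.

    Days are resampled i.i.d. with replacement (or in moving blocks of
    ``block_length`` days when given, for autocorrelation sensitivity). The
    exposure contrast defaults to the p95-vs-p50 of the analysis-day AT2 and
    is held fixed — like the hinge knot — across resamples. Raises
    ``FitError`` if more than ``max_failure_frac`` of the resample fits fail.
    """
    counts = np.asarray(counts, dtype=float)
    at2 = series["at2_c"].to_numpy(dtype=float)
    if at_ref_c is None:
        at_ref_c = float(np.percentile(at2, 50))
    if at_hi_c is None:
        at_hi_c = float(np.percentile(at2, 95))

    fit, rr = _fit_and_contrast(series, counts, spec, weights, at_hi_c, at_ref_c, None)
    knot = fit.at_knot_c
    af = attributable_fraction(rr)
    est = EffectEstimate(rr=rr, af_percent=af, at_hi_c=at_hi_c, at_ref_c=at_ref_c,
                         n_boot=n_boot)
    if n_boot <= 0:
        return est

    rng = np.random.default_rng(seed)
    n = len(series)
    start = np.asarray(fit.params, dtype=float)
    rrs = []
    failures = 0
    for _ in range(n_boot):
        if block_length:
            n_blocks = int(np.ceil(n / block_length))
            starts = rng.integers(0, n - block_length + 1, size=n_blocks)
            idx = np.concatenate([np.arange(s, s + block_length) for s in starts])[:n]
        else:
            idx = rng.integers(0, n, size=n)
        try:
            _, rr_b = _fit_and_contrast(
                series.iloc[idx], counts[idx], spec,
                None if weights is None else np.asarray(weights)[idx],
                at_hi_c, at_ref_c, knot, start_params=start,
            )
            rrs.append(rr_b)
        except (FitError, DesignError):
            failures += 1
    if failures > max_failure_frac * n_boot:
        raise FitError(f"{failures}/{n_boot} bootstrap refits failed")
    rrs = np.asarray(rrs)
    afs = (1.0 - 1.0 / rrs) * 100.0
    est.rr_ci = tuple(np.percentile(rrs, [2.5, 97.5]))
    est.af_ci = tuple(np.percentile(afs, [2.5, 97.5]))
    return est
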