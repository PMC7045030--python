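"""Additive effect modification: RERI from a count model on stratum-expanded
daily data.

The daily counts are expanded to one row per (date x combination of the six
binary maternal indicators), materializing zero-count cells. A single count
model — negative binomial by default, falling back to Poisson when the
estimated overdispersion sits at the zero boundary — includes shared seasonal
and year splines, the apparent-temperature hinge terms, all six indicator
main effects and indicator-by-temperature interactions (on both the linear
and hinge terms). The relative excess risk due to interaction for modifier
``EM`` at the high-vs-reference exposure contrast is

    RERI = RR(hi, EM=1) - RR(hi, EM=0) - RR(ref, EM=1) + 1

with every RR taken against the common (ref, EM=0) denominator, all other
modifiers held at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import MODIFIERS
from .total_effects import FitError, ModelSpec, bspline_basis

__all__ = [
    "ReriResult",
    "expand_strata",
    "fit_interaction_model",
    "compute_reri",
    "bootstrap_reri",
    "reri_from_rrs",
    "resample_date_blocks",
]


@dataclass
class ReriResult:
    modifier: str
    reri: float
    at_hi_c: float
    at_ref_c: float
    ci: tuple | None = None
    n_boot: int = 0


def reri_from_rrs(rr11: float, rr10: float, rr01: float) -> float:
    """RERI identity: rr11 - rr10 - rr01 + 1."""
    return rr11 - rr10 - rr01 + 1.0


def expand_strata(births: pd.DataFrame, materialize_zeros: bool = True) -> pd.DataFrame:
    """Expand birth data to one row per (date x indicator combination).

    Accepts either per-birth records (one row per birth, ``count`` absent)
    or pre-aggregated stratum counts. All 48 legal combinations of the six
    indicators (the two age groups never co-occur) are materialized per date
    with zero counts unless ``materialize_zeros`` is False.

    Raises ``ValueError`` if any record carries both age indicators.
    """
    df = births.copy()
    if "count" not in df.columns:
        df["count"] = 1
    for m in MODIFIERS:
        if m not in df.columns:
            raise ValueError(f"indicator column {m!r} missing from birth records")
    if ((df["age16_19"] == 1) & (df["age30plus"] == 1)).any():
        raise ValueError("age16_19 and age30plus are mutually exclusive")

    agg = df.groupby(["date", *MODIFIERS], as_index=False)["count"].sum()
    if not materialize_zeros:
        return agg

    dates = pd.Index(sorted(df["date"].unique()), name="date")
    combos = [
        c
        for c in pd.MultiIndex.from_product([[0, 1]] * len(MODIFIERS), names=MODIFIERS)
        if not (c[1] == 1 and c[2] == 1)
    ]
    full = pd.MultiIndex.from_tuples(
        [(d, *c) for d in dates for c in combos], names=["date", *MODIFIERS]
    )
    out = (
        agg.set_index(["date", *MODIFIERS])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    out["count"] = out["count"].astype(int)
    return out


def _interaction_design(strata: pd.DataFrame, series: pd.DataFrame, spec: ModelSpec):
    """Design matrix on the stratum-expanded rows.

    Seasonal/year splines and the AT terms are functions of the date and are
    shared across strata; indicator mains and AT-by-indicator interactions
    complete the design. The AT linear term is centred at the hinge knot.
    """
    dates = pd.DatetimeIndex(strata["date"])
    at2 = series["at2_c"].reindex(dates).to_numpy(dtype=float)
    if np.isnan(at2).any():
        raise ValueError("exposure series does not cover all stratum dates")
    knot = spec.at_knot_c
    if knot is None:
        daily_at = series["at2_c"].reindex(pd.DatetimeIndex(sorted(set(dates))))
        knot = float(np.median(daily_at.to_numpy(dtype=float)))
    at_lin = at2 - knot
    at_hinge = np.maximum(0.0, at2 - knot)

    cols = {"const": np.ones(len(strata))}
    doy = dates.dayofyear.to_numpy(dtype=float)
    for j, col in enumerate(bspline_basis(doy, spec.doy_knots)[:, 1:].T):
        cols[f"doy_bs{j}"] = col
    year = dates.year.to_numpy(dtype=float)
    uyears = np.unique(year)
    if len(uyears) > 1:
        if len(uyears) >= spec.year_knots + 5:
            for j, col in enumerate(bspline_basis(year, spec.year_knots)[:, 1:].T):
                cols[f"year_bs{j}"] = col
        else:
            for yv in uyears[1:]:
                cols[f"year_{int(yv)}"] = (year == yv).astype(float)
    cols["at_lin"] = at_lin
    cols["at_hinge"] = at_hinge
    for m in MODIFIERS:
        ind = strata[m].to_numpy(dtype=float)
        cols[f"em_{m}"] = ind
        cols[f"em_{m}_x_at_lin"] = ind * at_lin
        cols[f"em_{m}_x_at_hinge"] = ind * at_hinge
    X = pd.DataFrame(cols)
    return X, float(knot)


@dataclass
class InteractionFit:
    result: object
    at_knot_c: float
    family: str  # "negative_binomial" or "poisson" (boundary fallback)
    alpha: float  # NB overdispersion estimate (0 under the Poisson fallback)


#: Moment-estimated overdispersion below which the Poisson fallback applies.
#: With sparse stratum-day cells the moment estimator wobbles by a few
#: hundredths around zero under Poisson truth; genuine overdispersion of
#: interest sits an order of magnitude above this.
ALPHA_BOUNDARY = 0.15


def fit_interaction_model(
    strata: pd.DataFrame,
    series: pd.DataFrame,
    spec: ModelSpec | None = None,
    start_params=None,
    family: str = "auto",
) -> InteractionFit:
    """Fit the stratum-expanded count model.

    A Poisson GLM supplies starting values and a moment estimate of the
    negative-binomial overdispersion ``alpha``. Under ``family="auto"``
    (default) a negative-binomial ML fit (dispersion estimated by maximum
    likelihood) is performed unless the moment estimate sits at the zero
    boundary, in which case the Poisson fit is returned with the family
    flagged — the NB likelihood degenerates to Poisson there and its
    optimizer is unreliable. ``family="negative_binomial"`` forces the NB
    fit; ``family="poisson"`` skips it.
    """
    spec = spec or ModelSpec()
    X, knot = _interaction_design(strata, series, spec)
    y = strata["count"].to_numpy(dtype=float)
    return _fit_from_design(y, X, knot, family=family, start_params=start_params)


def _fit_from_design(y, X, knot, family="auto", start_params=None) -> InteractionFit:
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit(start_params=start_params)
    mu = pois.fittedvalues
    alpha_mom = float(max(0.0, np.sum((y - mu) ** 2 - mu) / np.sum(mu**2)))
    if family == "poisson" or (family == "auto" and alpha_mom < ALPHA_BOUNDARY):
        return InteractionFit(result=pois, at_knot_c=knot, family="poisson", alpha=0.0)
    nb = sm.NegativeBinomial(y, X, loglike_method="nb2")
    start = np.r_[np.asarray(pois.params), max(alpha_mom, 1e-4)]
    try:
        res = nb.fit(start_params=start, disp=0, maxiter=200)
    except Exception as exc:
        raise FitError(f"negative binomial fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise FitError("negative binomial fit did not converge")
    return InteractionFit(
        result=res, at_knot_c=knot, family="negative_binomial",
        alpha=float(np.asarray(res.params)[-1]),
    )


def _coef_series(fit: InteractionFit) -> pd.Series:
    p = fit.result.params
    if isinstance(p, pd.Series):
        return p.drop("alpha", errors="ignore")
    # discrete NB returns a plain array ordered like exog + alpha
    names = [n for n in fit.result.model.exog_names if n != "alpha"]
    return pd.Series(np.asarray(p)[: len(names)], index=names)


def _lp_delta(coef: pd.Series, knot: float, modifier: str, at_c: float, em: int,
              at_ref_c: float) -> float:
    """Linear-predictor difference of (at_c, em) vs (at_ref_c, 0), all other
    modifiers at 0."""
    if f"em_{modifier}" not in coef.index:
        raise KeyError(f"modifier {modifier!r} not in the fitted model")
    k = knot

    def lp(at, em_val):
        h = max(0.0, at - k)
        v = coef["at_lin"] * (at - k) + coef["at_hinge"] * h
        if em_val:
            v += (
                coef[f"em_{modifier}"]
                + coef[f"em_{modifier}_x_at_lin"] * (at - k)
                + coef[f"em_{modifier}_x_at_hinge"] * h
            )
        return v

    return float(lp(at_c, em) - lp(at_ref_c, 0))


def _reri_from_coef(coef: pd.Series, knot: float, modifier: str,
                    at_hi_c: float, at_ref_c: float) -> float:
    rr11 = float(np.exp(_lp_delta(coef, knot, modifier, at_hi_c, 1, at_ref_c)))
    rr10 = float(np.exp(_lp_delta(coef, knot, modifier, at_hi_c, 0, at_ref_c)))
    rr01 = float(np.exp(_lp_delta(coef, knot, modifier, at_ref_c, 1, at_ref_c)))
    return reri_from_rrs(rr11, rr10, rr01)


def resample_date_blocks(row_blocks, rng):
    """Draw a cluster-bootstrap row index: whole date blocks, with
    replacement, so each resample preserves every sampled date's complete
    stratum composition (and hence its within-date count sum)."""
    pick = rng.choice(len(row_blocks), size=len(row_blocks), replace=True)
    return np.concatenate([row_blocks[i] for i in pick]), pick


def _poisson_irls(y, X, start, maxiter=50, tol=1e-9):
    """Minimal Newton/IRLS Poisson solver for hot bootstrap loops."""
    beta = np.asarray(start, dtype=float).copy()
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        g = X.T @ (y - mu)
        H = (X * mu[:, None]).T @ X
        step = np.linalg.solve(H, g)
        beta += step
        if np.max(np.abs(step)) < tol:
            return beta
    raise FitError("IRLS did not converge")


def compute_reri(fit: InteractionFit, modifier: str, at_hi_c: float, at_ref_c: float) -> ReriResult:
    """RERI for one modifier at the given exposure contrast.

    The three RRs share the (ref, EM=0) denominator; RERI is their exact
    additive-excess combination ``rr11 - rr10 - rr01 + 1``.
    """
    coef = _coef_series(fit)
    return ReriResult(
        modifier=modifier,
        reri=_reri_from_coef(coef, fit.at_knot_c, modifier, at_hi_c, at_ref_c),
        at_hi_c=at_hi_c,
        at_ref_c=at_ref_c,
    )


def bootstrap_reri(
    strata: pd.DataFrame,
    series: pd.DataFrame,
    spec: ModelSpec | None = None,
    at_hi_c: float | None = None,
    at_ref_c: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    modifiers=MODIFIERS,
    max_failure_frac: float = 0.05,
) -> dict:
    """Cluster bootstrap (dates resampled, strata of a date move together)
    of the RERI for every modifier. Returns ``{modifier: ReriResult}``.
    """
    spec = spec or ModelSpec()
    daily_at = series["at2_c"].reindex(pd.DatetimeIndex(sorted(strata["date"].unique())))
    at_vals = daily_at.to_numpy(dtype=float)
    if at_ref_c is None:
        at_ref_c = float(np.percentile(at_vals, 50))
    if at_hi_c is None:
        at_hi_c = float(np.percentile(at_vals, 95))
    if spec.at_knot_c is None:
        spec = ModelSpec(**{**spec.__dict__, "at_knot_c": float(np.median(at_vals))})

    strata = strata.sort_values("date", kind="stable").reset_index(drop=True)
    X, knot = _interaction_design(strata, series, spec)
    y = strata["count"].to_numpy(dtype=float)
    fit = _fit_from_design(y, X, knot)
    point = {m: compute_reri(fit, m, at_hi_c, at_ref_c) for m in modifiers}

    # the design is a pure function of (date, stratum); build it once and
    # resample whole-date row blocks, so every resample reuses the same
    # basis and knot
    codes, dates = pd.factorize(strata["date"], sort=True)
    row_blocks = [np.flatnonzero(codes == i) for i in range(len(dates))]
    Xv = X.to_numpy()
    rng = np.random.default_rng(seed)
    draws = {m: [] for m in modifiers}
    failures = 0
    start = np.asarray(fit.result.params)
    if fit.family == "negative_binomial":
        start = start[:-1]
    cols = list(X.columns)
    for _ in range(n_boot):
        idx, _pick = resample_date_blocks(row_blocks, rng)
        try:
            # resamples inherit the point fit's family so a boundary flip
            # cannot mix estimators inside one interval
            if fit.family == "poisson":
                beta = _poisson_irls(y[idx], Xv[idx], start)
                coef = pd.Series(beta, index=cols)
            else:
                Xb = pd.DataFrame(Xv[idx], columns=cols)
                f = _fit_from_design(y[idx], Xb, knot, family=fit.family,
                                     start_params=start)
                coef = _coef_series(f)
            for m in modifiers:
                draws[m].append(_reri_from_coef(coef, knot, m, at_hi_c, at_ref_c))
        except (FitError, np.linalg.LinAlgError):
            failures += 1
    if failures > max_failure_frac * n_boot:
        raise FitError(f"{failures}/{n_boot} RERI bootstrap refits failed")
    for m in modifiers:
        point[m].ci = tuple(np.percentile(draws[m], [2.5, 97.5]))
        point[m].n_boot = n_boot
    return point
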