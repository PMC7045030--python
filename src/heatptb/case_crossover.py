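"""Time-stratified case-crossover sensitivity analysis.

The study calendar is partitioned into fixed strata (2-week or 3-week blocks
anchored at the first study date, or calendar months). Each case day is
compared with the other days of its stratum — by default only those falling
on the same weekday, which controls day-of-week patterns. A count-weighted
conditional logistic likelihood over the matched sets yields the odds ratio
for the same apparent-temperature hinge contrast as the time-series model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = ["ReferentSet", "build_referents", "fit_conditional_logistic", "CaseCrossoverFit"]

STRATUM_RULES = ("two_week", "three_week", "month")


@dataclass
class ReferentSet:
    case_date: pd.Timestamp
    referent_dates: list
    stratum_rule: str
    weekday_matched: bool


def _stratum_ids(dates: pd.DatetimeIndex, rule: str) -> np.ndarray:
    if rule == "two_week":
        return ((dates - dates.min()).days // 14).to_numpy()
    if rule == "three_week":
        return ((dates - dates.min()).days // 21).to_numpy()
    if rule == "month":
        return (dates.year * 12 + dates.month).to_numpy()
    raise ValueError(f"unknown stratum rule {rule!r}; choose from {STRATUM_RULES}")


def build_referents(
    case_dates,
    stratum_rule: str = "two_week",
    weekday_matched: bool = True,
    calendar=None,
):
    """Referent sets for each case day under a time-stratified design.

    Parameters
    ----------
    case_dates : iterable of dates
        Days with at least one case.
    calendar : iterable of dates, optional
        The full study calendar from which referents may be drawn; defaults
        to the case days themselves (appropriate when every study day is in
        the series).

    Returns
    -------
    sets : list of ReferentSet
        One per case day that has at least one eligible referent.
    n_dropped : int
        Case days dropped because their stratum offered no referent.
    """
    case_dates = pd.DatetimeIndex(sorted(pd.DatetimeIndex(case_dates).unique()))
    cal = case_dates if calendar is None else pd.DatetimeIndex(sorted(pd.DatetimeIndex(calendar).unique()))
    strata = _stratum_ids(cal, stratum_rule)
    frame = pd.DataFrame({"stratum": strata, "weekday": cal.dayofweek}, index=cal)

    sets, n_dropped = [], 0
    for d in case_dates:
        if d not in frame.index:
            n_dropped += 1
            continue
        row = frame.loc[d]
        pool = frame[frame["stratum"] == row["stratum"]]
        if weekday_matched:
            pool = pool[pool["weekday"] == row["weekday"]]
        referents = [r for r in pool.index if r != d]
        if not referents:
            n_dropped += 1
            continue
        sets.append(
            ReferentSet(
                case_date=d,
                referent_dates=referents,
                stratum_rule=stratum_rule,
                weekday_matched=weekday_matched,
            )
        )
    return sets, n_dropped


@dataclass
class CaseCrossoverFit:
    params: np.ndarray  # (b_lin, b_hinge)
    at_knot_c: float
    odds_ratio: float
    at_hi_c: float
    at_ref_c: float
    loglike: float
    converged: bool
    log_or_se: float = float("nan")  # delta-method SE of the contrast log-OR


def fit_conditional_logistic(
    referent_sets,
    exposure: pd.Series,
    counts: pd.Series,
    at_knot_c: float | None = None,
    at_hi_c: float | None = None,
    at_ref_c: float | None = None,
) -> CaseCrossoverFit:
    """Count-weighted conditional logistic fit over the matched sets.

    The linear predictor uses the same centred-linear + hinge apparent
    temperature parameterization as the time-series model. Each case day
    contributes its daily case count times the conditional log likelihood of
    its own day against its referent days. Raises ``RuntimeError`` on
    non-convergence (e.g. complete separation).

    Returns the odds ratio for ``at_hi_c`` versus ``at_ref_c`` (defaulting
    to the p95 and p50 of the exposure over the case days).
    """
    at = exposure.dropna()
    for s in referent_sets:
        if s.case_date not in at.index or any(d not in at.index for d in s.referent_dates):
            raise ValueError("exposure missing on a case or referent day")
    vals = np.array([at.loc[s.case_date] for s in referent_sets])
    if at_knot_c is None:
        at_knot_c = float(np.median(vals))
    if at_ref_c is None:
        at_ref_c = float(np.percentile(vals, 50))
    if at_hi_c is None:
        at_hi_c = float(np.percentile(vals, 95))

    def feats(a):
        a = np.asarray(a, dtype=float)
        return np.column_stack([a - at_knot_c, np.maximum(0.0, a - at_knot_c)])

    # pad sets (case day first) into a dense array for a vectorized
    # conditional likelihood; padded slots are masked out of the logsumexp
    kept = [s for s in referent_sets
            if s.case_date in counts.index and float(counts.loc[s.case_date]) > 0]
    if not kept:
        raise ValueError("no informative matched sets")
    width = 1 + max(len(s.referent_dates) for s in kept)
    n = len(kept)
    A = np.zeros((n, width))
    mask = np.zeros((n, width), dtype=bool)
    w = np.empty(n)
    for i, s in enumerate(kept):
        days = [s.case_date, *s.referent_dates]
        A[i, : len(days)] = at.loc[days].to_numpy()
        mask[i, : len(days)] = True
        w[i] = float(counts.loc[s.case_date])
    X = np.stack([A - at_knot_c, np.maximum(0.0, A - at_knot_c)], axis=-1)
    neg_inf = -np.inf

    def negloglike(beta):
        eta = X @ beta
        eta = np.where(mask, eta, neg_inf)
        lse = logsumexp(eta, axis=1)
        p = np.exp(eta - lse[:, None])
        nll = -np.sum(w * (eta[:, 0] - lse))
        grad = -np.einsum("i,ij->j", w, X[:, 0, :] - np.einsum("ik,ikj->ij", p, X))
        return nll, grad

    res = minimize(negloglike, np.zeros(2), jac=True, method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 500})
    if not res.success and res.status != 2:  # status 2: precision loss at optimum
        raise RuntimeError(f"conditional logistic fit failed: {res.message}")
    beta = res.x
    contrast = feats([at_hi_c])[0] - feats([at_ref_c])[0]

    # observed information at the optimum for a delta-method SE
    eta = np.where(mask, X @ beta, neg_inf)
    p = np.exp(eta - logsumexp(eta, axis=1)[:, None])
    xbar = np.einsum("ik,ikj->ij", p, X)
    xc = X - xbar[:, None, :]
    info = np.einsum("i,ik,ikj,ikl->jl", w, p, xc, xc)
    try:
        var = float(contrast @ np.linalg.solve(info, contrast))
        se = float(np.sqrt(max(var, 0.0)))
    except np.linalg.LinAlgError:
        se = float("nan")

    return CaseCrossoverFit(
        params=beta,
        at_knot_c=at_knot_c,
        odds_ratio=float(np.exp(contrast @ beta)),
        at_hi_c=at_hi_c,
        at_ref_c=at_ref_c,
        loglike=-res.fun,
        converged=True,
        log_or_se=se,
    )
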