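"""Trend detection: Mann-Kendall tests, trait regressions, loess turning point.

The Mann-Kendall statistic S counts concordant minus discordant pairs of a
series against time.  Kendall's Tau (tau-b, tie-corrected) measures the
strength of the monotone trend; significance uses the tie-corrected variance
with a continuity-corrected normal approximation, or the exact null
distribution for short tie-free series.

Crown-damage thresholds for growth decline are derived from the per-tree
Tau values: the damage at which the fitted Tau~damage regression crosses
zero, and the smallest damage among trees whose individual negative trend is
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chronology import Chronology

__all__ = [
    "TrendResult",
    "TraitTrendFit",
    "TrendError",
    "mann_kendall",
    "trait_trend_regression",
    "loess_trend",
    "damage_thresholds",
]


class TrendError(ValueError):
    pass


@dataclass
class TrendResult:
    tau: float
    p: float
    s: int
    n: int
    period: tuple[int, int]
    direction_significant: bool  # two-sided p < 0.05


@dataclass
class TraitTrendFit:
    trait: str
    slope: float
    intercept: float
    p: float
    r2: float
    zero_crossing: float | None  # trait value where fitted Tau = 0
    n: int
    underdetermined: bool = False


def mann_kendall(
    values,
    period: tuple[int, int] | None = None,
    first_year: int | None = None,
    *,
    alpha: float = 0.05,
) -> TrendResult:
    """Mann-Kendall trend test of annual values against time.

    ``values`` may be a Chronology (optionally restricted to ``period``) or a
    plain array (``first_year`` then labels the first entry; it defaults to
    index 0).  Tau is the tie-corrected tau-b; p is two-sided, exact for
    n <= 10 without ties, else from the continuity-corrected normal
    approximation with tie-corrected variance.
    """
    if isinstance(values, Chronology):
        chron = values
        if period is None:
            period = (chron.first_year, chron.last_year)
        x = chron.window(*period)
        fy = period[0]
    else:
        x = np.asarray(values, dtype=float)
        fy = first_year if first_year is not None else 0
        if period is not None:
            lo, hi = period
            if lo < fy or hi > fy + len(x) - 1:
                raise TrendError(f"period {period} outside series span")
            x = x[lo - fy : hi - fy + 1]
            fy = lo
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise TrendError("missing values in trend period")
    n = len(x)
    if n < 8:
        raise TrendError(f"Mann-Kendall needs n >= 8, got {n}")

    diffs = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diffs, k=1).sum())

    # tie groups in the data
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    d0 = n * (n - 1) // 2
    tie_term = np.sum(ties * (ties - 1)) / 2.0
    denom = np.sqrt(d0 * (d0 - tie_term))  # tau-b denominator (time has no ties)
    tau = s / denom if denom > 0 else 0.0

    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:  # constant series
        p = 1.0
    elif n <= 10 and ties.size == 0:
        # exact two-sided p from the null distribution of tau (no ties)
        p = float(stats.kendalltau(np.arange(n), x, method="exact").pvalue)
    else:
        z = (s - np.sign(s)) / np.sqrt(var_s)  # continuity correction
        p = float(2 * stats.norm.sf(abs(z)))
    period_out = period if period is not None else (fy, fy + n - 1)
    return TrendResult(
        tau=float(tau), p=p, s=s, n=n, period=period_out,
        direction_significant=bool(p < alpha),
    )


def trait_trend_regression(
    taus, trait, name: str = "trait", *, crossing_alpha: float = 0.1
) -> TraitTrendFit:
    """OLS of per-tree Kendall Tau on a tree trait.

    The zero crossing (-intercept / slope, the trait value where the fitted
    trend flips sign) is reported only when the slope differs from zero at
    the 0.1 level; otherwise it is withheld as uninformative.
    """
    y = np.asarray(taus, dtype=float)
    x = np.asarray(trait, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise TrendError("need >= 2 matched (tau, trait) pairs")
    if len(x) < 3:
        under = True
    else:
        under = False
    if np.std(x) == 0:
        raise TrendError(f"trait {name!r} has zero variance")
    res = stats.linregress(x, y)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    r2 = float(res.rvalue**2)
    zero = None
    if res.slope != 0 and (p < crossing_alpha or under and r2 == 1.0):
        zero = float(-res.intercept / res.slope)
    return TraitTrendFit(
        trait=name, slope=float(res.slope), intercept=float(res.intercept),
        p=p, r2=r2, zero_crossing=zero, n=len(x), underdetermined=under,
    )


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1 - np.abs(u) ** 3, 0, None) ** 3
    return w


def loess_smooth(y: np.ndarray, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Local polynomial (default quadratic) regression with tricube weights."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = np.arange(n, dtype=float)
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        w = _tricube(d[idx] / h) if h > 0 else np.ones(len(idx))
        X = np.vander(x[idx] - x[i], degree + 1, increasing=True)
        W = w[:, None]
        beta, *_ = np.linalg.lstsq(X * W, y[idx] * w, rcond=None)
        out[i] = beta[0]
    return out


def loess_trend(
    chron: Chronology | np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    *,
    first_year: int | None = None,
) -> tuple[np.ndarray, int | None]:
    """Loess smooth of a chronology and the year growth turned downward.

    The turning year is the year of the smooth's global maximum, reported
    only when the smooth ends below that maximum (i.e. there actually is a
    subsequent decline); monotone or flat smooths yield ``None``.
    """
    if isinstance(chron, Chronology):
        y = chron.values
        fy = chron.first_year
    else:
        y = np.asarray(chron, dtype=float)
        fy = first_year if first_year is not None else 0
    mask = np.isfinite(y)
    y = y[mask]
    fy = fy + int(np.argmax(mask))
    if len(y) < 20:
        raise TrendError("loess_trend needs >= 20 years")
    sm = loess_smooth(y, span=span, degree=degree)
    imax = int(np.argmax(sm))
    tol = 1e-9 * max(1.0, np.abs(sm).max())
    if sm[-1] < sm[imax] - tol and imax < len(sm) - 1:
        return sm, fy + imax
    return sm, None


def damage_thresholds(
    taus: dict[str, TrendResult], damage: dict[str, float]
) -> dict[str, float | None]:
    """Crown-damage thresholds for growth decline.

    * ``tau_zero_crossing`` — damage where the fitted Tau~damage line crosses
      zero (trend flips negative beyond it);
    * ``min_damage_significant_negative`` — smallest damage among trees with
      an individually significant negative trend.
    """
    trees = sorted(set(taus) & set(damage))
    fit = trait_trend_regression(
        [taus[t].tau for t in trees], [damage[t] for t in trees], name="damage"
    )
    sig_neg = [
        damage[t] for t in trees
        if taus[t].direction_significant and taus[t].tau < 0
    ]
    return {
        "tau_zero_crossing": fit.zero_crossing,
        "min_damage_significant_negative": min(sig_neg) if sig_neg else None,
        "regression_p": fit.p,
        "regression_r2": fit.r2,
        "slope": fit.slope,
    }
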