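"""Climate-growth sensitivity: bootstrapped monthly correlations and the
crown-damage dependence of seasonal sensitivity.

For each of the 19 monthly slots of the southern-hemisphere season window,
the annual chronology (mean-line standardized, so long-term trends are kept)
is correlated with that slot's regional climate departure over the analysis
period.  Significance comes from a paired bootstrap: years are resampled with
replacement and a slot is significant when the percentile 95 % interval of r
excludes zero.

Per-tree seasonal sensitivity is the arithmetic mean of the per-slot Pearson
r values over a slot subset (e.g. current-season DJF temperature).  Its
dependence on crown damage is modeled by a Gaussian generalized additive
model — a penalized B-spline smooth of damage (basis dimension 5, smoothing
parameter by generalized cross-validation) — summarized by the deviance
explained and an approximate F-test of the smooth term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

from .chronology import Chronology
from .climate import ClimateDeparture, SLOT_LABELS, season_window

__all__ = [
    "SensitivityResult",
    "DamageSensitivityFit",
    "SensitivityError",
    "monthly_correlations",
    "seasonal_sensitivity",
    "damage_sensitivity_fit",
    "DJF_SLOTS",
    "JFM_SLOTS",
]


class SensitivityError(ValueError):
    pass


#: current-season December-February slot indices in the 19-slot window
DJF_SLOTS: tuple[int, ...] = (
    SLOT_LABELS.index("cur.Dec"),
    SLOT_LABELS.index("cur.Jan"),
    SLOT_LABELS.index("cur.Feb"),
)
#: current-season January-March slot indices
JFM_SLOTS: tuple[int, ...] = (
    SLOT_LABELS.index("cur.Jan"),
    SLOT_LABELS.index("cur.Feb"),
    SLOT_LABELS.index("cur.Mar"),
)


@dataclass
class SensitivityResult:
    variable: str
    r: np.ndarray  # 19 per-slot Pearson correlations
    significant: np.ndarray  # 19 bootstrap flags at 0.05
    ci_low: np.ndarray
    ci_high: np.ndarray
    period: tuple[int, int]
    input_kind: str = "BAI"  # "RWL" | "BAI"
    standardization: str = "mean_line"
    slot_labels: tuple[str, ...] = tuple(SLOT_LABELS)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slot": list(self.slot_labels),
                "r": self.r,
                "significant": self.significant,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass
class DamageSensitivityFit:
    aggregate: str  # e.g. "DJF temperature"
    deviance_explained: float
    p_smooth: float
    edf: float
    damage_grid: np.ndarray
    fitted: np.ndarray
    alpha: float


def _slot_matrix(
    climate: ClimateDeparture, years: np.ndarray
) -> np.ndarray:
    """19 x n_years matrix of slot departures for the given growth years."""
    lookup = dict(zip(climate.values.index, climate.values.to_numpy()))
    out = np.full((19, len(years)), np.nan)
    for k, y in enumerate(years):
        for s, (yy, mm) in enumerate(season_window(int(y)).calendar()):
            out[s, k] = lookup.get((yy, mm), np.nan)
    return out


def monthly_correlations(
    chron: Chronology,
    climate: ClimateDeparture,
    period: tuple[int, int],
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    alpha: float = 0.05,
    min_overlap: int = 30,
    input_kind: str = "BAI",
) -> SensitivityResult:
    """Bootstrapped Pearson correlations of a chronology with the 19 slots."""
    if seed is None:
        raise SensitivityError("a bootstrap seed is required for reproducibility")
    start, end = period
    start = max(start, chron.first_year)
    end = min(end, chron.last_year)
    years = np.arange(start, end + 1)
    g = chron.window(start, end)
    slots = _slot_matrix(climate, years)
    valid = np.isfinite(g) & np.all(np.isfinite(slots), axis=0)
    years, g, slots = years[valid], g[valid], slots[:, valid]
    n = len(years)
    if n < min_overlap:
        raise SensitivityError(
            f"only {n} overlapping years in {period} (< {min_overlap})"
        )
    r = _pearson_rows(slots, g)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.empty((n_boot, 19))
    for b in range(n_boot):
        take = idx[b]
        boot[b] = _pearson_rows(slots[:, take], g[take])
    lo = np.nanpercentile(boot, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(boot, 100 * (1 - alpha / 2), axis=0)
    sig = (lo > 0) | (hi < 0)
    return SensitivityResult(
        variable=climate.variable,
        r=r, significant=sig, ci_low=lo, ci_high=hi,
        period=(int(years[0]), int(years[-1])), input_kind=input_kind,
    )


def _pearson_rows(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``rows`` against ``y`` (vectorized)."""
    yc = y - y.mean()
    rc = rows - rows.mean(axis=1, keepdims=True)
    num = rc @ yc
    den = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return out


def seasonal_sensitivity(
    tree_series: Chronology,
    climate: ClimateDeparture,
    slots: tuple[int, ...],
    period: tuple[int, int],
    *,
    min_overlap: int = 30,
) -> float:
    """Mean per-slot Pearson r of one tree's standardized series.

    Averages the correlation coefficients of the selected monthly slots (not
    the correlation with the seasonal mean).
    """
    start, end = period
    start = max(start, tree_series.first_year)
    end = min(end, tree_series.last_year)
    years = np.arange(start, end + 1)
    g = tree_series.window(start, end)
    mat = _slot_matrix(climate, years)[list(slots)]
    valid = np.isfinite(g) & np.all(np.isfinite(mat), axis=0)
    if valid.sum() < min_overlap:
        raise SensitivityError(
            f"only {int(valid.sum())} overlapping years (< {min_overlap})"
        )
    rs = _pearson_rows(mat[:, valid], g[valid])
    return float(np.mean(rs))


def damage_sensitivity_fit(
    per_tree_r,
    damage,
    aggregate: str = "DJF temperature",
    *,
    df: int = 5,
    n_grid: int = 101,
) -> DamageSensitivityFit:
    """Penalized-spline Gaussian GAM of seasonal sensitivity on crown damage.

    Basis dimension ``df`` B-splines; the penalty weight is chosen by
    generalized cross-validation.  Deviance explained is
    1 - residual/null deviance; the smooth term's p comes from an approximate
    F-test on its effective degrees of freedom.
    """
    y = np.asarray(per_tree_r, dtype=float)
    x = np.asarray(damage, dtype=float)
    if len(x) != len(y):
        raise SensitivityError("per_tree_r and damage lengths differ")
    if len(x) < 10:
        raise SensitivityError(f"need >= 10 trees, got {len(x)}")
    if np.std(x) == 0:
        raise SensitivityError("crown damage has zero variance")
    n = len(y)
    if np.std(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        grid = np.linspace(x.min(), x.max(), n_grid)
        return DamageSensitivityFit(
            aggregate=aggregate, deviance_explained=0.0, p_smooth=1.0,
            edf=1.0, damage_grid=grid, fitted=np.full(n_grid, y[0]),
            alpha=float("inf"),
        )
    bs = BSplines(x[:, None], df=[df], degree=[3], include_intercept=False)
    exog = np.ones((n, 1))
    model = GLMGam(y, exog, smoother=bs)
    model.fit()  # initializes scale attributes needed by the GCV search
    # Nelder-Mead keeps the search deterministic (basinhopping draws from
    # the global RNG)
    alpha, _, _ = model.select_penweight(criterion="gcv", method="nm",
                                         disp=0)
    res = GLMGam(y, exog, smoother=bs, alpha=alpha).fit()
    edf = float(np.sum(res.edf))
    dev_expl = float(1.0 - res.deviance / res.null_deviance)
    # Significance of the damage term: exact F-test of the unpenalized
    # spline basis (k columns) against the intercept-only model.  A test on
    # the GCV-selected effective df would be anticonservative because the
    # smoothness was chosen from the same data.
    X = np.column_stack([np.ones(n), bs.basis])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    df1_exact = rank - 1
    df2_exact = n - rank
    if rss <= 0 or df2_exact <= 0:
        p = 0.0 if tss > rss else 1.0
    elif tss <= rss:
        p = 1.0
    else:
        F = ((tss - rss) / df1_exact) / (rss / df2_exact)
        p = float(stats.f.sf(F, df1_exact, df2_exact))
    grid = np.linspace(x.min(), x.max(), n_grid)
    basis_grid = bs.transform(grid[:, None])
    fitted = res.params[0] + basis_grid @ res.params[1:]
    return DamageSensitivityFit(
        aggregate=aggregate, deviance_explained=dev_expl, p_smooth=p,
        edf=edf, damage_grid=grid, fitted=np.asarray(fitted),
        alpha=float(np.atleast_1d(alpha)[0]),
    )
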