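"""Cross-dating statistics, detrending, robust-mean chronologies, EPS/Rbar.

A chronology is the per-year Tukey-biweight robust mean of many standardized
ring series.  Signal strength is summarized by the mean inter-series
correlation (Rbar) and the Expressed Population Signal,

    EPS = n * rbar / (n * rbar + 1 - rbar),

with 0.85 the conventional adequacy threshold.

Two detrending families are provided, both with ratio standardization
(index = value / fit):

* ``spline32`` — a cubic smoothing spline whose frequency response is 0.5 at
  a 32-year wavelength (the standard dendro "50 % frequency cut-off"
  parameterization; for unit-spaced years the penalty weight is
  ``(32 / 2 pi) ** 4``);
* ``mean_line`` — a horizontal line at the series mean, which preserves
  low-frequency trends in the index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.stats import pearsonr

from .growth import BAISeries
from .ringio import RingSeries

__all__ = [
    "Chronology",
    "ChronologyStats",
    "ChronologyError",
    "normalize_p2yrsl",
    "crossdate_stats",
    "detrend",
    "spline32_fit",
    "biweight_mean",
    "eps_from_rbar",
    "rbar_and_eps",
    "build_chronology",
    "IndexSeries",
]

T_SENTINEL = 1e6  # reported t when r is numerically 1


class ChronologyError(ValueError):
    pass


@dataclass
class IndexSeries:
    """A dated dimensionless (or BAI) index series used to build chronologies."""

    series_id: str
    first_year: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Chronology:
    """Per-year robust mean with sample depth.

    ``first_reliable_year`` is the first year with sample depth >= the
    configured minimum (conventionally 5 trees).
    """

    first_year: int
    values: np.ndarray
    sample_depth: np.ndarray
    first_reliable_year: int | None = None

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def window(self, start: int, end: int) -> np.ndarray:
        """Values on the inclusive [start, end] year window."""
        if start < self.first_year or end > self.last_year:
            raise ChronologyError(
                f"window {start}-{end} outside chronology span "
                f"{self.first_year}-{self.last_year}"
            )
        return self.values[start - self.first_year : end - self.first_year + 1]


@dataclass
class ChronologyStats:
    eps: float
    rbar: float
    n_trees: float
    period: tuple[int, int]
    n_pairs: int = 0


# ---------------------------------------------------------------------------
# Cross-dating
# ---------------------------------------------------------------------------

def normalize_p2yrsl(series: RingSeries) -> IndexSeries:
    """Proportion-of-last-two-years, log-transformed: ln(2 w_t / (w_t + w_{t-1})).

    Removes level and trend so that series can be compared for cross-dating.
    The first year is dropped; zero widths are rejected (log undefined).
    """
    w = series.widths
    if len(w) < 2:
        raise ChronologyError("P2YrsL needs >= 2 years")
    if np.any(w <= 0):
        raise ChronologyError(
            f"series {series.series_id!r}: zero/negative width; P2YrsL undefined"
        )
    p = np.log(2.0 * w[1:] / (w[1:] + w[:-1]))
    return IndexSeries(series_id=series.series_id,
                       first_year=series.first_year + 1, values=p)


def crossdate_stats(
    series: IndexSeries,
    master: IndexSeries,
    *,
    r_threshold: float = 0.32,
    t_threshold: float = 3.5,
    min_overlap: int = 10,
) -> tuple[float, float, bool]:
    """Correlation-based dating validation of a series against a master.

    Returns (r, t, pass) where r is the Pearson correlation on the common
    years, t = r * sqrt((n - 2) / (1 - r^2)), and the series passes when
    r > 0.32 and t > 3.5 (both strict).
    """
    start = max(series.first_year, master.first_year)
    end = min(series.last_year, master.last_year)
    n = end - start + 1
    if n < min_overlap:
        raise ChronologyError(
            f"overlap {n} < {min_overlap} years between series and master"
        )
    a = series.values[start - series.first_year : end - series.first_year + 1]
    b = master.values[start - master.first_year : end - master.first_year + 1]
    r = float(np.corrcoef(a, b)[0, 1])
    if 1 - r * r < 1e-12:
        t = T_SENTINEL if r > 0 else -T_SENTINEL
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
    ok = (r > r_threshold) and (t > t_threshold)
    return r, float(t), bool(ok)


# ---------------------------------------------------------------------------
# Detrending / standardization
# ---------------------------------------------------------------------------

def spline32_fit(values: np.ndarray, nyrs: float = 32.0) -> np.ndarray:
    """Fitted values of the 50 %-cutoff smoothing spline (unit-spaced years)."""
    x = np.arange(len(values), dtype=float)
    lam = (nyrs / (2.0 * np.pi)) ** 4
    return np.asarray(make_smoothing_spline(x, np.asarray(values, float),
                                            lam=lam)(x))


def detrend(
    series: RingSeries | BAISeries | IndexSeries,
    method: str = "spline32",
    *,
    nyrs: float = 32.0,
) -> IndexSeries:
    """Ratio-standardize a series by a fitted growth curve.

    ``spline32`` divides by the 32-year 50 %-cutoff smoothing spline (removes
    age/size trends and slow disturbances); ``mean_line`` divides by the
    series mean (keeps all low-frequency variation — used where long-term
    climate trends are the signal of interest).
    """
    values = series.widths if isinstance(series, RingSeries) else (
        series.bai if isinstance(series, BAISeries) else series.values
    )
    sid = getattr(series, "series_id", None) or getattr(series, "tree_id", "?")
    values = np.asarray(values, dtype=float)
    if method == "mean_line":
        fit = np.full_like(values, values.mean())
        if fit[0] <= 0:
            raise ChronologyError(f"series {sid!r}: non-positive mean")
    elif method == "spline32":
        if len(values) < 5:
            raise ChronologyError("spline32 needs >= 5 years")
        fit = spline32_fit(values, nyrs=nyrs)
        bad = np.nonzero(fit <= 0)[0]
        if bad.size:
            year = series.first_year + int(bad[0])
            raise ChronologyError(
                f"series {sid!r}: non-positive spline fit in year {year}"
            )
    else:
        raise ChronologyError(f"unknown detrending method {method!r}")
    return IndexSeries(series_id=str(sid), first_year=series.first_year,
                       values=values / fit)


# ---------------------------------------------------------------------------
# Robust mean and signal strength
# ---------------------------------------------------------------------------

def biweight_mean(values, c: float = 9.0, n_iter: int = 10) -> float:
    """Tukey's biweight robust location estimate.

    Weights (1 - u^2)^2 with u = (x - m) / (c * MAD); the location is iterated
    from the median.  When the MAD is zero (e.g. a majority of identical
    values) the median is returned.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ChronologyError("biweight_mean of empty set")
    if x.size == 1:
        return float(x[0])
    m = float(np.median(x))
    mad = float(np.median(np.abs(x - m)))
    if mad == 0:
        return m
    for _ in range(n_iter):
        u = (x - m) / (c * mad)
        w = (1 - u * u) ** 2
        w[np.abs(u) >= 1] = 0.0
        if w.sum() == 0:
            return m
        m = float(np.sum(w * x) / w.sum())
    return m


def eps_from_rbar(n: float, rbar: float) -> float:
    """Expressed Population Signal from sample size and mean inter-series r."""
    return n * rbar / (n * rbar + 1.0 - rbar)


def rbar_and_eps(
    indexed: list[IndexSeries],
    period: tuple[int, int],
    *,
    min_overlap: int = 30,
) -> ChronologyStats:
    """Mean pairwise inter-series correlation and EPS over a period.

    Rbar is the pairwise-complete estimator: each pair of series contributes
    the Pearson correlation over its common years within the period, provided
    the overlap is at least ``min_overlap`` years.  EPS uses the mean sample
    depth over the period as n.
    """
    if len(indexed) < 2:
        raise ChronologyError("rbar_and_eps needs >= 2 series")
    start, end = period
    cors = []
    for i in range(len(indexed)):
        for j in range(i + 1, len(indexed)):
            a, b = indexed[i], indexed[j]
            s = max(a.first_year, b.first_year, start)
            e = min(a.last_year, b.last_year, end)
            n = e - s + 1
            if n < min_overlap:
                continue
            va = a.values[s - a.first_year : e - a.first_year + 1]
            vb = b.values[s - b.first_year : e - b.first_year + 1]
            if va.std() == 0 or vb.std() == 0:
                continue
            cors.append(pearsonr(va, vb)[0])
    if not cors:
        raise ChronologyError(
            f"no series pair overlaps >= {min_overlap} years in {period}"
        )
    rbar = float(np.mean(cors))
    depth = np.zeros(end - start + 1)
    for s_ in indexed:
        lo = max(s_.first_year, start)
        hi = min(s_.last_year, end)
        if hi >= lo:
            depth[lo - start : hi - start + 1] += 1
    n_mean = float(depth[depth > 0].mean())
    return ChronologyStats(
        eps=eps_from_rbar(n_mean, rbar),
        rbar=rbar,
        n_trees=n_mean,
        period=period,
        n_pairs=len(cors),
    )


def build_chronology(
    indexed: list[IndexSeries], *, min_depth: int = 5
) -> Chronology:
    """Per-year Tukey-biweight mean over the available index series."""
    if not indexed:
        raise ChronologyError("build_chronology: no series")
    first = min(s.first_year for s in indexed)
    last = max(s.last_year for s in indexed)
    n_years = last - first + 1
    values = np.full(n_years, np.nan)
    depth = np.zeros(n_years, dtype=int)
    for k in range(n_years):
        year = first + k
        vals = [
            s.values[year - s.first_year]
            for s in indexed
            if s.first_year <= year <= s.last_year
        ]
        if vals:
            values[k] = biweight_mean(vals)
            depth[k] = len(vals)
    reliable = np.nonzero(depth >= min_depth)[0]
    first_reliable = int(first + reliable[0]) if reliable.size else None
    return Chronology(first_year=first, values=values, sample_depth=depth,
                      first_reliable_year=first_reliable)
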