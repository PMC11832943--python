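"""Growth geometry: basal area increment, competition, simple growth summaries.

Basal area increment (BAI) is reconstructed backwards from the diameter at
breast height: the outermost ring's radius is anchored at dbh/2 and each ring
width is subtracted going inward,

    BAI_t = pi * (r_t**2 - r_{t-1}**2).

Local competition is quantified with the Hegyi index, the distance-weighted
sum of neighbor-to-target diameter ratios over the five nearest neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ringio import RingSeries, TreeRecord

__all__ = [
    "BAISeries",
    "GrowthError",
    "bai_from_dbh",
    "hegyi_index",
    "series_summaries",
    "recent_growth_stats",
]


class GrowthError(ValueError):
    pass


@dataclass
class BAISeries:
    """Annual basal area increments (mm^2 / yr) for one tree."""

    tree_id: str
    first_year: int
    bai: np.ndarray

    def __post_init__(self) -> None:
        self.bai = np.asarray(self.bai, dtype=float)
        if np.any(self.bai < -1e-9):
            raise GrowthError(f"tree {self.tree_id!r}: negative BAI")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.bai) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.bai)


def bai_from_dbh(
    rings: RingSeries,
    dbh: float,
    *,
    tolerance: float = 0.25,
    rescale: bool = False,
) -> BAISeries:
    """Reconstruct BAI backwards from dbh through the ring-width series.

    The last (most recent) ring's outer radius is anchored at ``dbh / 2`` (no
    bark correction).  Going inward, each previous radius is the current one
    minus the ring width.  Any residual radius inside the innermost measured
    ring (cores rarely reach the pith) serves as that ring's inner radius but
    produces no BAI record of its own.

    Parameters
    ----------
    rings
        Dated widths in mm, oldest first.
    dbh
        Diameter at breast height in mm; must be > 0.
    tolerance
        Allowed relative excess of the cumulative width sum over ``dbh / 2``
        before an error is raised (cores can overshoot the geometric radius
        when DBH underestimates the coring path).
    rescale
        If True, widths are first rescaled proportionally so that their sum
        equals ``dbh / 2`` exactly.
    """
    if dbh <= 0:
        raise GrowthError("dbh must be > 0")
    widths = rings.widths.astype(float)
    radius = dbh / 2.0
    total = widths.sum()
    if rescale:
        if total <= 0:
            raise GrowthError("cannot rescale an all-zero series")
        widths = widths * (radius / total)
        total = radius
    if total > radius * (1 + tolerance):
        raise GrowthError(
            f"tree {rings.tree_id!r}: cumulative ring widths {total:.1f} mm "
            f"exceed dbh/2 = {radius:.1f} mm by more than {tolerance:.0%} "
            f"(excess {total - radius:.1f} mm)"
        )
    # outer radius after each ring, proceeding outward from the residual core
    inner0 = max(radius - total, 0.0)
    if total > radius:  # within tolerance: clamp the anchor to the width sum
        inner0 = 0.0
        radius = total
    r = inner0 + np.cumsum(widths)
    r_prev = np.concatenate([[inner0], r[:-1]])
    bai = np.pi * (r**2 - r_prev**2)
    return BAISeries(tree_id=rings.tree_id, first_year=rings.first_year, bai=bai)


def hegyi_index(target: TreeRecord, n_neighbors: int = 5) -> float:
    """Hegyi competition index over the ``n_neighbors`` nearest neighbors.

    CI_i = sum_j (dbh_j / dbh_i) / dist_ij, with dbh in common units and
    distances in m.
    """
    if target.dbh <= 0:
        raise GrowthError("target dbh must be > 0")
    if not target.neighbors:
        raise GrowthError(f"tree {target.tree_id!r}: no neighbors recorded")
    neigh = sorted(target.neighbors, key=lambda t: t[1])[:n_neighbors]
    ci = 0.0
    for dbh_j, dist in neigh:
        if dist <= 0:
            raise GrowthError("neighbor distance must be > 0")
        ci += (dbh_j / target.dbh) / dist
    return ci


def series_summaries(rings: RingSeries) -> tuple[int, float]:
    """Minimum age (ring count at coring height) and mean ring width (mm)."""
    if len(rings) == 0:
        raise GrowthError("empty series")
    return len(rings), float(rings.widths.mean())


def recent_growth_stats(
    bai: BAISeries, window: tuple[int, int]
) -> tuple[float, float]:
    """Mean and coefficient of variation of BAI over an inclusive year window.

    CV = sample standard deviation (ddof=1) / mean; NaN (flagged) when the
    window mean is zero.
    """
    start, end = window
    if start < bai.first_year or end > bai.last_year or end < start:
        raise GrowthError(
            f"window {window} outside series span "
            f"({bai.first_year}-{bai.last_year})"
        )
    seg = bai.bai[start - bai.first_year : end - bai.first_year + 1]
    mean = float(seg.mean())
    if mean == 0:
        return mean, float("nan")
    sd = float(seg.std(ddof=1)) if len(seg) > 1 else 0.0
    return mean, sd / mean
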