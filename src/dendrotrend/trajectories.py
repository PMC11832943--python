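"""Divergent growth trajectories: PCA growth modes and group assignment.

The BAI matrix (years as observations, trees as variables) is analyzed by
principal components on the correlation scale: each tree's series is
standardized before the eigen-decomposition, because BAI levels differ widely
among trees.  Each tree is then assigned to the retained component whose
score series its own BAI correlates with most strongly (in magnitude;
component signs are arbitrary), which splits the stand into groups that share
a long-term growth trajectory.  Group trait differences are tested with a
Welch t-test for DBH and Mann-Whitney rank-sum tests for the other traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthModes",
    "GroupAssignment",
    "TrajectoryError",
    "pca_growth_modes",
    "assign_to_mode",
    "compare_groups",
]


class TrajectoryError(ValueError):
    pass


@dataclass
class GrowthModes:
    """Retained principal components of the standardized BAI matrix."""

    period: tuple[int, int]
    sdevs: np.ndarray  # per-component standard deviations
    var_explained: np.ndarray  # fractions of total variance
    scores: pd.DataFrame  # years x components ("PC1", ...)
    loadings: pd.DataFrame  # trees x components


@dataclass
class GroupAssignment:
    labels: dict[str, str]  # tree_id -> "PC1" | "PC2" | ...
    correlations: pd.DataFrame  # trees x components, Pearson r with scores
    ties: list[str] = field(default_factory=list)


def _matrix_window(bai_matrix: pd.DataFrame, period: tuple[int, int]) -> pd.DataFrame:
    start, end = period
    sub = bai_matrix.loc[(bai_matrix.index >= start) & (bai_matrix.index <= end)]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise TrajectoryError(
            f"missing BAI cells within {period} for trees {bad}"
        )
    missing_years = sorted(set(range(start, end + 1)) - set(sub.index))
    if missing_years:
        raise TrajectoryError(f"years absent from BAI matrix: {missing_years}")
    return sub


def pca_growth_modes(
    bai_matrix: pd.DataFrame, period: tuple[int, int], k: int = 2
) -> GrowthModes:
    """PCA of the years x trees BAI matrix over the common period.

    Columns (trees) are standardized to zero mean and unit variance, so the
    decomposition is of the inter-tree correlation matrix.  Component signs
    are fixed so the mean loading is positive.  ``sdevs`` are the component
    standard deviations on that scale (sum of squares = number of trees) and
    ``var_explained`` their fractions of total variance.
    """
    sub = _matrix_window(bai_matrix, period)
    n_years, n_trees = sub.shape
    if n_trees < k:
        raise TrajectoryError(f"need >= {k} trees, got {n_trees}")
    X = sub.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    sdevs_all = s / np.sqrt(n_years - 1)
    var_all = sdevs_all**2 / np.sum(sdevs_all**2)
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    # sign convention: mean loading positive
    for i in range(k):
        if loadings[:, i].mean() < 0:
            loadings[:, i] *= -1
            scores[:, i] *= -1
    return GrowthModes(
        period=period,
        sdevs=sdevs_all[:k],
        var_explained=var_all[:k],
        scores=pd.DataFrame(scores, index=sub.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=sub.columns, columns=comp),
    )


def assign_to_mode(
    bai_matrix: pd.DataFrame, modes: GrowthModes
) -> GroupAssignment:
    """Assign each tree to the component its BAI correlates with most.

    Correlations are between the tree's BAI over the PCA period and each
    retained component's score series; the argmax is over |r| so that the
    arbitrary component sign cannot change assignments.  Exact ties break
    toward the lower component index and are flagged.
    """
    if modes.scores.shape[1] < 2:
        raise TrajectoryError("need >= 2 retained components")
    sub = _matrix_window(bai_matrix, modes.period)
    comp = list(modes.scores.columns)
    rows = {}
    labels = {}
    ties = []
    for tree in sub.columns:
        y = sub[tree].to_numpy(dtype=float)
        rs = [float(np.corrcoef(y, modes.scores[c])[0, 1]) for c in comp]
        rows[tree] = rs
        mags = np.abs(rs)
        best = int(np.argmax(mags))
        if np.sum(np.isclose(mags, mags[best])) > 1:
            ties.append(str(tree))
        labels[str(tree)] = comp[best]
    return GroupAssignment(
        labels=labels,
        correlations=pd.DataFrame.from_dict(rows, orient="index", columns=comp),
        ties=ties,
    )


#: which test each trait gets: Welch t for DBH, rank-sum otherwise
_WELCH_TRAITS = {"dbh"}


def compare_groups(
    traits: pd.DataFrame, labels: dict[str, str], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-trait two-group tests between trajectory groups.

    ``traits`` is indexed by tree_id with one column per trait (dbh, height,
    min_age, damage, hegyi, mean_rwl ...).  Returns a frame with the test
    name, statistic, two-sided p and significance flag per trait.
    """
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise TrajectoryError(f"expected exactly 2 groups, got {groups}")
    g1 = [t for t, g in labels.items() if g == groups[0]]
    g2 = [t for t, g in labels.items() if g == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise TrajectoryError("each group needs >= 2 trees")
    out = []
    for trait in traits.columns:
        a = traits.loc[traits.index.isin(g1), trait].dropna().to_numpy(float)
        b = traits.loc[traits.index.isin(g2), trait].dropna().to_numpy(float)
        if trait in _WELCH_TRAITS:
            res = stats.ttest_ind(a, b, equal_var=False)
            test = "welch_t"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann_whitney"
        p = float(res.pvalue)
        if not np.isfinite(p):  # degenerate zero-variance input
            p = 1.0
        out.append(
            {
                "trait": trait,
                "test": test,
                "statistic": float(res.statistic),
                "p": p,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(out).set_index("trait")
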