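"""Post-search proteomic comparison.

Global-mean normalization, pairwise differential abundance (Welch t on log₂
abundances), joint fold-change/p candidate gating, a barycentric triangular
projection summarising three pairwise contrasts, and per-protein Z-scores.

The triangle projection places each protein at the convex combination of the
three group vertices weighted by its normalized group-mean abundances
``w_g = m_g / Σ m_h``: a protein with equal levels in all groups sits at the
centroid, and raising one group's level moves the point strictly toward that
group's vertex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "ComparisonResult",
    "TriplotPoint",
    "normalize_global_mean",
    "pairwise_compare",
    "select_candidates",
    "triplot_coordinates",
    "triangle_vertices",
    "zscore_matrix",
    "plot_triplot",
]

DEFAULT_FC_MIN = 1.5
DEFAULT_P_MAX = 0.05


@dataclass
class AbundanceTable:
    """Linear-scale protein abundances (proteins × samples) with group labels.

    Missing values are explicit NaN.  ``group_of`` maps every sample id to
    its group label.
    """

    values: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.group_of)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("protein and sample ids must be unique")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def group_means(self, groups: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {g: self.values[self.samples_in(g)].mean(axis=1) for g in groups}
        )

    @classmethod
    def from_csv(cls, abundance_path, groups_path) -> "AbundanceTable":
        """Read abundance matrix (first column = protein id) and sample→group CSV."""
        values = pd.read_csv(abundance_path, index_col=0)
        groups = pd.read_csv(groups_path)
        group_of = dict(zip(groups.iloc[:, 0].astype(str), groups.iloc[:, 1].astype(str)))
        return cls(values, group_of)

    def to_csv(self, abundance_path, groups_path=None) -> None:
        self.values.to_csv(abundance_path)
        if groups_path is not None:
            pd.DataFrame(
                {"sample": self.sample_ids, "group": [self.group_of[s] for s in self.sample_ids]}
            ).to_csv(groups_path, index=False)


@dataclass
class ComparisonResult:
    """Differential abundance of one protein in one pairwise contrast."""

    protein_id: str
    log2_ratio: float
    fold_change: float  # 2^|log2_ratio|, two-sided
    p_value: float
    significant: bool = False


@dataclass
class TriplotPoint:
    """Barycentric summary of one protein across three groups."""

    protein_id: str
    weights: tuple[float, float, float]
    xy: tuple[float, float]


def normalize_global_mean(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample so all sample means equal the grand mean.

    The grand mean is the average of per-sample means (over non-missing
    values); a sample with no observed values is an error.
    """
    means = table.values.mean(axis=0, skipna=True)
    if means.isna().any():
        bad = list(means.index[means.isna()])
        raise ValueError(f"samples with all-missing values: {bad}")
    grand = means.mean()
    scaled = table.values * (grand / means)
    return AbundanceTable(scaled, dict(table.group_of))


def _welch_log2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t p-values on log₂ values, rows = proteins."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        # zero-variance rows trip scipy's precision warning; they are
        # resolved explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # identical-values degenerate case: zero variance in both groups
    var0 = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    same = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[var0 & same] = 1.0
    p[var0 & ~same] = 0.0
    return p


def pairwise_compare(
    table: AbundanceTable, group_a: str, group_b: str
) -> list[ComparisonResult]:
    """Per-protein log₂ ratio of group means (a over b) and Welch-t p-value.

    The t-test runs on log₂-transformed abundances.  Proteins with a
    non-positive or missing group mean are excluded with a logged reason.
    """
    sa, sb = table.samples_in(group_a), table.samples_in(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both groups need at least 2 replicates")
    A = table.values[sa].to_numpy(float)
    B = table.values[sb].to_numpy(float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    ok = (
        np.isfinite(mean_a) & np.isfinite(mean_b)
        & (mean_a > 0) & (mean_b > 0)
        & (A > 0).all(axis=1) & (B > 0).all(axis=1)
    )
    excluded = np.flatnonzero(~ok)
    if excluded.size:
        logger.info(
            "%s vs %s: excluded %d proteins with missing/non-positive abundance",
            group_a, group_b, excluded.size,
        )
    pvals = np.ones(len(table.values))
    pvals[ok] = _welch_log2(np.log2(A[ok]), np.log2(B[ok]))
    results = []
    ids = table.protein_ids
    for i in np.flatnonzero(ok):
        lr = float(np.log2(mean_a[i] / mean_b[i]))
        results.append(
            ComparisonResult(
                protein_id=ids[i],
                log2_ratio=lr,
                fold_change=float(2.0 ** abs(lr)),
                p_value=float(pvals[i]),
            )
        )
    return results


def select_candidates(
    results: list[ComparisonResult],
    fc_min: float = DEFAULT_FC_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> dict[str, list[ComparisonResult]]:
    """Joint gate: fold change ≥ ``fc_min`` (two-sided) and p ≤ ``p_max``.

    Returns candidates partitioned into ``"increased"`` (ratio ≥ fc_min) and
    ``"decreased"`` (ratio ≤ 1/fc_min); every returned result has its
    ``significant`` flag set.
    """
    increased, decreased = [], []
    for r in results:
        r.significant = r.fold_change >= fc_min and r.p_value <= p_max
        if not r.significant:
            continue
        (increased if r.log2_ratio > 0 else decreased).append(r)
    return {"increased": increased, "decreased": decreased}


def triangle_vertices() -> np.ndarray:
    """Vertices of the unit-side equilateral triangle, one per group."""
    return np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])


def triplot_coordinates(
    table: AbundanceTable, groups: tuple[str, str, str]
) -> list[TriplotPoint]:
    """Barycentric triangle coordinates for three compared groups.

    Weights are the normalized group-mean abundances; proteins whose group
    means are all zero/missing are excluded with a logged reason.
    """
    if len(set(groups)) != 3:
        raise ValueError("three distinct group labels required")
    means = table.group_means(list(groups)).to_numpy(float)
    verts = triangle_vertices()
    points = []
    n_excluded = 0
    for pid, m in zip(table.protein_ids, means):
        if not np.all(np.isfinite(m)) or m.sum() <= 0 or np.any(m < 0):
            n_excluded += 1
            continue
        w = m / m.sum()
        xy = w @ verts
        points.append(TriplotPoint(pid, tuple(w), (float(xy[0]), float(xy[1]))))
    if n_excluded:
        logger.info("triplot: excluded %d proteins with no usable group means", n_excluded)
    return points


def zscore_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Per-protein Z-scores across samples (sample SD, n−1 denominator).

    Zero-variance rows come back all-zero with a logged note.
    """
    v = table.values
    mu = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.info("zscore_matrix: %d zero-variance rows emitted as zeros", int(flat.sum()))
    sd = sd.replace(0.0, np.nan)
    z = v.sub(mu, axis=0).div(sd, axis=0)
    z.loc[flat.to_numpy()] = 0.0
    return z


def plot_triplot(
    points: list[TriplotPoint],
    groups: tuple[str, str, str],
    highlight: dict[str, str] | None = None,
    ax=None,
):
    """Scatter the triangle projection; ``highlight`` maps protein id to color."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    verts = triangle_vertices()
    tri = np.vstack([verts, verts[:1]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    for (x, y), g in zip(verts, groups):
        ax.annotate(g, (x, y), textcoords="offset points", xytext=(0, 6), ha="center")
    xy = np.array([p.xy for p in points])
    if len(xy):
        colors = [
            (highlight or {}).get(p.protein_id, "0.6") for p in points
        ]
        ax.scatter(xy[:, 0], xy[:, 1], s=8, c=colors, alpha=0.7, linewidths=0)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
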