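"""Strain-pair similarity, variance partitioning and clustering.

Strain similarity is the Pearson correlation between two strains' profiles
over traits (pairwise-complete, after scaling each trait to unit variance
across strains). A grouping factor — species, population or source
habitat — labels each unordered pair *within* (same level) or *between*
(different levels); a one-way ANOVA of the pair correlations on that
two-level label quantifies, via the adjusted R-squared, how much of the
variation in strain-pair similarity the factor explains. Pairs sharing a
strain are not independent; following common practice for this design the
ANOVA ignores that dependence, so its p-values are anti-conservative (a
caveat carried in the result object).

Clustering is average-linkage (UPGMA) agglomeration on the distance
``1 - r`` with the centered Pearson correlation, missing values handled
pairwise-complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "scale_traits",
    "pairwise_similarity",
    "count_pairs",
    "label_pairs",
    "partition",
    "VariancePartitionResult",
    "Dendrogram",
    "upgma_cluster",
    "to_newick",
]

MIN_SHARED_TRAITS = 3


def scale_traits(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale every trait column to unit variance across strains.

    Missing values are omitted from the variance; columns with zero
    variance or fewer than two observations are dropped with a warning.
    Idempotent: scaling an already-scaled matrix changes nothing.
    """
    sd = matrix.std(axis=0, ddof=1)
    bad = sd.index[(sd == 0) | sd.isna() | (matrix.notna().sum(axis=0) < 2)]
    if len(bad):
        warnings.warn(f"dropping {len(bad)} zero-variance or under-observed trait column(s)")
    kept = matrix.drop(columns=list(bad))
    return kept / sd.drop(list(bad))


def pairwise_similarity(
    matrix: pd.DataFrame, min_shared: int = MIN_SHARED_TRAITS
) -> pd.DataFrame:
    """Pearson correlation for every unordered strain pair.

    Correlations use the traits present in both strains (pairwise-complete
    deletion). Pairs sharing fewer than ``min_shared`` traits are flagged
    invalid (``r`` NaN).

    Returns a tidy frame: ``strain_a, strain_b, r, n_traits_used, valid``.
    """
    strains = list(matrix.index)
    if len(strains) < 2:
        raise ValueError("need at least two strains")
    corr = matrix.T.corr(min_periods=min_shared)  # strains x strains, pairwise-complete
    present = matrix.notna().to_numpy().astype(int)
    shared = present @ present.T
    rows = []
    for i in range(len(strains)):
        for j in range(i + 1, len(strains)):
            n_shared = int(shared[i, j])
            r = corr.iat[i, j]
            valid = n_shared >= min_shared and not pd.isna(r)
            rows.append(
                dict(
                    strain_a=strains[i],
                    strain_b=strains[j],
                    r=float(r) if valid else np.nan,
                    n_traits_used=n_shared,
                    valid=valid,
                )
            )
    return pd.DataFrame(rows)


def count_pairs(group_sizes: Sequence[int], mode: str) -> int:
    """Exact number of within- or between-group unordered pairs.

    ``within``: sum of C(n_i, 2); ``between``: sum over i < j of n_i * n_j.
    """
    sizes = [int(n) for n in group_sizes]
    if any(n < 0 for n in sizes):
        raise ValueError("group sizes must be >= 0")
    if mode == "within":
        return sum(comb(n, 2) for n in sizes)
    if mode == "between":
        total = 0
        for i in range(len(sizes)):
            for j in range(i + 1, len(sizes)):
                total += sizes[i] * sizes[j]
        return total
    raise ValueError(f"unknown mode {mode!r}")


def label_pairs(
    pairs: pd.DataFrame,
    meta: pd.DataFrame,
    factor: str,
    universe: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Attach within/between labels for a grouping factor.

    Parameters
    ----------
    pairs : DataFrame
        Output of :func:`pairwise_similarity`.
    meta : DataFrame
        Strain metadata with ``strain_id`` and the ``factor`` column
        (species / population / source).
    factor : str
        Column of ``meta`` to group by.
    universe : sequence of str, optional
        Restrict to pairs where both strains are in this set (e.g. the
        population and source partitions are run on *S. cerevisiae* pairs
        only).
    """
    level = meta.set_index("strain_id")[factor]
    out = pairs.copy()
    if universe is not None:
        keep = out["strain_a"].isin(universe) & out["strain_b"].isin(universe)
        out = out[keep].reset_index(drop=True)
    la = out["strain_a"].map(level)
    lb = out["strain_b"].map(level)
    out["factor"] = factor
    out["group"] = np.where(la == lb, "within", "between")
    return out


@dataclass
class VariancePartitionResult:
    """One-way ANOVA of pair similarity on a within/between label."""

    factor: str
    F: float
    p_value: float
    adj_r2: float
    group_means: dict = field(default_factory=dict)
    n_within: int = 0
    n_between: int = 0
    caveat: str = (
        "pairs sharing a strain are treated as independent; p-values are "
        "anti-conservative"
    )


def partition(
    pairs: pd.DataFrame, factor: Optional[str] = None, response: str = "r"
) -> VariancePartitionResult:
    """Partition pair-similarity variance by a within/between factor.

    Ordinary least squares of the pair correlation on the two-level group
    label; reports the ANOVA F statistic, its p-value and the adjusted
    R-squared ``1 - (1 - R^2) (N - 1) / (N - 2)``. ``response="r2"``
    squares the correlations first (an alternative similarity response;
    see the module docstring of :mod:`ploidypheno`).
    """
    df = pairs.dropna(subset=[("r")]).copy()
    if factor is None:
        factor = str(df["factor"].iloc[0]) if "factor" in df and len(df) else "factor"
    y = df["r"].to_numpy(dtype=float)
    if response == "r2":
        y = y**2
    elif response != "r":
        raise ValueError(f"unknown response {response!r}")
    groups = df["group"].to_numpy()
    n_within = int((groups == "within").sum())
    n_between = int((groups == "between").sum())
    if n_within == 0 or n_between == 0:
        raise ValueError("both within and between groups must be nonempty")
    x = (groups == "within").astype(float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    means = {
        "within": float(y[groups == "within"].mean()),
        "between": float(y[groups == "between"].mean()),
    }
    return VariancePartitionResult(
        factor=factor,
        F=float(model.fvalue),
        p_value=float(model.f_pvalue),
        adj_r2=float(model.rsquared_adj),
        group_means=means,
        n_within=n_within,
        n_between=n_between,
    )


@dataclass
class Dendrogram:
    """Average-linkage tree over strains.

    ``linkage`` is a scipy linkage matrix (merge heights in column 2,
    non-decreasing for UPGMA); ``labels`` the leaf order matching the
    original distance matrix; ``imputed_pairs`` counts invalid distances
    replaced by the maximum observed distance.
    """

    linkage: np.ndarray
    labels: list[str]
    imputed_pairs: int = 0

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic(self) -> np.ndarray:
        """Condensed matrix of cophenetic (merge-height) distances."""
        return hierarchy.cophenet(self.linkage)


def upgma_cluster(
    matrix: pd.DataFrame, min_shared: int = MIN_SHARED_TRAITS
) -> Dendrogram:
    """UPGMA clustering of strains with centered-Pearson distance.

    Distance between strains is ``1 - r`` with r the (centered) Pearson
    correlation over shared traits; invalid pairs (too few shared traits)
    are imputed at the maximum observed distance and counted in the
    result. Agglomeration is average linkage, so merge heights are
    monotone non-decreasing.
    """
    pairs = pairwise_similarity(matrix, min_shared=min_shared)
    labels = list(matrix.index)
    n = len(labels)
    idx = {s: i for i, s in enumerate(labels)}
    dist = np.zeros((n, n))
    invalid = []
    for row in pairs.itertuples(index=False):
        i, j = idx[row.strain_a], idx[row.strain_b]
        if row.valid:
            dist[i, j] = dist[j, i] = 1.0 - row.r
        else:
            invalid.append((i, j))
    if invalid:
        finite_max = dist.max() if dist.max() > 0 else 2.0
        for i, j in invalid:
            dist[i, j] = dist[j, i] = finite_max
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(linkage=Z, labels=labels, imputed_pairs=len(invalid))


def to_newick(dendrogram: Dendrogram) -> str:
    """Serialize a dendrogram as a Newick string with branch lengths.

    Node heights are half the merge distance (ultrametric convention: the
    leaf-to-leaf path length through the tree equals the merge distance).
    """
    tree = hierarchy.to_tree(dendrogram.linkage)
    labels = dendrogram.labels

    def height(node) -> float:
        return 0.0 if node.is_leaf() else node.dist / 2.0

    def render(node, parent_height: float) -> str:
        bl = max(parent_height - height(node), 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{bl:.10g}"
        left = render(node.left, height(node))
        right = render(node.right, height(node))
        return f"({left},{right}):{bl:.10g}"

    root_h = height(tree)
    left = render(tree.left, root_h)
    right = render(tree.right, root_h)
    return f"({left},{right}):0;"
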