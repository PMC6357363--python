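"""Variance-based gene selection and agglomerative hierarchical clustering.

Clustering operates on the continuous gene-level matrix (discrete codes are
a display layer) under either a correlation distance (1 - Pearson r, in
[0, 2]) or Euclidean distance, with average (UPGMA) or complete linkage.
The agglomeration is implemented directly so that tie-breaking is fully
deterministic: at each step the closest pair with the lexicographically
smallest cluster-id pair merges, ids being leaf indices 0..n-1 followed by
merge ids n, n+1, ... as in the usual linkage-matrix convention.

Pairwise distances use pairwise-complete observations; an item pair with
fewer than two overlapping non-missing entries is an error naming the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .genomic_data import GeneCNVMatrix

DISTANCES = ("one_minus_pearson", "euclidean")
LINKAGES = ("average", "complete")


def select_variable_genes(matrix: GeneCNVMatrix, k: int) -> list[str]:
    """The ``k`` genes with the largest sample standard deviation.

    Missing entries are ignored (a gene needs >= 2 non-missing values to be
    eligible); ties break by annotation order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    sds = matrix.values.std(axis=1, ddof=1, skipna=True)
    eligible = sds.notna()
    n_eligible = int(eligible.sum())
    if k > n_eligible:
        raise ValueError(
            f"k={k} exceeds the {n_eligible} genes with >= 2 non-missing values"
        )
    sd_arr = sds.to_numpy(dtype=float)
    sd_arr[~eligible.to_numpy()] = -np.inf
    order = np.argsort(-sd_arr, kind="stable")  # stable: ties keep annotation order
    return [matrix.values.index[i] for i in order[:k]]


def _pairwise_distances(items: pd.DataFrame, distance: str) -> np.ndarray:
    """Distance matrix over rows of ``items`` using pairwise-complete data."""
    X = items.to_numpy(dtype=float)
    labels = list(items.index)
    n = X.shape[0]
    finite = np.isfinite(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = finite[i] & finite[j]
            if mask.sum() < 2:
                raise ValueError(
                    f"items {labels[i]!r} and {labels[j]!r} share fewer than "
                    "2 non-missing entries"
                )
            xi, xj = X[i, mask], X[j, mask]
            if distance == "euclidean":
                d = float(np.sqrt(np.sum((xi - xj) ** 2)))
            else:  # one_minus_pearson
                sx, sy = xi.std(), xj.std()
                if sx == 0 or sy == 0:
                    raise ValueError(
                        f"items {labels[i]!r} and {labels[j]!r} have a constant "
                        "profile; correlation distance undefined"
                    )
                r = float(np.corrcoef(xi, xj)[0, 1])
                d = 1.0 - r
            D[i, j] = D[j, i] = d
    return D


@dataclass
class ClusterResult:
    """Merge tree of one agglomerative clustering run.

    ``merges`` lists (left_id, right_id, height) with left_id < right_id;
    leaf ids are 0..n-1 in input order and merge m creates id n+m.
    ``leaf_order`` gives item labels in dendrogram order (left subtree
    first).
    """

    axis: str
    labels: list[str]
    merges: list[tuple[int, int, float]]
    leaf_order: list[str]
    distance_name: str
    linkage_name: str

    def to_newick(self) -> str:
        """Newick text with branch lengths = parent height - child height."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        children: dict[int, tuple[int, int]] = {}
        for m, (a, b, h) in enumerate(self.merges):
            node = n + m
            heights[node] = h
            children[node] = (a, b)

        def render(node: int, parent_height: float) -> str:
            bl = max(parent_height - heights[node], 0.0)
            if node < n:
                label = str(self.labels[node]).replace(" ", "_").replace(",", "_")
                return f"{label}:{bl:.10g}"
            a, b = children[node]
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{bl:.10g}"

        root = n + len(self.merges) - 1
        a, b = children[root]
        h = heights[root]
        return f"({render(a, h)},{render(b, h)});"


def hierarchical_cluster(
    matrix,
    axis: str = "samples",
    distance: str = "one_minus_pearson",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of a gene-level matrix along one axis.

    ``matrix`` may be a :class:`GeneCNVMatrix` or a plain DataFrame
    (rows = genes, columns = samples). ``axis='samples'`` clusters columns,
    ``axis='genes'`` clusters rows.
    """
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if axis not in ("genes", "samples"):
        raise ValueError("axis must be 'genes' or 'samples'")
    values = matrix.values if isinstance(matrix, GeneCNVMatrix) else matrix
    items = values.T if axis == "samples" else values
    labels = [str(x) for x in items.index]
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 items to cluster")

    D = _pairwise_distances(items, distance)

    # Active clusters: id -> (size, member leaf ids); distances in a dict
    # keyed by ordered id pairs.
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    children: dict[int, tuple[int, int]] = {}

    for step in range(n - 1):
        best_d, best_pair = None, None
        for (a, b), d in dist.items():
            if best_d is None or d < best_d or (d == best_d and (a, b) < best_pair):
                best_d, best_pair = d, (a, b)
        d, (a, b) = best_d, best_pair
        new_id = n + step
        merges.append((a, b, float(d)))
        children[new_id] = (a, b)
        active.discard(a)
        active.discard(b)
        for x in sorted(active):
            da = dist.pop((min(a, x), max(a, x)))
            db = dist.pop((min(b, x), max(b, x)))
            if linkage == "average":
                dnew = (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
            else:
                dnew = max(da, db)
            dist[(x, new_id)] = dnew
        del dist[(a, b)]
        sizes[new_id] = sizes[a] + sizes[b]
        active.add(new_id)

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    leaf_order = [labels[i] for i in leaves(n + len(merges) - 1)]
    return ClusterResult(
        axis=axis, labels=labels, merges=merges, leaf_order=leaf_order,
        distance_name=distance, linkage_name=linkage,
    )


class CNVHierarchicalClustering(BaseEstimator):
    """Estimator wrapper around :func:`hierarchical_cluster`.

    Parameters mirror the function; after ``fit`` the result is available
    as ``merge_tree_`` (the linkage-style merge list), ``leaf_order_`` and
    ``result_``.
    """

    def __init__(self, axis: str = "samples", distance: str = "one_minus_pearson",
                 linkage: str = "average"):
        self.axis = axis
        self.distance = distance
        self.linkage = linkage

    def fit(self, X, y=None):
        result = hierarchical_cluster(
            X, axis=self.axis, distance=self.distance, linkage=self.linkage
        )
        self.result_ = result
        self.merge_tree_ = result.merges
        self.leaf_order_ = result.leaf_order
        return self


def export_cluster(result: ClusterResult, matrix, newick_path, order_path) -> None:
    """Write the merge tree (Newick) and the reordered matrix (TSV)."""
    with open(newick_path, "w") as fh:
        fh.write(result.to_newick() + "\n")
    values = matrix.values if isinstance(matrix, GeneCNVMatrix) else matrix
    if result.axis == "samples":
        reordered = values.loc[:, result.leaf_order]
    else:
        reordered = values.loc[result.leaf_order]
    reordered.to_csv(order_path, sep="\t")
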