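"""Hierarchical clustering of genome-proportion profiles.

Species are clustered by their repeat-cluster GP profiles (rows
normalized to relative composition, Euclidean distance, UPGMA linkage),
with ordinary bootstrap support over repeat clusters: columns are
resampled with replacement and each internal node is scored by the
fraction of replicate trees containing the same leaf set.  The same
machinery, applied to the transposed matrix, groups repeat clusters by
their cross-species abundance pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def _normalize_rows(matrix: np.ndarray) -> np.ndarray:
    sums = matrix.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return matrix / sums


def _linkage(matrix: np.ndarray, distance: str, method: str) -> np.ndarray:
    return hierarchy.linkage(pdist(matrix, metric=distance), method=method)


def _clades(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    """Leaf set of every internal node, in merge order."""
    n = len(labels)
    sets: list[frozenset] = [frozenset([lab]) for lab in labels]
    clades = []
    for a, b, _, _ in Z:
        merged = sets[int(a)] | sets[int(b)]
        sets.append(merged)
        clades.append(merged)
    return clades


@dataclass
class Dendrogram:
    """UPGMA tree over profile rows with per-node bootstrap support."""

    labels: list[str]
    linkage: np.ndarray = field(repr=False)
    support: dict[frozenset, float] = field(default_factory=dict, repr=False)
    distance: str = "euclidean"
    method: str = "average"
    n_boot: int = 0

    def clades(self) -> list[frozenset]:
        return _clades(self.linkage, self.labels)

    def top_split(self) -> tuple[frozenset, frozenset]:
        """The two leaf sets separated by the root."""
        clades = self.clades()
        root = clades[-1]
        # the last merge joins the two children of the root
        a, b = self.linkage[-1, 0], self.linkage[-1, 1]
        sets = [frozenset([lab]) for lab in self.labels] + clades
        return sets[int(a)], sets[int(b)]

    def clade_support(self, leaves) -> float:
        return self.support.get(frozenset(leaves), 0.0)

    def to_newick(self) -> str:
        """Newick with bootstrap supports as internal node labels."""
        tree = hierarchy.to_tree(self.linkage)
        sets = [frozenset([lab]) for lab in self.labels]

        def leafset(node):
            if node.is_leaf():
                return sets[node.id]
            return leafset(node.left) | leafset(node.right)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            inner = ",".join(rec(c, node.dist) for c in (node.left, node.right))
            sup = self.support.get(leafset(node))
            label = f"{sup:.3f}" if sup is not None else ""
            return f"({inner}){label}:{length:.6g}"

        inner = ",".join(rec(c, tree.dist) for c in (tree.left, tree.right))
        root_sup = self.support.get(frozenset(self.labels))
        return f"({inner}){'' if root_sup is None else f'{root_sup:.3f}'};"


def cluster_species(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    method: str = "average",
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    normalize: bool = True,
) -> Dendrogram:
    """Cluster profile rows with column-bootstrap support.

    ``matrix``: rows = species (or repeat clusters), columns = repeat
    clusters (or species), values = genome proportions.  The tree for the
    observed matrix is deterministic; bootstrap resamples columns with
    replacement and records, for each internal node, the fraction of
    replicates whose tree contains the same leaf set.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 rows to cluster")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("genome proportions must be non-negative")
    labels = [str(x) for x in matrix.index]
    X = matrix.to_numpy(dtype=float)
    if normalize:
        X = _normalize_rows(X)
    Z = _linkage(X, distance, method)
    clades = _clades(Z, labels)
    hits = {c: 0 for c in clades}
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, p, size=p)
        Zb = _linkage(X[:, cols], distance, method)
        for c in _clades(Zb, labels):
            if c in hits:
                hits[c] += 1
    support = {c: (hits[c] / n_boot if n_boot else float("nan")) for c in clades}
    if n_boot:
        support[frozenset(labels)] = 1.0  # root clade is in every replicate
    return Dendrogram(labels=labels, linkage=Z, support=support,
                      distance=distance, method=method, n_boot=n_boot)


def group_repeat_clusters(
    matrix: pd.DataFrame,
    cut_fraction: float = 0.5,
    distance: str = "euclidean",
    method: str = "average",
) -> pd.DataFrame:
    """Partition repeat clusters by cross-species abundance pattern.

    ``matrix``: rows = repeat clusters, columns = species, values = GP.
    Rows are normalized (so proportional patterns group together), UPGMA
    clustered, and the tree is cut at ``cut_fraction`` of the maximum
    merge height.  Returns a frame indexed by cluster with ``group`` ids
    (1-based, ordered by decreasing group share) and the group share =
    mean over species of the group's summed GP.
    """
    if matrix.shape[0] < 1:
        raise ValueError("empty profile matrix")
    if matrix.shape[0] == 1:
        return pd.DataFrame({"group": [1],
                             "group_share": [float(matrix.iloc[0].mean())]},
                            index=matrix.index)
    X = _normalize_rows(matrix.to_numpy(dtype=float))
    Z = _linkage(X, distance, method)
    height = Z[:, 2].max()
    assign = hierarchy.fcluster(Z, t=cut_fraction * height, criterion="distance")
    out = pd.DataFrame({"group_raw": assign}, index=matrix.index)
    shares = {
        g: float(matrix.loc[out["group_raw"] == g].sum(axis=0).mean())
        for g in np.unique(assign)
    }
    order = sorted(shares, key=lambda g: -shares[g])
    remap = {g: i + 1 for i, g in enumerate(order)}
    out["group"] = out["group_raw"].map(remap)
    out["group_share"] = out["group_raw"].map(shares)
    return out[["group", "group_share"]]
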