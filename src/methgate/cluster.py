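"""Hierarchical clustering of responder genes on temporal profiles.

Distance is 1 - Pearson correlation between per-condition mean profiles;
trees are built by average linkage (UPGMA).  The agglomeration is
implemented directly so that the merge order is fully deterministic:
among equally close pairs the pair containing the lowest leaf index wins
(then the lower opposing minimum leaf index).  Heights are checked for
monotonicity; average linkage on a non-metric correlation distance can in
principle produce inversions, which are logged rather than assumed away.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GeneSet

logger = logging.getLogger("methgate")

__all__ = [
    "Dendrogram",
    "condition_mean_profiles",
    "pearson_distance",
    "average_linkage_cluster",
    "split_groups",
    "es_response_log2fc",
]


@dataclass
class Dendrogram:
    """Binary merge tree over gene leaves (scipy-style linkage rows).

    ``merges[k] = (i, j, height, size)`` merges clusters i and j into
    cluster ``n_leaves + k``; leaves are clusters ``0..n_leaves-1`` in
    the order of ``leaves``.
    """

    leaves: list
    merges: list

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def linkage_matrix(self) -> np.ndarray:
        return np.array(self.merges, dtype=float).reshape(-1, 4)

    def _members(self) -> list:
        clusters = [frozenset([i]) for i in range(self.n_leaves)]
        for i, j, _, _ in self.merges:
            clusters.append(clusters[int(i)] | clusters[int(j)])
        return clusters

    def root_split(self) -> tuple[frozenset, frozenset]:
        """Leaf labels of the two clusters joined by the final merge."""
        if not self.merges:
            raise ValueError("degenerate tree: nothing to split")
        clusters = self._members()
        i, j, _, _ = self.merges[-1]
        left = frozenset(self.leaves[k] for k in clusters[int(i)])
        right = frozenset(self.leaves[k] for k in clusters[int(j)])
        return left, right

    def to_newick(self) -> str:
        nodes = [str(label) for label in self.leaves]
        heights = [0.0] * self.n_leaves
        for i, j, h, _ in self.merges:
            i, j = int(i), int(j)
            bi = max(h - heights[i], 0.0) / 2.0
            bj = max(h - heights[j], 0.0) / 2.0
            nodes.append(f"({nodes[i]}:{bi:.6g},{nodes[j]}:{bj:.6g})")
            heights.append(h)
        return nodes[-1] + ";"


def condition_mean_profiles(
    matrix: ExpressionMatrix, genes=None, standardize: bool = True
) -> pd.DataFrame:
    """Per-gene mean profile over design cells (context, genotype,
    treatment, time_h), replicates averaged; rows optionally centered and
    scaled to unit variance (cosmetic for correlation distance)."""
    values = matrix.values if genes is None else matrix.values.loc[list(genes)]
    keys = matrix.design[["context", "genotype", "treatment", "time_h"]]
    key_tuples = pd.MultiIndex.from_frame(keys)
    profiles = values.T.groupby(key_tuples).mean().T
    profiles.columns = [
        f"{c}_{g}_{tr}_{t}h" for c, g, tr, t in profiles.columns
    ]
    if standardize:
        centered = profiles.sub(profiles.mean(axis=1), axis=0)
        sd = centered.std(axis=1, ddof=0)
        if (sd == 0).any():
            flat = list(profiles.index[sd == 0])
            raise ValueError(f"zero-variance profile for gene(s) {flat[:5]}")
        profiles = centered.div(sd, axis=0)
    return profiles


def pearson_distance(profiles: pd.DataFrame) -> np.ndarray:
    """Distance matrix d(i,j) = 1 - Pearson r between gene profiles."""
    arr = profiles.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need >= 2 conditions per gene")
    sd = arr.std(axis=1)
    if (sd == 0).any():
        flat = list(profiles.index[sd == 0])
        raise ValueError(f"zero-variance profile for gene(s) {flat[:5]}")
    corr = np.corrcoef(arr)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def average_linkage_cluster(dist: np.ndarray, labels=None) -> Dendrogram:
    """Agglomerative UPGMA over a full distance matrix.

    The inter-cluster distance is the size-weighted mean of member
    pairwise distances (maintained by the Lance-Williams update).  Ties
    are broken toward the pair containing the lowest original leaf index.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least two leaves to cluster")
    if dist.shape != (n, n) or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    if labels is None:
        labels = list(range(n))
    labels = list(labels)

    active = {i: {"id": i, "size": 1, "minleaf": i} for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dist[i, j]

    merges = []
    next_id = n
    heights = []
    keys = list(active.keys())
    for step in range(n - 1):
        best = None
        for ii in range(len(keys)):
            for jj in range(ii + 1, len(keys)):
                a, b = keys[ii], keys[jj]
                dij = d[(min(a, b), max(a, b))]
                la = min(active[a]["minleaf"], active[b]["minleaf"])
                lb = max(active[a]["minleaf"], active[b]["minleaf"])
                cand = (dij, la, lb)
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        (height, _, _), a, b = best
        sa, sb = active[a]["size"], active[b]["size"]
        merges.append(
            (active[a]["id"], active[b]["id"], float(height), sa + sb)
        )
        heights.append(height)
        new_key = min(a, b)
        other_key = max(a, b)
        for c in keys:
            if c in (a, b):
                continue
            dac = d[(min(a, c), max(a, c))]
            dbc = d[(min(b, c), max(b, c))]
            d[(min(new_key, c), max(new_key, c))] = (sa * dac + sb * dbc) / (
                sa + sb
            )
        active[new_key] = {
            "id": next_id,
            "size": sa + sb,
            "minleaf": min(active[a]["minleaf"], active[b]["minleaf"]),
        }
        del active[other_key]
        keys = sorted(active.keys())
        next_id += 1

    if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
        logger.warning("average_linkage_cluster: non-monotone merge heights")
    return Dendrogram(leaves=labels, merges=merges)


def es_response_log2fc(
    matrix: ExpressionMatrix, genes, time_h: int = 72
) -> pd.Series:
    """Per-gene log2 fold change, ES Dex+ vs Dex- at ``time_h`` (both
    genotypes pooled) — used to orient the group-1/group-2 split."""
    plus = matrix.select(context="ES", treatment="Dex+", time_h=time_h)
    minus = matrix.select(context="ES", treatment="Dex-", time_h=time_h)
    if not plus or not minus:
        raise ValueError(f"missing ES Dex+/Dex- samples at {time_h} h")
    sub = matrix.values.loc[list(genes)]
    return sub[plus].mean(axis=1) - sub[minus].mean(axis=1)


def split_groups(
    tree: Dendrogram, es_response: pd.Series
) -> tuple[GeneSet, GeneSet]:
    """Cut the tree at the root into two clusters; the cluster with the
    higher mean ES response is group 1 (ES-responsive, endoderm-like),
    the other group 2 (mesoderm-restricted).  On an exact tie the cluster
    holding the lowest-index leaf becomes group 1 (warning logged)."""
    left, right = tree.root_split()
    mean_left = float(es_response.loc[list(left)].mean())
    mean_right = float(es_response.loc[list(right)].mean())
    if mean_left == mean_right:
        warnings.warn(
            "split_groups: equal mean ES response; lowest-index leaf cluster "
            "labeled group 1",
            RuntimeWarning,
        )
        first_leaf = tree.leaves[0]
        g1, g2 = (left, right) if first_leaf in left else (right, left)
    elif mean_left > mean_right:
        g1, g2 = left, right
    else:
        g1, g2 = right, left
    return (
        GeneSet(label="group1", members=frozenset(g1)),
        GeneSet(label="group2", members=frozenset(g2)),
    )
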