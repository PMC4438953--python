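"""Unsupervised hierarchical clustering of samples or features.

Distance is 1 - Pearson correlation; linkage is unweighted average
(UPGMA) with a deterministic tie-break: among equidistant cluster pairs
the pair whose lexicographically smallest member labels come first is
merged. A two-branch root cut recovers the two major sample clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GROUP_NORMAL
from .errors import DomainError, UsageError


@dataclass
class Dendrogram:
    """Merge tree over labeled leaves.

    ``merges`` is an ordered list of (node_a, node_b, height) triples;
    leaves are numbered 0..n-1 in label order, merge k creates node n+k.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]
    _members: dict[int, frozenset[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != max(n - 1, 0):
            raise UsageError(f"{n} leaves require {n - 1} merges")
        self._members = {i: frozenset([i]) for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            self._members[n + k] = self._members[a] | self._members[b]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def members(self, node: int) -> list[str]:
        return sorted(self.labels[i] for i in self._members[node])

    @property
    def leaf_order(self) -> list[str]:
        """Left-to-right leaf permutation implied by the merge order."""
        if not self.merges:
            return list(self.labels)
        n = len(self.labels)

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            a, b, _ = self.merges[node - n]
            return walk(a) + walk(b)

        root = n + len(self.merges) - 1
        return [self.labels[i] for i in walk(root)]

    def to_newick(self) -> str:
        """Newick-like string with merge heights as branch annotations."""
        n = len(self.labels)

        def node_str(node: int, parent_h: float) -> str:
            if node < n:
                return f"{self.labels[node]}:{parent_h:.6g}"
            a, b, h = self.merges[node - n]
            return f"({node_str(a, h)},{node_str(b, h)}):{max(parent_h - h, 0.0):.6g}"

        root = n + len(self.merges) - 1
        if n == 1:
            return f"{self.labels[0]};"
        a, b, h = self.merges[-1]
        return f"({node_str(a, h)},{node_str(b, h)});"


def pearson_distance(matrix: ExpressionMatrix, axis: str = "samples") -> pd.DataFrame:
    """Pairwise 1 - Pearson-r distances between samples or features."""
    if axis == "samples":
        vectors = matrix.values.T
        labels = list(matrix.sample_ids)
    elif axis == "features":
        vectors = matrix.values
        labels = list(matrix.feature_ids)
    else:
        raise UsageError(f"axis must be 'samples' or 'features', got {axis!r}")
    if vectors.shape[0] < 2:
        raise UsageError("need at least two vectors")
    sd = vectors.std(axis=1)
    if np.any(sd == 0):
        bad = labels[int(np.argwhere(sd == 0)[0][0])]
        raise DomainError(f"zero-variance vector {bad!r}")
    r = np.corrcoef(vectors)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=labels, columns=labels)


def average_linkage(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA merge sequence over a symmetric distance matrix.

    Cluster-to-cluster distance is the unweighted mean of member
    pairwise distances (maintained by Lance-Williams update). Ties are
    broken by the lexicographically smallest member labels, making the
    merge order platform-independent.
    """
    if not isinstance(dist, pd.DataFrame):
        raise UsageError("average_linkage expects a labeled DataFrame")
    d = dist.to_numpy(dtype=float)
    labels = [str(c) for c in dist.columns]
    if d.shape[0] != d.shape[1] or list(dist.index) != list(dist.columns):
        raise UsageError("distance matrix must be square with matching labels")
    if not np.allclose(d, d.T, atol=1e-12):
        raise UsageError("distance matrix must be symmetric")
    n = d.shape[0]

    # active cluster id -> (size, representative label = lexicographic min)
    size = {i: 1 for i in range(n)}
    rep = {i: labels[i] for i in range(n)}
    dd: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dd[(i, j)] = float(d[i, j])
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), dij in dd.items():
            ra, rb = sorted((rep[i], rep[j]))
            key = (dij, ra, rb)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = dd[(i, j)] if (i, j) in dd else dd[(j, i)]
        a, b = (i, j) if rep[i] <= rep[j] else (j, i)
        merges.append((a, b, h))
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dik = dd.pop((min(i, k), max(i, k)))
            djk = dd.pop((min(j, k), max(j, k)))
            dd[(min(new, k), max(new, k))] = (
                size[i] * dik + size[j] * djk
            ) / (size[i] + size[j])
        del dd[(min(i, j), max(i, j))]
        size[new] = size[i] + size[j]
        rep[new] = min(rep[i], rep[j])
        active.discard(i)
        active.discard(j)
        active.add(new)
    return Dendrogram(labels=labels, merges=merges)


def cut_two(
    dendrogram: Dendrogram, normal_ids: Sequence[str] | None = None
) -> dict[str, str]:
    """Split the tree at the root merge into two sample clusters.

    The component containing the lexicographically smallest normal
    sample id is labeled ``cluster1`` (falling back to the smallest leaf
    label when no normal ids are supplied).
    """
    if dendrogram.n_leaves < 2:
        raise UsageError("cut_two needs at least two leaves")
    a, b, _ = dendrogram.merges[-1]
    side_a = set(dendrogram.members(a))
    side_b = set(dendrogram.members(b))
    anchors = sorted(normal_ids) if normal_ids else sorted(dendrogram.labels)
    anchor = next((x for x in anchors if x in side_a | side_b), None)
    if anchor is None:
        raise UsageError("no anchor sample found in the tree")
    first, second = (side_a, side_b) if anchor in side_a else (side_b, side_a)
    out = {s: "cluster1" for s in first}
    out.update({s: "cluster2" for s in second})
    return out


def cluster_samples(
    matrix: ExpressionMatrix,
) -> tuple[Dendrogram, dict[str, str]]:
    """Convenience: distance + linkage + two-cluster cut on samples."""
    dist = pearson_distance(matrix, axis="samples")
    tree = average_linkage(dist)
    normals = [s for s, g in zip(matrix.sample_ids, matrix.groups) if g == GROUP_NORMAL]
    return tree, cut_two(tree, normal_ids=normals)


def export_heatmap_tsv(
    matrix: ExpressionMatrix, path: str | Path
) -> tuple[list[str], list[str]]:
    """Write the doubly reordered matrix (features and samples clustered).

    Returns the (feature_order, sample_order) leaf orders; image
    rendering is intentionally left to downstream tooling.
    """
    sample_order = average_linkage(pearson_distance(matrix, axis="samples")).leaf_order
    if matrix.n_features >= 2:
        feature_order = average_linkage(
            pearson_distance(matrix, axis="features")
        ).leaf_order
    else:
        feature_order = list(matrix.feature_ids)
    df = pd.DataFrame(
        matrix.values, index=matrix.feature_ids, columns=matrix.sample_ids
    )
    df = df.loc[feature_order, sample_order]
    df.to_csv(path, sep="\t", index_label="feature_id")
    return feature_order, sample_order
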