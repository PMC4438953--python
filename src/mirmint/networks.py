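"""Bipartite miRNA-GO and miRNA-mRNA networks ranked by degree.

The adjacency is binary by default so that node degrees are plain edge
counts; weighted strengths (summed association weights) are kept
separately and exported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import GeneSetCollection
from .errors import DomainError, UsageError
from .integration import RegulatoryPair


@dataclass
class BipartiteNetwork:
    """A strictly bipartite graph between miRNAs and partner nodes.

    ``left_nodes``/``right_nodes`` map node id -> regulation direction
    (None when not applicable, e.g. GO terms). ``edges`` maps
    (left, right) -> association weight.
    """

    left_nodes: dict[str, str | None]
    right_nodes: dict[str, str | None]
    edges: dict[tuple[str, str], float]
    right_type: str = "partner"

    def __post_init__(self) -> None:
        overlap = set(self.left_nodes) & set(self.right_nodes)
        if overlap:
            raise DomainError(f"nodes on both sides: {sorted(overlap)[:3]}")
        for left, right in self.edges:
            if left not in self.left_nodes or right not in self.right_nodes:
                raise DomainError(f"edge ({left}, {right}) references unknown node")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def left_degrees(self) -> dict[str, int]:
        deg = {node: 0 for node in self.left_nodes}
        for left, _ in self.edges:
            deg[left] += 1
        return deg

    def right_degrees(self) -> dict[str, int]:
        deg = {node: 0 for node in self.right_nodes}
        for _, right in self.edges:
            deg[right] += 1
        return deg

    def adjacency(self, weighted: bool = False) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense adjacency matrix A=(a_ij) plus row/column node orders."""
        rows = sorted(self.left_nodes)
        cols = sorted(self.right_nodes)
        a = np.zeros((len(rows), len(cols)))
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: j for j, c in enumerate(cols)}
        for (left, right), w in self.edges.items():
            a[ri[left], ci[right]] = w if weighted else 1.0
        return a, rows, cols

    def validate_degree_balance(self) -> None:
        sl = sum(self.left_degrees().values())
        sr = sum(self.right_degrees().values())
        if not (sl == sr == self.n_edges):
            raise DomainError(
                f"degree sums {sl}/{sr} disagree with edge count {self.n_edges}"
            )


def build_mirna_go(
    pairs: Sequence[RegulatoryPair],
    significant_terms: Sequence[str],
    gene_sets: GeneSetCollection,
) -> BipartiteNetwork:
    """Edge (miRNA, term) iff some filtered pair's gene is a term member.

    Only genes that survived the anti-correlation filter contribute, and
    only the supplied significant terms become nodes.
    """
    missing = [t for t in significant_terms if t not in gene_sets.sets]
    if missing:
        raise UsageError(f"terms absent from the collection: {missing[:3]}")
    left: dict[str, str | None] = {}
    right: dict[str, str | None] = {t: None for t in significant_terms}
    edges: dict[tuple[str, str], float] = {}
    members = {t: set(gene_sets.members(t)) for t in significant_terms}
    for p in pairs:
        left.setdefault(p.mirna_id, p.mirna_direction)
        for term in significant_terms:
            if p.gene_id in members[term]:
                key = (p.mirna_id, term)
                edges[key] = edges.get(key, 0.0) + p.weight
    # drop miRNAs with no edge into any term? keep them as isolated nodes
    return BipartiteNetwork(
        left_nodes=left, right_nodes=right, edges=edges, right_type="GO"
    )


def build_mirna_mrna(pairs: Sequence[RegulatoryPair]) -> BipartiteNetwork:
    """One edge per distinct (miRNA, gene) regulatory pair."""
    left: dict[str, str | None] = {}
    right: dict[str, str | None] = {}
    edges: dict[tuple[str, str], float] = {}
    for p in pairs:
        left.setdefault(p.mirna_id, p.mirna_direction)
        right.setdefault(p.gene_id, p.gene_direction)
        key = (p.mirna_id, p.gene_id)
        if key not in edges:
            edges[key] = p.weight
    return BipartiteNetwork(
        left_nodes=left, right_nodes=right, edges=edges, right_type="mRNA"
    )


def rank_key_nodes(
    network: BipartiteNetwork, side: str = "left"
) -> list[tuple[str, int]]:
    """Nodes of one side ordered by degree descending, ties lexicographic."""
    if side == "left":
        deg = network.left_degrees()
    elif side == "right":
        deg = network.right_degrees()
    else:
        raise UsageError("side must be 'left' or 'right'")
    return sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))


def write_characteristics_table(network: BipartiteNetwork, path: str | Path) -> None:
    """Degree listing for both sides, mirroring published degree tables."""
    with Path(path).open("w") as fh:
        fh.write("node_type\tname\tdegree\n")
        for name, degree in rank_key_nodes(network, "left"):
            fh.write(f"miRNA\t{name}\t{degree}\n")
        for name, degree in rank_key_nodes(network, "right"):
            fh.write(f"{network.right_type}\t{name}\t{degree}\n")
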