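"""Readers and writers for every external format the pipeline touches.

All downstream modules consume only the in-memory domain types defined
here (:class:`ExpressionMatrix`, :class:`GeneSetCollection`,
:class:`PlatformMap`); no other module opens a data file directly.

Supported formats: tab-separated expression matrices, the table block of
GEO Series-Matrix files, FASTA, GMT gene-set files, edge-list TSV and
GraphML network exports, and small JSON reports.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, LabelingError, UsageError

logger = logging.getLogger("mirmint")

GROUP_TUMOR = "tumor"
GROUP_NORMAL = "normal"
VALID_GROUPS = frozenset({GROUP_TUMOR, GROUP_NORMAL})

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}


def canonical_mirna_id(name: str) -> str:
    """Canonical form for miRNA identifiers.

    miRNA names following the ``hsa-...`` convention are compared
    case-insensitively (``hsa-miR-923`` == ``hsa-mir-923``); every other
    identifier is compared case-sensitively.
    """
    if name.lower().startswith("hsa-"):
        return name.lower()
    return name


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix with per-sample group labels.

    ``values`` is a float array with one row per feature; missing
    measurements are stored as NaN, never as zero. ``scale`` records
    whether values are on the linear or log2 scale so that a double log
    transform can be refused.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    groups: list[str]
    values: np.ndarray
    scale: str = "linear"
    platform_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise UsageError("expression values must be a 2-D array")
        if self.values.shape[0] != len(self.feature_ids):
            raise UsageError(
                f"{self.values.shape[0]} rows but {len(self.feature_ids)} feature ids"
            )
        if self.values.shape[1] != len(self.sample_ids):
            raise UsageError(
                f"{self.values.shape[1]} columns but {len(self.sample_ids)} sample ids"
            )
        if len(self.groups) != len(self.sample_ids):
            raise UsageError("one group label per sample required")
        bad = set(self.groups) - VALID_GROUPS
        if bad:
            raise LabelingError(f"unknown group labels: {sorted(bad)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise UsageError("duplicate sample ids are not permitted")
        if self.scale not in ("linear", "log2"):
            raise UsageError(f"unknown scale {self.scale!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_mask(self, label: str) -> np.ndarray:
        return np.array([g == label for g in self.groups], dtype=bool)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            groups=list(self.groups),
            values=self.values.copy(),
            scale=self.scale,
            platform_tag=self.platform_tag,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GO terms, pathways) keyed by term id.

    ``sets`` maps term_id -> (term_name, ordered unique member list).
    ``universe`` is an optional explicit background; when absent the
    union of all members serves as the default universe.
    """

    sets: dict[str, tuple[str, list[str]]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {term_id!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {term_id!r} has duplicate members")

    def members(self, term_id: str) -> list[str]:
        return self.sets[term_id][1]

    def name(self, term_id: str) -> str:
        return self.sets[term_id][0]

    def default_universe(self) -> list[str]:
        if self.universe is not None:
            return list(self.universe)
        seen: dict[str, None] = {}
        for _, members in self.sets.values():
            for m in members:
                seen.setdefault(m)
        return list(seen)

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.universe == other.universe


@dataclass
class PlatformMap:
    """Probe-to-gene-symbol mapping; many-to-one and one-to-many allowed."""

    mapping: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe, genes in self.mapping.items():
            if not probe:
                raise FormatError("empty probe id in platform map")
            if not genes or any(not g for g in genes):
                raise FormatError(f"probe {probe!r} maps to an empty gene symbol")

    def genes_for(self, probe: str) -> list[str]:
        return self.mapping.get(probe, [])

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _parse_value(token: str) -> float:
    if token.strip().lower() in _MISSING_TOKENS:
        return float("nan")
    try:
        return float(token)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value {token!r}") from exc


def read_expression(
    path: str | Path,
    format: str = "tsv",
    group_spec: Mapping[str, str] | None = None,
    scale: str = "linear",
    platform_tag: str = "",
) -> ExpressionMatrix:
    """Read an expression matrix from ``tsv`` or ``series_matrix`` format.

    ``group_spec`` must assign a group label to every sample in the file;
    a sample without a label raises :class:`LabelingError`.
    """
    path = Path(path)
    if format == "tsv":
        header, rows = _read_table_lines(path.read_text().splitlines(), path)
    elif format == "series_matrix":
        header, rows = _read_series_matrix(path)
    else:
        raise UsageError(f"unknown expression format {format!r}")

    if group_spec is None:
        raise UsageError("group_spec is required")
    sample_ids = header
    groups = []
    for s in sample_ids:
        if s not in group_spec:
            raise LabelingError(f"sample {s!r} has no group assignment")
        groups.append(group_spec[s])

    feature_ids = [r[0] for r in rows]
    values = np.array(
        [[_parse_value(tok) for tok in r[1:]] for r in rows], dtype=float
    ).reshape(len(rows), len(sample_ids))
    return ExpressionMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        groups=groups,
        values=values,
        scale=scale,
        platform_tag=platform_tag,
    )


def _read_table_lines(
    lines: Sequence[str], path: Path
) -> tuple[list[str], list[list[str]]]:
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty expression file")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header row must name at least one sample")
    sample_ids = [_unquote(h) for h in header[1:]]
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        fields = ln.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{i}: expected {len(header)} fields, found {len(fields)}"
            )
        fields[0] = _unquote(fields[0])
        rows.append(fields)
    return sample_ids, rows


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == '"' and token[-1] == '"':
        token = token[1:-1]
    return token


def _read_series_matrix(path: Path) -> tuple[list[str], list[list[str]]]:
    """Extract the expression table block of a GEO Series-Matrix file.

    Only the ``!series_matrix_table_begin``/``end`` block plus the
    ``!Sample_title`` / ``!Sample_geo_accession`` metadata lines are
    understood; full SOFT parsing is out of scope.
    """
    table_lines: list[str] = []
    in_table = False
    saw_begin = False
    for ln in path.read_text().splitlines():
        if ln.startswith("!series_matrix_table_begin"):
            in_table = True
            saw_begin = True
            continue
        if ln.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table_lines.append(ln)
    if not saw_begin:
        raise FormatError(f"{path}: no !series_matrix_table_begin sentinel found")
    if not table_lines:
        raise FormatError(f"{path}: empty series-matrix table block")
    return _read_table_lines(table_lines, path)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            cells = ["" if np.isnan(v) else format(v, ".10g") for v in row]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


def read_group_spec(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sample_id<TAB>group`` -> mapping."""
    spec: dict[str, str] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{i}: expected 'sample<TAB>group'")
        spec[fields[0]] = fields[1]
    return spec


def write_group_spec(spec: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sample, group in spec.items():
            fh.write(f"{sample}\t{group}\n")


def preprocess_missing(
    matrix: ExpressionMatrix, max_missing_frac: float = 0.2
) -> ExpressionMatrix:
    """Drop features with too many missing values, mean-impute the rest.

    A feature with more than ``max_missing_frac`` missing values across
    the cohort is excluded; remaining missing entries are replaced by
    the mean of the observed values within the same group.
    """
    values = matrix.values
    missing = np.isnan(values)
    keep = missing.mean(axis=1) <= max_missing_frac
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("preprocess_missing: dropped %d features", n_dropped)
    values = values[keep].copy()
    feature_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    for label in set(matrix.groups):
        cols = matrix.group_mask(label)
        block = values[:, cols]
        if block.size == 0:
            continue
        row_means = np.nanmean(np.where(np.isnan(block), np.nan, block), axis=1)
        nan_rows, nan_cols = np.where(np.isnan(block))
        block[nan_rows, nan_cols] = row_means[nan_rows]
        values[:, cols] = block
    return ExpressionMatrix(
        feature_ids=feature_ids,
        sample_ids=list(matrix.sample_ids),
        groups=list(matrix.groups),
        values=values,
        scale=matrix.scale,
        platform_tag=matrix.platform_tag,
    )


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``term_id<TAB>term_name<TAB>member...`` per line."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{i}: GMT line needs >=3 tab-separated fields")
        term_id, term_name = fields[0], fields[1]
        members: list[str] = []
        seen: set[str] = set()
        for m in fields[2:]:
            if m and m not in seen:
                members.append(m)
                seen.add(m)
        sets[term_id] = (term_name, members)
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term_id, (name, members) in collection.sets.items():
            fh.write("\t".join([term_id, name, *members]) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: sequence}``.

    Sequences are upper-cased and T is normalized to U so that all
    downstream seed matching happens on the RNA alphabet. The id is the
    first whitespace-delimited token after ``>``.
    """
    path = Path(path)
    text = path.read_text()
    for ln in text.splitlines():
        if not ln.strip():
            continue
        if not ln.startswith(">"):
            raise FormatError(f"{path}: sequence data before any FASTA header")
        break
    records: dict[str, str] = {}
    with path.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records[rec.id] = str(rec.seq).upper().replace("T", "U")
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# platform maps
# ---------------------------------------------------------------------------

def read_platform_map(path: str | Path) -> PlatformMap:
    """TSV with columns ``probe_id<TAB>gene_symbol`` (repeat lines for
    one-to-many probes)."""
    mapping: dict[str, list[str]] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{i}: expected 'probe<TAB>gene'")
        probe, gene = fields[0], fields[1]
        mapping.setdefault(probe, [])
        if gene not in mapping[probe]:
            mapping[probe].append(gene)
    return PlatformMap(mapping=mapping)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(network, path: str | Path, format: str = "edge_tsv") -> None:
    """Serialize a bipartite network as ``edge_tsv`` or ``graphml``.

    edge_tsv: one edge per line ``mirna<TAB>partner<TAB>weight`` after a
    header. GraphML nodes carry ``node_type`` (miRNA vs partner class)
    and ``direction`` attributes; edges carry ``weight``.
    """
    path = Path(path)
    if format == "edge_tsv":
        with path.open("w") as fh:
            fh.write("mirna\tpartner\tweight\n")
            for (left, right), w in sorted(network.edges.items()):
                fh.write(f"{left}\t{right}\t{w:.10g}\n")
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        for node, direction in network.left_nodes.items():
            g.add_node(node, node_type="miRNA", direction=direction or "")
        for node, direction in network.right_nodes.items():
            g.add_node(node, node_type=network.right_type, direction=direction or "")
        for (left, right), w in network.edges.items():
            g.add_edge(left, right, weight=float(w))
        nx.write_graphml(g, path)
    else:
        raise UsageError(f"unknown network format {format!r}")


def read_network_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """Read an edge_tsv file back into a (mirna, partner, weight) list."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["mirna", "partner"]:
        raise FormatError(f"{path}: missing edge_tsv header")
    edges = []
    for i, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{i}: expected 3 fields")
        edges.append((fields[0], fields[1], float(fields[2])))
    return edges


def read_degree_table(path: str | Path) -> pd.DataFrame:
    """Read a published network-characteristics table.

    Expected columns: ``node_type``, ``name``, ``degree``. Used for the
    fixtures transcribed from the TSCC study's printed degree tables.
    """
    df = pd.read_csv(path, sep="\t", dtype={"node_type": str, "name": str})
    expected = {"node_type", "name", "degree"}
    if not expected.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(expected)}")
    df["degree"] = df["degree"].astype(int)
    return df


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
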