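"""Intersection of predicted targets with differential expression.

"Negative correlation" here means opposite direction of differential
expression between a miRNA and its predicted target: the miRNA and mRNA
cohorts come from different patients, so sample-level correlation is
undefined and direction anti-concordance is the operative filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .data_io import PlatformMap, canonical_mirna_id
from .diffexpr import DEResult
from .errors import DomainError, UsageError
from .seed_targets import TargetPair

logger = logging.getLogger("mirmint")


@dataclass
class RegulatoryPair:
    """An anti-correlated miRNA -> gene regulatory candidate."""

    mirna_id: str
    mirna_direction: str
    gene_id: str
    gene_direction: str
    weight: float

    def __post_init__(self) -> None:
        if {self.mirna_direction, self.gene_direction} != {"up", "down"}:
            raise DomainError(
                f"{self.mirna_id}->{self.gene_id}: directions must be opposite"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)


def collapse_probes(
    results: Sequence[DEResult], platform_map: PlatformMap
) -> list[DEResult]:
    """Collapse probe-level DE results to gene level.

    Per gene the probe with the largest |log_fc| is representative (ties
    by smaller FDR, then probe id). Probes missing from the map are
    dropped with a logged count.
    """
    best: dict[str, DEResult] = {}
    n_unmapped = 0
    for r in results:
        genes = platform_map.genes_for(r.feature_id)
        if not genes:
            n_unmapped += 1
            continue
        for gene in genes:
            cur = best.get(gene)
            if cur is None or (
                (abs(r.log_fc), -r.fdr, r.feature_id)
                > (abs(cur.log_fc), -cur.fdr, cur.feature_id)
            ):
                best[gene] = r
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_unmapped)
    out = []
    for gene in sorted(best):
        r = best[gene]
        out.append(
            DEResult(
                feature_id=gene,
                log_fc=r.log_fc,
                fold_change=r.fold_change,
                mean_tumor=r.mean_tumor,
                mean_normal=r.mean_normal,
                t_stat=r.t_stat,
                p_value=r.p_value,
                fdr=r.fdr,
                direction=r.direction,
            )
        )
    return out


def intersect_and_filter(
    pairs: Sequence[TargetPair],
    de_mirnas: Sequence[DEResult],
    de_genes: Sequence[DEResult],
) -> list[RegulatoryPair]:
    """Keep predicted pairs whose miRNA and gene are both DE with
    opposite directions; weight = |log_fc_miRNA| * |log_fc_gene|.

    Features with log_fc exactly 0 carry no direction and never match.
    """
    mirna_by_id = {canonical_mirna_id(r.feature_id): r for r in de_mirnas}
    gene_by_id = {r.feature_id: r for r in de_genes}
    out: list[RegulatoryPair] = []
    seen: set[tuple[str, str]] = set()
    for p in sorted(pairs, key=lambda p: p.key):
        m = mirna_by_id.get(canonical_mirna_id(p.mirna_id))
        g = gene_by_id.get(p.gene_id)
        if m is None or g is None:
            continue
        if m.direction is None or g.direction is None:
            continue
        if m.direction == g.direction:
            continue
        key = (m.feature_id, g.feature_id)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            RegulatoryPair(
                mirna_id=m.feature_id,
                mirna_direction=m.direction,
                gene_id=g.feature_id,
                gene_direction=g.direction,
                weight=abs(m.log_fc) * abs(g.log_fc),
            )
        )
    return out


_PAIR_COLUMNS = ["mirna", "gene", "mirna_direction", "gene_direction", "weight"]


def write_pairs(pairs: Sequence[RegulatoryPair], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_PAIR_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.mirna_id}\t{p.gene_id}\t{p.mirna_direction}\t"
                f"{p.gene_direction}\t{format(p.weight, '.10g')}\n"
            )


def read_pairs(path: str | Path) -> list[RegulatoryPair]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _PAIR_COLUMNS:
        raise UsageError(f"{path}: not a regulatory-pair table (bad header)")
    out = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        f = ln.split("\t")
        out.append(
            RegulatoryPair(
                mirna_id=f[0],
                gene_id=f[1],
                mirna_direction=f[2],
                gene_direction=f[3],
                weight=float(f[4]),
            )
        )
    return out
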