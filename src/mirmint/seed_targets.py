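"""Seed-region target-site prediction on 3'UTR sequences.

Site classes follow the canonical seed-match taxonomy:

* 8mer      — exact Watson-Crick match to miRNA positions 2-8 followed
              (3'-ward on the UTR) by an A,
* 7mer-m8   — exact match to positions 2-8,
* 7mer-A1   — exact match to positions 2-7 followed by an A.

The UTR "A" anchoring the site is required to be a literal adenosine,
not a complement of the miRNA's first base. G:U wobble pairing is not
considered, and overlapping classifications collapse to the strongest
class (8mer > 7mer-m8 > 7mer-A1). Precomputed prediction tables can be
imported instead of running the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import DomainError, FormatError
from .data_io import canonical_mirna_id

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

SITE_8MER = "8mer"
SITE_7MER_M8 = "7mer-m8"
SITE_7MER_A1 = "7mer-A1"
# ordered strongest first
SITE_CLASSES = (SITE_8MER, SITE_7MER_M8, SITE_7MER_A1)


@dataclass
class SeedSite:
    """One predicted seed-match site on a UTR (0-based half-open)."""

    mirna_id: str
    gene_id: str
    site_type: str
    utr_start: int
    utr_end: int
    matched_sequence: str

    def __post_init__(self) -> None:
        width = self.utr_end - self.utr_start
        expected = 8 if self.site_type == SITE_8MER else 7
        if self.site_type not in SITE_CLASSES:
            raise DomainError(f"unknown site type {self.site_type!r}")
        if width != expected:
            raise DomainError(
                f"{self.site_type} site must span {expected} nt, got {width}"
            )
        if len(self.matched_sequence) != width:
            raise DomainError("matched_sequence length disagrees with coordinates")


@dataclass
class TargetPair:
    """A (miRNA, gene) interaction backed by one or more seed sites."""

    mirna_id: str
    gene_id: str
    n_sites: dict[str, int] = field(default_factory=dict)
    source: str = "predicted"

    def __post_init__(self) -> None:
        if self.source == "predicted" and self.total_sites < 1:
            raise DomainError("a predicted TargetPair needs at least one site")

    @property
    def total_sites(self) -> int:
        return sum(self.n_sites.values())

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)


def _check_rna(seq: str, what: str) -> None:
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise DomainError(
            f"{what} contains non-RNA letters {sorted(bad)}; "
            "normalize T->U before calling (read_fasta does this)"
        )


def reverse_complement(seq: str) -> str:
    _check_rna(seq, "sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def seed_of(mirna_sequence: str) -> str:
    """The 7-nt seed: nucleotides 2-8 (1-based) of the mature miRNA."""
    if len(mirna_sequence) < 8:
        raise DomainError("miRNA sequence must be at least 8 nt")
    _check_rna(mirna_sequence, "miRNA sequence")
    return mirna_sequence[1:8]


def site_patterns(mirna_sequence: str) -> dict[str, str]:
    """UTR-side match strings for each site class of one miRNA."""
    seed = seed_of(mirna_sequence)
    match_2_8 = reverse_complement(seed)  # pairs seed positions 2-8
    match_2_7 = reverse_complement(seed[:6])  # pairs seed positions 2-7
    return {
        SITE_8MER: match_2_8 + "A",
        SITE_7MER_M8: match_2_8,
        SITE_7MER_A1: match_2_7 + "A",
    }


def find_sites(
    mirna_sequence: str,
    utr_sequence: str,
    mirna_id: str = "",
    gene_id: str = "",
) -> list[SeedSite]:
    """All seed-match sites of one miRNA on one UTR, strongest class only.

    A weaker-class match whose interval is contained in a stronger-class
    site is suppressed (an 8mer always contains a 7mer-m8 and a 7mer-A1).
    """
    _check_rna(utr_sequence, "UTR sequence")
    patterns = site_patterns(mirna_sequence)
    sites: list[SeedSite] = []
    covered: list[tuple[int, int]] = []
    for site_type in SITE_CLASSES:
        pat = patterns[site_type]
        start = utr_sequence.find(pat)
        while start != -1:
            end = start + len(pat)
            contained = any(s <= start and end <= e for s, e in covered)
            if not contained:
                sites.append(
                    SeedSite(
                        mirna_id=mirna_id,
                        gene_id=gene_id,
                        site_type=site_type,
                        utr_start=start,
                        utr_end=end,
                        matched_sequence=utr_sequence[start:end],
                    )
                )
                covered.append((start, end))
            start = utr_sequence.find(pat, start + 1)
    sites.sort(key=lambda s: (s.utr_start, s.utr_end))
    return sites


def predict_targets(
    mirnas: Mapping[str, str], utrs: Mapping[str, str]
) -> list[TargetPair]:
    """Scan every (miRNA, UTR) combination; one pair per hit with >=1 site.

    Uses a substring pre-screen so the full site classifier only runs on
    candidate pairs; output order is deterministic by (mirna_id, gene_id).
    """
    if not mirnas or not utrs:
        raise DomainError("predict_targets requires non-empty sequence maps")
    pairs: list[TargetPair] = []
    pattern_cache = {mid: site_patterns(seq) for mid, seq in mirnas.items()}
    for mirna_id in sorted(mirnas):
        pats = pattern_cache[mirna_id]
        m8 = pats[SITE_7MER_M8]
        a1 = pats[SITE_7MER_A1]
        for gene_id in sorted(utrs):
            utr = utrs[gene_id]
            if m8 not in utr and a1 not in utr:
                continue
            sites = find_sites(mirnas[mirna_id], utr, mirna_id, gene_id)
            if not sites:
                continue
            counts: dict[str, int] = {}
            for s in sites:
                counts[s.site_type] = counts.get(s.site_type, 0) + 1
            pairs.append(
                TargetPair(
                    mirna_id=mirna_id,
                    gene_id=gene_id,
                    n_sites=counts,
                    source="predicted",
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# import / export
# ---------------------------------------------------------------------------

def import_predictions(path: str | Path) -> list[TargetPair]:
    """Read a prediction table with at least (mirna, gene) columns.

    Duplicate rows collapse to one pair; optional per-class site-count
    columns named after the site classes are summed across duplicates.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    if "mirna" not in header or "gene" not in header:
        raise FormatError(f"{path}: prediction table needs 'mirna' and 'gene' columns")
    idx = {name: header.index(name) for name in header}
    merged: dict[tuple[str, str], dict[str, int]] = {}
    order: list[tuple[str, str]] = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        f = ln.split("\t")
        key = (canonical_mirna_id(f[idx["mirna"]]), f[idx["gene"]])
        if key not in merged:
            merged[key] = {}
            order.append(key)
        for cls in SITE_CLASSES:
            if cls in idx and idx[cls] < len(f) and f[idx[cls]].strip():
                count = int(f[idx[cls]])
                if count:
                    merged[key][cls] = merged[key].get(cls, 0) + count
    return [
        TargetPair(mirna_id=m, gene_id=g, n_sites=dict(merged[(m, g)]), source="imported")
        for m, g in sorted(order)
    ]


def export_predictions(pairs: Sequence[TargetPair], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("mirna\tgene\t" + "\t".join(SITE_CLASSES) + "\n")
        for p in sorted(pairs, key=lambda p: p.key):
            counts = [str(p.n_sites.get(cls, 0)) for cls in SITE_CLASSES]
            fh.write(f"{p.mirna_id}\t{p.gene_id}\t" + "\t".join(counts) + "\n")


def write_site_table(sites: Sequence[SeedSite], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("mirna\tgene\tsite_type\tstart\tend\tsequence\n")
        for s in sites:
            fh.write(
                f"{s.mirna_id}\t{s.gene_id}\t{s.site_type}\t"
                f"{s.utr_start}\t{s.utr_end}\t{s.matched_sequence}\n"
            )
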