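"""Synthetic paired miRNA/mRNA cohorts with known ground truth.

Generates two-group log2 expression for one miRNA cohort and two mRNA
cohorts, a planted anti-regulatory miRNA -> target map whose seed sites
are implanted into the target UTRs (and screened out of every other
UTR), and gene-set annotations in which one "true" term oversamples the
planted genes. Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_io import (
    ExpressionMatrix,
    GeneSetCollection,
    write_expression,
    write_fasta,
    write_gene_sets,
    write_group_spec,
    write_json,
)
from .errors import UsageError
from .seed_targets import site_patterns, SITE_7MER_A1, SITE_7MER_M8, SITE_8MER

_BASES = np.array(list("ACGU"))


@dataclass
class SynthConfig:
    """Knobs for one synthetic dataset.

    Default cohort shapes mirror the study design this pipeline targets:
    15 vs 3 miRNA samples, 26 vs 12 test-cohort and 37 vs 20
    confirmation-cohort mRNA samples.
    """

    n_mirnas: int = 200
    n_genes: int = 2000
    mirna_samples: tuple[int, int] = (15, 3)  # (tumor, normal)
    mrna_test_samples: tuple[int, int] = (26, 12)
    mrna_confirm_samples: tuple[int, int] = (37, 20)
    n_de_mirnas: int = 20
    targets_per_de_mirna: int = 5
    mirna_effect: float = 3.0  # planted log2 shift in tumor samples
    mrna_effect: float = 2.0
    noise_sd: float = 0.5
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 30)
    enrichment_strength: float = 0.8  # fraction of the true term from planted genes
    utr_length: int = 120
    mirna_length: int = 22
    max_reject_attempts: int = 5  # rejection draws before in-place masking
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de_mirnas > self.n_mirnas:
            raise UsageError("n_de_mirnas cannot exceed n_mirnas")
        if self.n_de_mirnas * self.targets_per_de_mirna > self.n_genes:
            raise UsageError("planted targets cannot exceed n_genes")
        if self.noise_sd <= 0:
            raise UsageError("noise_sd must be positive")
        if not 0.0 <= self.enrichment_strength <= 1.0:
            raise UsageError("enrichment_strength must lie in [0,1]")
        if self.utr_length < 16:
            raise UsageError("utr_length too short to implant a site")


@dataclass
class SynthTruth:
    """Ground truth of one generated dataset."""

    de_mirnas: dict[str, int]  # id -> +1 (up in tumor) / -1 (down)
    de_genes: dict[str, int]
    target_map: dict[str, list[str]]  # miRNA -> planted target genes
    true_term_ids: list[str]

    def __post_init__(self) -> None:
        for mirna, genes in self.target_map.items():
            if mirna in self.de_mirnas:
                for g in genes:
                    if g in self.de_genes and self.de_genes[g] != -self.de_mirnas[mirna]:
                        raise UsageError(
                            f"target {g} of {mirna} violates anti-regulation"
                        )

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return {(m, g) for m, genes in self.target_map.items() for g in genes}

    def to_dict(self) -> dict:
        return {
            "de_mirnas": self.de_mirnas,
            "de_genes": self.de_genes,
            "target_map": self.target_map,
            "true_term_ids": self.true_term_ids,
        }


@dataclass
class SyntheticDataset:
    config: SynthConfig
    mirna_expr: ExpressionMatrix
    mrna_test_expr: ExpressionMatrix
    mrna_confirm_expr: ExpressionMatrix
    mirna_seqs: dict[str, str]
    utr_seqs: dict[str, str]
    gene_sets: GeneSetCollection
    truth: SynthTruth


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _make_mirna_sequences(
    rng: np.random.Generator, ids: Sequence[str], length: int
) -> dict[str, str]:
    """Random mature miRNA sequences with non-colliding site patterns.

    Two constraints keep UTR screening exact and masking feasible:
    pairwise-distinct seed patterns (no UTR window can be a site of two
    miRNAs), and no miRNA's implanted 8mer string may contain another
    miRNA's site pattern (otherwise a planted site could never be
    cleaned of foreign hits).
    """
    seqs: dict[str, str] = {}
    pat7: dict[str, str] = {}
    pat6: dict[str, str] = {}
    planted: dict[str, str] = {}
    for mid in ids:
        for _ in range(5000):
            seq = _random_seq(rng, length)
            pats = site_patterns(seq)
            x7 = pats[SITE_7MER_M8]
            x6 = pats[SITE_7MER_A1][:-1]
            p8 = pats[SITE_8MER]
            if x7 in pat7 or x6 in pat6:
                continue
            if _scan_hits(p8, pat7, pat6):
                continue  # candidate's 8mer contains an existing site
            if any(
                _scan_hits(p, {x7: mid}, {x6: mid}) for p in planted.values()
            ):
                continue  # an existing 8mer contains the candidate's site
            pat7[x7] = mid
            pat6[x6] = mid
            planted[mid] = p8
            seqs[mid] = seq
            break
        else:  # pragma: no cover - the pattern space never exhausts in practice
            raise RuntimeError("could not draw a miRNA with a fresh seed")
    return seqs


def _scan_hits(
    utr: str, pat7: Mapping[str, str], pat6: Mapping[str, str]
) -> list[tuple[str, int, int]]:
    """All (mirna_id, start, end) seed-match windows in one UTR."""
    hits = []
    L = len(utr)
    for i in range(L - 5):
        w7 = utr[i : i + 7]
        if len(w7) == 7 and w7 in pat7:
            hits.append((pat7[w7], i, i + 7))
        if i + 7 <= L:
            w6 = utr[i : i + 6]
            if i + 6 < L and w6 in pat6 and utr[i + 6] == "A":
                hits.append((pat6[w6], i, i + 7))
    return hits


def _make_utr(
    rng: np.random.Generator,
    length: int,
    pat7: Mapping[str, str],
    pat6: Mapping[str, str],
    planted_pattern: str | None,
    allowed_mirna: str | None,
    max_reject: int,
) -> str:
    """One UTR, free of seed sites except (optionally) those of one miRNA.

    Rejection-samples first; after ``max_reject`` failed draws the
    accidental windows are masked in place by point mutation, which
    always terminates because each mutation can only destroy sites.
    """
    for attempt in range(max_reject + 20):
        chars = list(_random_seq(rng, length))
        interval = None
        if planted_pattern is not None:
            pos = int(rng.integers(0, length - len(planted_pattern) + 1))
            chars[pos : pos + len(planted_pattern)] = list(planted_pattern)
            interval = (pos, pos + len(planted_pattern))
        utr = "".join(chars)
        accidental = [
            h for h in _scan_hits(utr, pat7, pat6) if h[0] != allowed_mirna
        ]
        if not accidental:
            return utr
        if attempt < max_reject:
            continue
        ok = True
        for _ in range(300):
            hit = accidental[0]
            positions = [
                p
                for p in range(hit[1], hit[2])
                if interval is None or not (interval[0] <= p < interval[1])
            ]
            if not positions:
                ok = False  # offending window sits inside the planted site
                break
            p = int(rng.choice(positions))
            alternatives = [b for b in "ACGU" if b != chars[p]]
            chars[p] = alternatives[int(rng.integers(0, 3))]
            utr = "".join(chars)
            accidental = [
                h for h in _scan_hits(utr, pat7, pat6) if h[0] != allowed_mirna
            ]
            if not accidental:
                return utr
        if ok:  # pragma: no cover - masking always converges or hits `ok=False`
            break
    raise RuntimeError("could not generate a screened UTR")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _make_matrix(
    rng: np.random.Generator,
    feature_ids: Sequence[str],
    prefix: str,
    n_tumor: int,
    n_normal: int,
    noise_sd: float,
    effects: Mapping[str, float],
) -> ExpressionMatrix:
    n_feat = len(feature_ids)
    base = rng.uniform(6.0, 12.0, size=n_feat)
    values = base[:, None] + rng.normal(0.0, noise_sd, size=(n_feat, n_tumor + n_normal))
    for i, fid in enumerate(feature_ids):
        eff = effects.get(fid, 0.0)
        if eff:
            values[i, :n_tumor] += eff
    sample_ids = [f"{prefix}_T{i + 1:02d}" for i in range(n_tumor)] + [
        f"{prefix}_N{i + 1:02d}" for i in range(n_normal)
    ]
    groups = ["tumor"] * n_tumor + ["normal"] * n_normal
    return ExpressionMatrix(
        feature_ids=list(feature_ids),
        sample_ids=sample_ids,
        groups=groups,
        values=values,
        scale="log2",
        platform_tag=f"synthetic-{prefix}",
    )


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def generate(config: SynthConfig) -> SyntheticDataset:
    """Generate the full synthetic bundle for one seed."""
    rng = np.random.default_rng(config.seed)
    mirna_ids = [f"hsa-miR-sim{i + 1:04d}" for i in range(config.n_mirnas)]
    gene_ids = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]

    # planted regulators and their disjoint target blocks
    de_idx = rng.choice(config.n_mirnas, size=config.n_de_mirnas, replace=False)
    de_mirna_ids = [mirna_ids[i] for i in sorted(de_idx)]
    signs = np.ones(config.n_de_mirnas, dtype=int)
    signs[1::2] = -1
    rng.shuffle(signs)
    target_idx = rng.choice(
        config.n_genes,
        size=config.n_de_mirnas * config.targets_per_de_mirna,
        replace=False,
    )
    target_map: dict[str, list[str]] = {}
    gene_sign: dict[str, int] = {}
    for k, mid in enumerate(de_mirna_ids):
        block = target_idx[
            k * config.targets_per_de_mirna : (k + 1) * config.targets_per_de_mirna
        ]
        genes = sorted(gene_ids[i] for i in block)
        target_map[mid] = genes
        for g in genes:
            gene_sign[g] = -int(signs[k])

    de_mirnas = (
        {mid: int(signs[k]) for k, mid in enumerate(de_mirna_ids)}
        if config.mirna_effect != 0
        else {}
    )
    de_genes = dict(gene_sign) if config.mrna_effect != 0 else {}

    # sequences
    mirna_seqs = _make_mirna_sequences(rng, mirna_ids, config.mirna_length)
    pat7: dict[str, str] = {}
    pat6: dict[str, str] = {}
    for mid, seq in mirna_seqs.items():
        pats = site_patterns(seq)
        pat7[pats[SITE_7MER_M8]] = mid
        pat6[pats[SITE_7MER_A1][:-1]] = mid
    gene_owner = {
        g: mid for mid, genes in target_map.items() for g in genes
    }
    utr_seqs: dict[str, str] = {}
    for g in gene_ids:
        owner = gene_owner.get(g)
        planted = site_patterns(mirna_seqs[owner])[SITE_8MER] if owner else None
        utr_seqs[g] = _make_utr(
            rng,
            config.utr_length,
            pat7,
            pat6,
            planted,
            owner,
            config.max_reject_attempts,
        )

    # expression (directly on log2 scale)
    mirna_effects = {m: s * config.mirna_effect for m, s in de_mirnas.items()}
    gene_effects = {g: s * config.mrna_effect for g, s in de_genes.items()}
    mirna_expr = _make_matrix(
        rng, mirna_ids, "miR",
        *config.mirna_samples, config.noise_sd, mirna_effects,
    )
    mrna_test = _make_matrix(
        rng, gene_ids, "test",
        *config.mrna_test_samples, config.noise_sd, gene_effects,
    )
    mrna_confirm = _make_matrix(
        rng, gene_ids, "conf",
        *config.mrna_confirm_samples, config.noise_sd, gene_effects,
    )

    # annotations: decoy terms plus one true term oversampling planted genes
    planted_genes = sorted(gene_sign)
    sets: dict[str, tuple[str, list[str]]] = {}
    lo, hi = config.term_size_range
    true_term_ids: list[str] = []
    for t in range(config.n_terms):
        term_id = f"TERM{t + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if t == 0 and de_genes:
            n_planted = min(int(round(config.enrichment_strength * size)),
                            len(planted_genes))
            chosen = list(
                rng.choice(planted_genes, size=n_planted, replace=False)
            )
            others = [g for g in gene_ids if g not in gene_sign]
            filler = list(
                rng.choice(others, size=size - n_planted, replace=False)
            )
            members = sorted(set(chosen + filler))
            true_term_ids.append(term_id)
            name = "true planted term"
        else:
            members = sorted(
                set(rng.choice(gene_ids, size=size, replace=False))
            )
            name = f"decoy term {t + 1}"
        sets[term_id] = (name, members)
    gene_sets = GeneSetCollection(sets=sets)

    truth = SynthTruth(
        de_mirnas=de_mirnas,
        de_genes=de_genes,
        target_map=target_map,
        true_term_ids=true_term_ids,
    )
    return SyntheticDataset(
        config=config,
        mirna_expr=mirna_expr,
        mrna_test_expr=mrna_test,
        mrna_confirm_expr=mrna_confirm,
        mirna_seqs=mirna_seqs,
        utr_seqs=utr_seqs,
        gene_sets=gene_sets,
        truth=truth,
    )


def score_recovery(
    outputs: Mapping[str, Iterable], truth: SynthTruth
) -> dict[str, dict[str, float | None]]:
    """Set-overlap sensitivity/precision per pipeline stage.

    ``outputs`` may contain ``de_mirnas``, ``de_genes`` (iterables of
    ids), ``pairs`` (iterables of (mirna, gene) tuples) and ``terms``.
    Undefined ratios (empty truth or empty output) are reported as None.
    """
    truth_sets: dict[str, set] = {
        "de_mirnas": set(truth.de_mirnas),
        "de_genes": set(truth.de_genes),
        "pairs": truth.pair_set,
        "terms": set(truth.true_term_ids),
    }
    metrics: dict[str, dict[str, float | None]] = {}
    for stage, out in outputs.items():
        if stage not in truth_sets:
            raise UsageError(f"unknown recovery stage {stage!r}")
        out_set = {tuple(x) if isinstance(x, (list, tuple)) else x for x in out}
        tset = truth_sets[stage]
        hit = len(out_set & tset)
        metrics[stage] = {
            "sensitivity": hit / len(tset) if tset else None,
            "precision": hit / len(out_set) if out_set else None,
        }
    return metrics


def write_all(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input format plus the truth JSON.

    Expression values are exponentiated to the linear scale on write so
    that the pipeline's log-transform path is exercised on re-read.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for name, matrix in [
        ("mirna", dataset.mirna_expr),
        ("mrna_test", dataset.mrna_test_expr),
        ("mrna_confirm", dataset.mrna_confirm_expr),
    ]:
        linear = matrix.copy()
        linear.values = 2.0 ** linear.values
        linear.scale = "linear"
        expr_path = outdir / f"{name}_expr.tsv"
        write_expression(linear, expr_path)
        groups_path = outdir / f"{name}_groups.tsv"
        write_group_spec(dict(zip(matrix.sample_ids, matrix.groups)), groups_path)
        paths[f"{name}_expr"] = expr_path
        paths[f"{name}_groups"] = groups_path

    paths["mirna_fasta"] = outdir / "mirnas.fasta"
    write_fasta(dataset.mirna_seqs, paths["mirna_fasta"])
    paths["utr_fasta"] = outdir / "utrs.fasta"
    write_fasta(dataset.utr_seqs, paths["utr_fasta"])
    paths["gene_sets"] = outdir / "terms.gmt"
    write_gene_sets(dataset.gene_sets, paths["gene_sets"])
    paths["truth"] = outdir / "truth.json"
    write_json(dataset.truth.to_dict(), paths["truth"])
    return paths
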