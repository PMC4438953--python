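"""Gene-set over-representation testing.

Each term is tested twice on the same 2x2 table: a one-sided Fisher
exact (hypergeometric tail) test and a Pearson chi-square test without
continuity correction. The run-level paired-test FDR is

    FDR = 1 - Nk / T

where Nk counts terms whose Fisher P falls below their chi-square P and
T is the number of terms tested. Fold enrichment is the standard ratio
(nf/n)/(Nf/N). A per-term Benjamini-Hochberg column on the Fisher P is
reported alongside for practical ranking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .data_io import GeneSetCollection
from .diffexpr import bh_adjust
from .errors import DomainError, UsageError

logger = logging.getLogger("mirmint")


@dataclass
class EnrichmentResult:
    """Per-term counts and statistics for one enrichment run."""

    term_id: str
    term_name: str
    nf: int  # query genes annotated to the term
    n: int  # query size
    Nf: int  # universe genes annotated to the term
    N: int  # universe size
    fisher_p: float
    chi2_p: float
    run_fdr: float  # 1 - Nk/T, shared by all terms of the run
    fold_enrichment: float
    bh_p: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.nf <= min(self.n, self.Nf) and self.n <= self.N and self.Nf <= self.N):
            raise DomainError(f"{self.term_id}: inconsistent counts")
        for p in (self.fisher_p, self.chi2_p, self.run_fdr, self.bh_p):
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"{self.term_id}: statistic outside [0,1]")


def _check_counts(nf, n, Nf, N) -> None:
    nf, n, Nf, N = (np.asarray(x) for x in (nf, n, Nf, N))
    ok = (
        (nf >= 0)
        & (nf <= np.minimum(n, Nf))
        & (n <= N)
        & (Nf <= N)
        & (N >= 1)
    )
    if not np.all(ok):
        raise DomainError("2x2 table counts violate 0 <= nf <= min(n, Nf) <= N")


def fisher_enrichment(nf, n, Nf, N):
    """One-sided over-representation P = P(X >= nf), X ~ Hypergeom(N, Nf, n).

    Accepts scalars or broadcastable arrays.
    """
    _check_counts(nf, n, Nf, N)
    p = stats.hypergeom.sf(np.asarray(nf) - 1, N, Nf, n)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(nf) or np.ndim(p) == 0 else p


def chi2_enrichment(nf, n, Nf, N) -> float:
    """Two-sided Pearson chi-square on [[nf, n-nf], [Nf-nf, N-n-Nf+nf]].

    No continuity correction, 1 df. A degenerate table (zero marginal)
    returns p = 1 with a warning.
    """
    _check_counts(nf, n, Nf, N)
    table = np.array([[nf, n - nf], [Nf - nf, N - n - Nf + nf]], dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    if np.any(row == 0) or np.any(col == 0) or total == 0:
        warnings.warn("degenerate 2x2 table (zero marginal); chi2 p set to 1",
                      stacklevel=2)
        return 1.0
    expected = np.outer(row, col) / total
    statistic = float(((table - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(statistic, df=1))


def paired_fdr(fisher_ps: Sequence[float], chi2_ps: Sequence[float]) -> float:
    """Run-level FDR = 1 - Nk/T with Nk = #{Fisher P < chi-square P}."""
    if len(fisher_ps) != len(chi2_ps):
        raise UsageError("fisher and chi-square p-value lists differ in length")
    t = len(fisher_ps)
    if t < 1:
        raise UsageError("paired_fdr needs at least one term test")
    nk = sum(1 for f, c in zip(fisher_ps, chi2_ps) if f < c)
    return 1.0 - nk / t


def enrich(
    query_genes: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Iterable[str] | None = None,
    max_p: float = 0.01,
    max_fdr: float | None = None,
) -> list[EnrichmentResult]:
    """Test every gene set against the query; one result per term hit.

    The universe defaults to all genes carrying at least one annotation.
    Query genes outside the universe are dropped with a logged count.
    Results are sorted by Fisher P ascending, ties by fold enrichment
    descending then term id; the ``significant`` flag applies ``max_p``
    to the Fisher P and ``max_fdr`` (when given) to the run-level FDR.
    """
    uni = list(dict.fromkeys(universe)) if universe is not None else gene_sets.default_universe()
    uni_set = set(uni)
    query = list(dict.fromkeys(query_genes))
    dropped = [g for g in query if g not in uni_set]
    if dropped:
        logger.info("enrich: dropped %d query genes outside the universe", len(dropped))
    query = [g for g in query if g in uni_set]
    if not query:
        raise UsageError("query is empty after intersecting with the universe")
    query_set = set(query)
    n = len(query)
    N = len(uni_set)

    rows = []
    for term_id in sorted(gene_sets.sets):
        members = [m for m in gene_sets.members(term_id) if m in uni_set]
        Nf = len(members)
        nf = sum(1 for m in members if m in query_set)
        if nf < 1:
            continue
        fisher_p = fisher_enrichment(nf, n, Nf, N)
        chi2_p = chi2_enrichment(nf, n, Nf, N)
        fold = (nf / n) / (Nf / N)
        rows.append((term_id, nf, Nf, fisher_p, chi2_p, fold))
    if not rows:
        return []

    run_fdr = paired_fdr([r[3] for r in rows], [r[4] for r in rows])
    bh = bh_adjust([r[3] for r in rows])
    results = []
    for (term_id, nf, Nf, fisher_p, chi2_p, fold), bh_p in zip(rows, bh):
        significant = fisher_p < max_p and (max_fdr is None or run_fdr < max_fdr)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=gene_sets.name(term_id),
                nf=nf,
                n=n,
                Nf=Nf,
                N=N,
                fisher_p=float(fisher_p),
                chi2_p=float(chi2_p),
                run_fdr=float(run_fdr),
                fold_enrichment=float(fold),
                bh_p=float(bh_p),
                significant=significant,
            )
        )
    results.sort(key=lambda r: (r.fisher_p, -r.fold_enrichment, r.term_id))
    return results


_ENRICH_COLUMNS = [
    "term_id",
    "term_name",
    "nf",
    "n",
    "Nf",
    "N",
    "fisher_p",
    "chi2_p",
    "fold_enrichment",
    "bh_p",
    "run_fdr",
    "neg_log10_p",
    "significant",
]


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    """TSV export; the -log10(P) column supports pathway histograms."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(_ENRICH_COLUMNS) + "\n")
        for r in results:
            neg_log = -np.log10(r.fisher_p) if r.fisher_p > 0 else np.inf
            fh.write(
                "\t".join(
                    [
                        r.term_id,
                        r.term_name,
                        str(r.nf),
                        str(r.n),
                        str(r.Nf),
                        str(r.N),
                        format(r.fisher_p, ".6g"),
                        format(r.chi2_p, ".6g"),
                        format(r.fold_enrichment, ".6g"),
                        format(r.bh_p, ".6g"),
                        format(r.run_fdr, ".6g"),
                        format(neg_log, ".6g"),
                        str(r.significant).lower(),
                    ]
                )
                + "\n"
            )
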