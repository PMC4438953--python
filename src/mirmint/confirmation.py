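"""Cross-cohort direction-concordance confirmation.

Candidate genes from the network are looked up in an independent cohort;
a gene counts as detected if present on the confirmation platform at
all, and as concordant if its differential-expression direction matches
the test cohort. Significance in the confirmation cohort is not
required — only direction is re-checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .data_io import write_json
from .diffexpr import DEResult
from .errors import UsageError


@dataclass
class ConcordanceReport:
    candidates: list[str]
    detected: list[str]
    concordant: list[str]
    discordant: list[dict[str, str]]  # {gene, dir_test, dir_confirm}

    def __post_init__(self) -> None:
        det = set(self.detected)
        con = set(self.concordant)
        dis = {d["gene"] for d in self.discordant}
        if con | dis != det or not det <= set(self.candidates):
            raise UsageError("inconsistent concordance report")

    @property
    def n_detected(self) -> int:
        return len(self.detected)

    @property
    def n_concordant(self) -> int:
        return len(self.concordant)

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "n_detected": self.n_detected,
            "n_concordant": self.n_concordant,
            "detected": self.detected,
            "concordant": self.concordant,
            "discordant": self.discordant,
        }

    def write(self, path: str | Path) -> None:
        write_json(self.to_dict(), path)


def confirm_directions(
    candidates: Sequence[str],
    de_test: Sequence[DEResult],
    de_confirm: Sequence[DEResult],
) -> ConcordanceReport:
    """Compare gene-level fold-change directions across two cohorts.

    ``de_test`` and ``de_confirm`` are full (unfiltered) gene-level DE
    results from the two cohorts. Candidates absent from either result
    set are excluded from ``detected``.
    """
    if not candidates:
        raise UsageError("confirm_directions requires a non-empty candidate list")
    test_dir = {r.feature_id: r.direction for r in de_test}
    confirm_dir = {r.feature_id: r.direction for r in de_confirm}
    cand = sorted(dict.fromkeys(candidates))
    detected = [g for g in cand if g in confirm_dir and g in test_dir]
    concordant = []
    discordant = []
    for g in detected:
        dt, dc = test_dir[g], confirm_dir[g]
        if dt is not None and dt == dc:
            concordant.append(g)
        else:
            discordant.append(
                {"gene": g, "dir_test": dt or "none", "dir_confirm": dc or "none"}
            )
    return ConcordanceReport(
        candidates=cand,
        detected=detected,
        concordant=concordant,
        discordant=discordant,
    )
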