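"""Proteome motif census and the Method-of-Exclusion candidate scan.

The census counts proteins carrying a short motif (the "NNI-ome" when the
motif is NNI), the total occurrences, and the pool of candidate anchor
methionines (excluding each protein's initiator Met).  The exclusion scan
then slides an 11-residue M-anchored window over motif-bearing proteins and
rejects any window whose positions 2..11 contain a residue outside the
reference peptide's alphabet; survivors are scored by how many distinct
residues of the reference set they cover.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .chem import Peptide

__all__ = [
    "ProteomeCensus",
    "CandidateWindow",
    "DEFAULT_FORBIDDEN",
    "DEFAULT_REFERENCE",
    "census",
    "exclusion_scan",
    "rank_candidates",
]

#: Residues absent from the reference 14mer, plus M (used up as the anchor).
DEFAULT_FORBIDDEN = frozenset("ARNDCQHISWY") | {"M"}
#: The nine distinct residues of the reference 14mer less its NNI tail.
DEFAULT_REFERENCE = frozenset("MKPLTGVEF")


@dataclass(frozen=True)
class ProteomeCensus:
    protein_count: int
    motif: str
    proteins_with_motif: int
    total_motif_occurrences: int
    met_count_excluding_initiators: int


@dataclass(frozen=True)
class CandidateWindow:
    """An M-anchored window surviving the Method of Exclusion."""

    protein_id: str
    start: int  # 1-based position of the anchoring M
    window: str
    distinct_score: int


def _count_occurrences(sequence: str, motif: str, overlapping: bool) -> int:
    if overlapping:
        return sum(
            1
            for i in range(len(sequence) - len(motif) + 1)
            if sequence[i : i + len(motif)] == motif
        )
    return sequence.count(motif)


def census(
    proteome: Sequence[Peptide],
    motif: str,
    overlapping: bool = True,
) -> ProteomeCensus:
    """Motif census over a proteome.

    The Met count excludes residue 1 of every protein when it is M (the
    simplest consistent reading of discounting initiator methionines).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not proteome:
        raise ValueError("empty proteome")
    with_motif = 0
    occurrences = 0
    mets = 0
    for protein in proteome:
        n = _count_occurrences(protein.sequence, motif, overlapping)
        if n:
            with_motif += 1
            occurrences += n
            mets += protein.sequence.count("M")
            if protein.sequence[0] == "M":
                mets -= 1
    return ProteomeCensus(
        protein_count=len(proteome),
        motif=motif,
        proteins_with_motif=with_motif,
        total_motif_occurrences=occurrences,
        met_count_excluding_initiators=mets,
    )


def exclusion_scan(
    proteome: Sequence[Peptide],
    window_len: int = 11,
    forbidden: frozenset[str] = DEFAULT_FORBIDDEN,
    reference: frozenset[str] = DEFAULT_REFERENCE,
    motif: str | None = "NNI",
) -> list[CandidateWindow]:
    """All M-anchored windows passing the exclusion filter, ranked.

    When ``motif`` is given, only motif-bearing proteins are scanned (the
    published procedure restricts the pool to the NNI-ome).  Anchor Ms
    exclude initiator methionines; windows truncated at protein ends are
    skipped.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    candidates: list[CandidateWindow] = []
    for protein in proteome:
        seq = protein.sequence
        if motif and motif not in seq:
            continue
        for i in range(len(seq) - window_len + 1):
            if seq[i] != "M":
                continue
            if i == 0:  # initiator Met is not a candidate anchor
                continue
            window = seq[i : i + window_len]
            if any(r in forbidden for r in window[1:]):
                continue
            score = len(set(window) & reference)
            candidates.append(
                CandidateWindow(
                    protein_id=protein.name or "",
                    start=i + 1,
                    window=window,
                    distinct_score=score,
                )
            )
    return rank_candidates(candidates)[0]


def rank_candidates(
    candidates: Iterable[CandidateWindow],
) -> tuple[list[CandidateWindow], dict[int, int]]:
    """Descending by distinct score (ties by protein id, then position),
    plus a score histogram."""
    ranked = sorted(
        candidates, key=lambda c: (-c.distinct_score, c.protein_id, c.start)
    )
    histogram = dict(Counter(c.distinct_score for c in ranked))
    return ranked, histogram
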