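"""In-silico tryptic digestion and digest-peak matching.

Trypsin cleaves C-terminal to K and R, except when the next residue is
proline (the K/R-P rule); fragments with up to ``max_missed`` internal
uncut sites are generated, along with methionine-sulfoxide (MSO) variants
(+15.9994 Da per oxidised Met).  Fragment MH+ values are average-mass
(hydrolysed peptide + 1.008), reported to four decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Sequence

from .chem import MET_OXIDATION, PROTON, WATER, Peptide, residue_sum
from .matching import FitReport, Peak, classify_match

__all__ = [
    "TrypticFragment",
    "DigestAssignment",
    "trypsin_digest",
    "fragment_mh",
    "match_digest",
]

DEFAULT_TOLERANCE = Decimal("4.0")


@dataclass(frozen=True)
class TrypticFragment:
    """A predicted tryptic fragment (1-based inclusive local coordinates)."""

    start: int
    end: int
    sequence: str
    missed_cleavages: int
    oxidized_met_count: int
    mh: Decimal

    def label(self) -> str:
        tag = f"{self.sequence} [{self.start}-{self.end}, {self.missed_cleavages} missed]"
        if self.oxidized_met_count:
            tag += f" +{self.oxidized_met_count}MSO"
        return tag


@dataclass(frozen=True)
class DigestAssignment:
    peak: Peak
    fragment: TrypticFragment
    difference: Decimal
    deviation: Decimal
    pct_error: Decimal
    match_class: str
    secondary: TrypticFragment | None = None


def _cleavage_sites(sequence: str) -> list[int]:
    """0-based indices *after* which trypsin cuts (K/R not followed by P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def fragment_mh(fragment: TrypticFragment) -> Decimal:
    """Average-mass MH+ including any Met oxidations."""
    return (
        residue_sum(fragment.sequence)
        + WATER
        + PROTON
        + fragment.oxidized_met_count * MET_OXIDATION
    )


def trypsin_digest(peptide: Peptide, max_missed: int = 1) -> list[TrypticFragment]:
    """All tryptic fragments with 0..max_missed missed cleavages.

    Met-oxidation variants are emitted as separate candidates, one per
    oxidation count 0..(number of Ms in the fragment).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = peptide.sequence
    cuts = _cleavage_sites(seq)
    bounds = [0] + [c + 1 for c in cuts] + [len(seq)]
    fragments: list[TrypticFragment] = []
    seen: set[tuple[int, int, int]] = set()
    for i in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            sub = seq[start:end]
            for ox in range(sub.count("M") + 1):
                key = (start, end, ox)
                if key in seen:
                    continue
                seen.add(key)
                fragments.append(
                    TrypticFragment(
                        start=start + 1,
                        end=end,
                        sequence=sub,
                        missed_cleavages=missed,
                        oxidized_met_count=ox,
                        mh=residue_sum(sub) + WATER + PROTON + ox * MET_OXIDATION,
                    )
                )
    return fragments


def match_digest(
    peaks: Sequence[Peak],
    fragments: Sequence[TrypticFragment],
    tolerance: Decimal | float = DEFAULT_TOLERANCE,
) -> tuple[list[DigestAssignment], FitReport | None]:
    """Assign each peak its best fragment within the tolerance.

    Candidates within the tolerance are ranked by fewer oxidations, then
    smaller deviation, then fewer missed cleavages: unmodified fragments are
    preferred over sulfoxide variants when both fit, which matches standard
    fingerprinting practice.  The runner-up (if any) is kept as the
    ``secondary`` candidate, preserving dual annotations.
    """
    tolerance = Decimal(str(tolerance))
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    assignments: list[DigestAssignment] = []
    for peak in peaks:
        in_window = [f for f in fragments if abs(peak.mz - f.mh) <= tolerance]
        if not in_window:
            continue
        ranked = sorted(
            in_window,
            key=lambda f: (
                f.oxidized_met_count,
                abs(peak.mz - f.mh),
                f.missed_cleavages,
            ),
        )
        best = ranked[0]
        mh4 = best.mh.quantize(Decimal("0.0001"))
        difference = peak.mz - mh4
        assignments.append(
            DigestAssignment(
                peak=peak,
                fragment=best,
                difference=difference,
                deviation=abs(difference),
                pct_error=100 * abs(difference) / mh4,
                match_class=classify_match(peak.mz, mh4),
                secondary=ranked[1] if len(ranked) > 1 else None,
            )
        )
    report = _digest_report(assignments) if assignments else None
    return assignments, report


def _digest_report(assignments: Sequence[DigestAssignment]) -> FitReport:
    n = len(assignments)
    sum_obs = sum((a.peak.mz for a in assignments), Decimal(0))
    mhs = [a.fragment.mh.quantize(Decimal("0.0001")) for a in assignments]
    sum_match = sum(mhs, Decimal(0))
    count = sum(1 for a in assignments if a.match_class in ("integer", "next_integer"))
    return FitReport(
        n=n,
        mean_deviation=sum((a.deviation for a in assignments), Decimal(0)) / n,
        mean_signed_difference=sum((a.difference for a in assignments), Decimal(0)) / n,
        mean_pct_error=sum((a.pct_error for a in assignments), Decimal(0)) / n,
        count_integer_or_next=count,
        pct_integer_or_next=Decimal(100) * count / n,
        sum_observed=sum_obs,
        sum_matched=sum_match,
        sum_ratio_pct=Decimal(100) * sum_obs / sum_match,
        chi_sq_quantity=sum(
            ((a.peak.mz - m) ** 2 / m for a, m in zip(assignments, mhs)), Decimal(0)
        ),
    )
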