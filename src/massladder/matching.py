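"""Assignment of observed MALDI peaks to ladder cells and fit statistics.

Peaks are matched to the nearest ladder cell of the published polarity
(MH+ cells for C-terminal ladders, unprotonated cells for N-terminal
ladders).  Matches are classified by the integer rule of the source
analysis: an *integer match* shares the unrounded whole number (decimal
fractions ignored, i.e. truncation, never rounding) and a *next-integer
match* is one whole number up or down.  Reported differences and the
aggregate fit statistics are computed against the two-decimal ``printed``
cell masses, which is how the published tables were tallied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Sequence

from .chem import PROTON, Peptide
from .ladder import Ladder, LadderCell, build_ladder

__all__ = [
    "Peak",
    "MatchAssignment",
    "FitReport",
    "ModelComparison",
    "SuperheavyweightAssignment",
    "read_peaklist",
    "write_peaklist",
    "classify_match",
    "best_assignment",
    "fit_report",
    "compare_truncation_models",
    "superheavyweight_search",
]

#: Default acceptance window (Da); the largest published accepted deviation
#: is 7.84, and the source states no explicit cutoff.
DEFAULT_WINDOW = Decimal("10.0")
#: Peaks below this m/z are flagged (instrument low-mass gate).
DEFAULT_LOW_MASS_GATE = Decimal("1000")


@dataclass(frozen=True)
class Peak:
    """An observed singly-charged m/z value with optional intensity."""

    mz: Decimal
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")


@dataclass(frozen=True)
class MatchAssignment:
    """An observed peak paired with its best ladder cell."""

    peak: Peak
    cell: LadderCell
    difference: Decimal  # observed - printed match (signed)
    deviation: Decimal  # |difference|
    pct_error: Decimal  # 100 * deviation / match
    match_class: str  # "integer" | "next_integer" | "loose"
    below_gate: bool = False

    @property
    def match(self) -> Decimal:
        return self.cell.printed


@dataclass(frozen=True)
class FitReport:
    """Aggregate statistics of a set of assignments (the published caption
    quantities)."""

    n: int
    mean_deviation: Decimal
    mean_signed_difference: Decimal
    mean_pct_error: Decimal
    count_integer_or_next: int
    pct_integer_or_next: Decimal
    sum_observed: Decimal
    sum_matched: Decimal
    sum_ratio_pct: Decimal
    chi_sq_quantity: Decimal

    def round3(self, value: Decimal) -> Decimal:
        return value.quantize(Decimal("0.001"))


@dataclass(frozen=True)
class ModelComparison:
    cterm: FitReport
    nterm: FitReport
    cterm_assignments: tuple[MatchAssignment, ...]
    nterm_assignments: tuple[MatchAssignment, ...]
    verdict: str | None  # "cterm" | "nterm" | None for no peaks


@dataclass(frozen=True)
class SuperheavyweightAssignment:
    """A peak above the full-length MH+ explained as a fragment dimer or
    multimer of dually decremented monomers."""

    peak: Peak
    label: str  # "homodimer" | "heterodimer" | "multimer"
    cells: tuple[LadderCell, ...]
    copies: int
    mass: Decimal
    difference: Decimal


def read_peaklist(path: str | Path) -> list[Peak]:
    """Read a plain-text peak list: 1-2 numeric columns, whitespace- or
    comma-delimited, ``#`` comment lines.  Duplicates and order preserved."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            try:
                mz = Decimal(fields[0])
                intensity = float(fields[1]) if len(fields) > 1 else None
            except (ArithmeticError, ValueError) as exc:
                raise ValueError(
                    f"{path}: non-numeric field on line {lineno}: {line!r}"
                ) from exc
            peaks.append(Peak(mz=mz, intensity=intensity))
    if not peaks:
        warnings.warn(f"{path}: no peaks found", stacklevel=2)
    return peaks


def write_peaklist(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            if p.intensity is None:
                fh.write(f"{p.mz}\n")
            else:
                fh.write(f"{p.mz}\t{p.intensity:g}\n")


def _intpart(x: Decimal) -> int:
    return int(x)  # truncation toward zero


def classify_match(observed: Decimal | float, match: Decimal | float) -> str:
    """Integer / next-integer / loose, on unrounded whole numbers."""
    o = Decimal(str(observed)) if not isinstance(observed, Decimal) else observed
    m = Decimal(str(match)) if not isinstance(match, Decimal) else match
    if o <= 0 or m <= 0:
        raise ValueError("observed and match must be positive")
    gap = abs(_intpart(o) - _intpart(m))
    if gap == 0:
        return "integer"
    if gap == 1:
        return "next_integer"
    return "loose"


def _assign(peak: Peak, cell: LadderCell, low_mass_gate: Decimal) -> MatchAssignment:
    difference = peak.mz - cell.printed
    deviation = abs(difference)
    return MatchAssignment(
        peak=peak,
        cell=cell,
        difference=difference,
        deviation=deviation,
        pct_error=100 * deviation / cell.printed,
        match_class=classify_match(peak.mz, cell.printed),
        below_gate=peak.mz < low_mass_gate,
    )


def best_assignment(
    peak: Peak,
    ladder: Ladder,
    window: Decimal | float = DEFAULT_WINDOW,
    low_mass_gate: Decimal | float = DEFAULT_LOW_MASS_GATE,
) -> MatchAssignment | None:
    """Nearest canonical cell within the window, or ``None``.

    Deviation is minimised on exact cell masses; ties break toward fewer
    waters, then the larger mer.
    """
    window = Decimal(str(window))
    gate = Decimal(str(low_mass_gate))
    if window <= 0:
        raise ValueError("window must be positive")
    cells = ladder.canonical_cells()
    if not cells:
        raise ValueError("empty ladder")
    best = min(cells, key=lambda c: (abs(peak.mz - c.mass), c.waters, -c.mer))
    if abs(peak.mz - best.mass) > window:
        return None
    return _assign(peak, best, gate)


def fit_report(assignments: Sequence[MatchAssignment]) -> FitReport:
    """Aggregate the published caption quantities over an assignment list.

    ``chi_sq_quantity`` is the raw statistic sum((O - M)^2 / M) over the
    pairs; the source reports this figure as its "chi-squared", without a
    stated degrees-of-freedom referral, so it is named as a quantity and
    not a p-value.
    """
    if not assignments:
        raise ValueError("fit_report needs at least one assignment")
    n = len(assignments)
    sum_obs = sum((a.peak.mz for a in assignments), Decimal(0))
    sum_match = sum((a.match for a in assignments), Decimal(0))
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
            (a.difference * a.difference / a.match for a in assignments), Decimal(0)
        ),
    )


def compare_truncation_models(
    peaks: Sequence[Peak],
    peptide: Peptide,
    window: Decimal | float = DEFAULT_WINDOW,
    mer_min: int = 60,
    water_max: int = 8,
) -> ModelComparison:
    """Fit the same peaks against C-terminal and N-terminal loss ladders.

    The verdict names the side with more integer/next-integer matches, ties
    resolved by lower mean deviation; ``None`` when no peak matches either
    side.
    """
    reports = {}
    assigns = {}
    for side in ("cterm", "nterm"):
        ladder = build_ladder(peptide, side=side, mer_min=mer_min, water_max=water_max)
        matched = [
            a for p in peaks if (a := best_assignment(p, ladder, window)) is not None
        ]
        assigns[side] = tuple(matched)
        reports[side] = fit_report(matched) if matched else None
    verdict: str | None = None
    rc, rn = reports["cterm"], reports["nterm"]
    if rc is not None or rn is not None:
        key = lambda r: (
            (-r.count_integer_or_next, r.mean_deviation) if r else (1, Decimal(0))
        )
        verdict = "cterm" if key(rc) <= key(rn) else "nterm"
    return ModelComparison(
        cterm=rc,
        nterm=rn,
        cterm_assignments=assigns["cterm"],
        nterm_assignments=assigns["nterm"],
        verdict=verdict,
    )


def superheavyweight_search(
    peaks: Sequence[Peak],
    ladder: Ladder,
    window: Decimal | float = DEFAULT_WINDOW,
    max_copies: int = 8,
) -> list[SuperheavyweightAssignment]:
    """Explain peaks above the full-length MH+ as fragment dimers/multimers.

    Monomer candidates are the cells assigned to the *other* peaks of the
    same list (mirroring the published sum-of-the-lowest-peaks reasoning);
    hypotheses are homodimers, heterodimers of distinct assigned cells, and
    stacked homomultimers up to ``max_copies``.
    """
    window = Decimal(str(window))
    full_mh = ladder.cell(ladder.mer_max, 0, True).mass
    monomer_cells: list[LadderCell] = []
    for p in peaks:
        if p.mz <= full_mh:
            a = best_assignment(p, ladder, window)
            if a is not None:
                monomer_cells.append(a.cell)
    out: list[SuperheavyweightAssignment] = []
    for p in peaks:
        if p.mz <= full_mh:
            continue
        hypotheses: list[tuple[str, tuple[LadderCell, ...], int, Decimal]] = []
        for i, a in enumerate(monomer_cells):
            for m in range(2, max_copies + 1):
                mass = a.mass + (m - 1) * (a.mass - PROTON)
                label = "homodimer" if m == 2 else "multimer"
                hypotheses.append((label, (a,), m, mass))
            for b in monomer_cells[i + 1 :]:
                if b is a:
                    continue
                mass = a.mass + (b.mass - PROTON)
                hypotheses.append(("heterodimer", (a, b), 2, mass))
        if not hypotheses:
            continue
        label, cells, copies, mass = min(hypotheses, key=lambda h: abs(p.mz - h[3]))
        if abs(p.mz - mass) <= window:
            out.append(
                SuperheavyweightAssignment(
                    peak=p,
                    label=label,
                    cells=cells,
                    copies=copies,
                    mass=mass,
                    difference=p.mz - mass,
                )
            )
    return out
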