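"""Dual-decrementation mass ladders and dimer/multimer hypotheses.

The model: a polypeptide of length L sheds C-terminal residues (a 70mer down
through 69-, 68-, ...mers) and, independently, integer numbers of waters
(w x 18.015 Da).  Truncated species follow the b-type convention (prefix
residue sum + 1.008); the full-length species is the hydrolysed peptide.
N-terminal-loss ladders (prefix shed instead of suffix) are the competing
model, published unprotonated.

Each cell carries two masses:

``mass``
    the exact model value (Decimal; residue sums are exact).

``printed``
    the two-decimal value as the source tables display it.  The published
    grids were generated from two-decimal Expasy MW displays, converted with
    the table constants (- 18.015 + 1.008), protonated (+ 1.008), and the
    water columns chained by repeated subtraction from the *displayed* MH+,
    with ties falling downward.  Mirroring that pipeline is what lets the
    package regenerate the published tables cell-for-cell; see
    docs/methods.md for the full derivation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_DOWN

from .chem import (
    PROTON,
    WATER,
    WATER_AVERAGE,
    Peptide,
    average_mass,
    btype_mass,
    residue_sum,
)

__all__ = ["LadderCell", "Ladder", "build_ladder", "nterm_match", "dimer_mass", "multimer_mass"]

_CENT = Decimal("0.01")


def _r2(x: Decimal) -> Decimal:
    # The source tables' spreadsheet provenance resolves two-decimal ties
    # downward (binary-float displays); reproduced deliberately.
    return x.quantize(_CENT, rounding=ROUND_HALF_DOWN)


@dataclass(frozen=True)
class LadderCell:
    """One predicted species: n-mer with w water losses, +- protonation."""

    side: str  # "cterm" | "nterm"
    mer: int
    waters: int
    protonated: bool
    mass: Decimal
    printed: Decimal
    lost_residues: str
    canonical: bool = True  # published polarity for this side

    @property
    def integer_part(self) -> int:
        """Unrounded whole number of the printed mass (truncation)."""
        return int(self.printed)

    def label(self) -> str:
        charge = "MH+" if self.protonated else "M"
        return f"{self.mer}mer/{self.waters}w {charge}"


class Ladder:
    """Complete cell grid over a mer range and water cap for one side."""

    def __init__(
        self,
        peptide: Peptide,
        side: str,
        mer_min: int,
        water_max: int,
    ) -> None:
        if side not in ("cterm", "nterm"):
            raise ValueError(f"side must be 'cterm' or 'nterm', got {side!r}")
        L = len(peptide)
        if not 1 <= mer_min <= L:
            raise ValueError(f"mer_min must be in 1..{L}, got {mer_min}")
        if water_max < 0:
            raise ValueError("water_max must be >= 0")
        self.peptide = peptide
        self.side = side
        self.mer_min = mer_min
        self.mer_max = L
        self.water_max = water_max
        self.cells: dict[tuple[int, int, bool], LadderCell] = {}
        for mer in range(mer_min, L + 1):
            self._build_row(mer)

    # -- construction ---------------------------------------------------

    def _row_sequences(self, mer: int) -> tuple[str, str]:
        seq = self.peptide.sequence
        if self.side == "cterm":
            return seq[:mer], "-" + seq[mer:] if mer < len(seq) else "-"
        kept = seq[len(seq) - mer :]
        lost = seq[: len(seq) - mer]
        return kept, (lost + "-") if lost else "-"

    def _build_row(self, mer: int) -> None:
        L = len(self.peptide)
        kept, lost = self._row_sequences(mer)
        s = residue_sum(kept)
        mw_disp = _r2(s + WATER_AVERAGE)  # the 2-dp Expasy MW display
        if self.side == "cterm":
            if mer == L:
                unprot = average_mass(self.peptide)
                unprot_disp = mw_disp
            else:
                unprot = s + PROTON  # b-type
                unprot_disp = _r2(mw_disp - WATER + PROTON)
            prot = unprot + PROTON
            prot_disp = _r2(unprot_disp + PROTON)
        else:
            unprot = s + WATER  # hydrolysed fragment, published unprotonated
            unprot_disp = mw_disp
            prot = unprot + PROTON
            prot_disp = _r2(unprot_disp + PROTON)
        canonical_protonated = self.side == "cterm"
        for protonated, base, base_disp in (
            (False, unprot, unprot_disp),
            (True, prot, prot_disp),
        ):
            for w in range(self.water_max + 1):
                self.cells[(mer, w, protonated)] = LadderCell(
                    side=self.side,
                    mer=mer,
                    waters=w,
                    protonated=protonated,
                    mass=base - w * WATER,
                    printed=_r2(base_disp - w * WATER),
                    lost_residues=lost,
                    canonical=(protonated == canonical_protonated),
                )

    # -- access ----------------------------------------------------------

    def cell(self, mer: int, waters: int, protonated: bool = True) -> LadderCell:
        return self.cells[(mer, waters, protonated)]

    def canonical_cells(self) -> list[LadderCell]:
        """The cells in the published polarity (MH+ for C-terminal ladders,
        unprotonated for N-terminal ladders)."""
        return [c for c in self.cells.values() if c.canonical]

    def __iter__(self):
        return iter(self.cells.values())

    def __len__(self) -> int:
        return len(self.cells)

    # -- export ----------------------------------------------------------

    def to_tsv(self) -> str:
        """Table-style layout: mer, lost residues, M, MH+ (or M only for
        N-terminal ladders), then the chained water columns."""
        lines = []
        if self.side == "cterm":
            header = ["mer", "lost_residues", "M", "MH+"] + [
                f"-{k}H2O" for k in range(1, self.water_max + 1)
            ]
            lines.append("\t".join(header))
            for mer in range(self.mer_max, self.mer_min - 1, -1):
                row = [str(mer), self.cell(mer, 0, False).lost_residues]
                row.append(str(self.cell(mer, 0, False).printed))
                row.extend(
                    str(self.cell(mer, w, True).printed)
                    for w in range(0, self.water_max + 1)
                )
                lines.append("\t".join(row))
        else:
            header = ["mer", "lost_residues", "M"] + [
                f"-{k}H2O" for k in range(1, self.water_max + 1)
            ]
            lines.append("\t".join(header))
            for mer in range(self.mer_max, self.mer_min - 1, -1):
                row = [str(mer), self.cell(mer, 0, False).lost_residues]
                row.extend(
                    str(self.cell(mer, w, False).printed)
                    for w in range(0, self.water_max + 1)
                )
                lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "side": c.side,
                    "mer": c.mer,
                    "waters": c.waters,
                    "protonated": c.protonated,
                    "mass": str(c.mass),
                    "printed": str(c.printed),
                    "lost_residues": c.lost_residues,
                }
                for c in self.cells.values()
            ],
            indent=2,
        )


def build_ladder(
    peptide: Peptide,
    side: str = "cterm",
    mer_min: int = 1,
    water_max: int = 8,
) -> Ladder:
    """Build the complete truncation x water-loss grid for one side.

    The default water cap of 8 matches the published grid's eight water
    columns; assignments wanting deeper losses need an explicit larger cap.
    """
    return Ladder(peptide, side, mer_min, water_max)


def nterm_match(peptide: Peptide, dropped_prefix_len: int, waters: int) -> Decimal:
    """Exact mass of the N-terminal-loss species (published unprotonated):
    suffix residue sum + water - waters x 18.015."""
    L = len(peptide)
    if not 0 <= dropped_prefix_len < L:
        raise ValueError(f"dropped prefix must be in 0..{L - 1}")
    suffix = peptide.sequence[dropped_prefix_len:]
    return residue_sum(suffix) + WATER - waters * WATER


def dimer_mass(a: LadderCell, b: LadderCell) -> Decimal:
    """Fragment dimer sharing one charge: MH+(a) + M(b) = MH+(a) + MH+(b) - 1.008."""
    if not (a.protonated and b.protonated):
        raise ValueError("dimer hypotheses are built from MH+ cells")
    return a.mass + (b.mass - PROTON)


def multimer_mass(cell: LadderCell, copies: int) -> Decimal:
    """m stacked copies sharing one charge: MH+ + (m - 1) x (MH+ - 1.008)."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if not cell.protonated:
        raise ValueError("multimer hypotheses are built from MH+ cells")
    return cell.mass + (copies - 1) * (cell.mass - PROTON)
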