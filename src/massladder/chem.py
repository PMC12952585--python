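"""Peptide sequences and average-isotopic-mass arithmetic.

This module holds the primitives every other module builds on: a validated
:class:`Peptide` container (optionally carrying master-protein position
offsets, so spliced proteoforms remember where their residues came from),
average-mass sums over the Expasy residue-mass table, b-type (acylium-like)
prefix masses, molecular formulae, a Bjellqvist/Expasy theoretical pI, and
the splice/variant constructors used to assemble proteoforms from a master
protein.

All mass arithmetic is done in :class:`decimal.Decimal`.  The residue table
carries four decimals, so sums are exact; this is what lets the truncation
ladders reproduce published two-decimal tables bit-for-bit instead of
drifting through binary floating point.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AVERAGE_RESIDUE_MASS",
    "WATER",
    "WATER_AVERAGE",
    "PROTON",
    "MET_OXIDATION",
    "AMINO_ACIDS",
    "Peptide",
    "MolecularFormula",
    "average_mass",
    "protonate",
    "btype_mass",
    "molecular_formula",
    "net_charge",
    "isoelectric_point",
    "splice_proteoform",
    "apply_variants",
    "read_fasta",
    "write_fasta",
]

#: Expasy average residue masses (Da), as used by Compute pI/Mw.
AVERAGE_RESIDUE_MASS: dict[str, Decimal] = {
    "G": Decimal("57.0519"),
    "A": Decimal("71.0788"),
    "S": Decimal("87.0782"),
    "P": Decimal("97.1167"),
    "V": Decimal("99.1326"),
    "T": Decimal("101.1051"),
    "C": Decimal("103.1388"),
    "L": Decimal("113.1594"),
    "I": Decimal("113.1594"),
    "N": Decimal("114.1038"),
    "D": Decimal("115.0886"),
    "Q": Decimal("128.1307"),
    "K": Decimal("128.1741"),
    "E": Decimal("129.1155"),
    "M": Decimal("131.1926"),
    "H": Decimal("137.1411"),
    "F": Decimal("147.1766"),
    "R": Decimal("156.1875"),
    "Y": Decimal("163.1760"),
    "W": Decimal("186.2132"),
}

#: Water mass used by the published tables (their column header value).
WATER = Decimal("18.015")
#: Average mass of water at full precision, used when mirroring Expasy MW displays.
WATER_AVERAGE = Decimal("18.01524")
#: Proton mass used by the published tables for MH+.
PROTON = Decimal("1.008")
#: Mass shift of methionine oxidation to the sulfoxide (MSO).
MET_OXIDATION = Decimal("15.9994")

AMINO_ACIDS = frozenset(AVERAGE_RESIDUE_MASS)

# Residue (i.e. water-free) elemental compositions, C/H/N/O/S.
_RESIDUE_FORMULA: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

# Standard atomic weights, for the formula-mass cross check only.
_ATOMIC_WEIGHT = {
    "C": Decimal("12.011"),
    "H": Decimal("1.008"),
    "N": Decimal("14.007"),
    "O": Decimal("15.999"),
    "S": Decimal("32.06"),
}

# Bjellqvist pKa set (the Expasy Compute pI/Mw values).
_PK_POSITIVE = {"K": 10.0, "R": 12.0, "H": 5.98}
_PK_NEGATIVE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_PK_NTERM_DEFAULT = 7.5
_PK_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
_PK_CTERM_DEFAULT = 3.55
_PK_CTERM = {"D": 4.55, "E": 4.75}


def _validate_sequence(sequence: str) -> None:
    for i, symbol in enumerate(sequence, start=1):
        if symbol not in AMINO_ACIDS:
            raise ValueError(
                f"unknown residue symbol {symbol!r} at position {i}"
            )
    if not sequence:
        raise ValueError("a peptide needs at least one residue")


@dataclass(frozen=True)
class Peptide:
    """An amino-acid sequence with 1-based positions.

    ``offsets``, when present, maps each local position to a position in a
    master protein (one entry per residue); spliced proteoforms use it to
    keep track of which master residues they were assembled from.
    """

    sequence: str
    name: str | None = None
    offsets: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        if self.offsets is not None and len(self.offsets) != len(self.sequence):
            raise ValueError("offsets must carry one master position per residue")

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]

    def master_position(self, position: int) -> int | None:
        """Master-protein position of a local 1-based position, if tracked."""
        if self.offsets is None:
            return None
        if not 1 <= position <= len(self.offsets):
            raise IndexError(f"position {position} outside 1..{len(self.offsets)}")
        return self.offsets[position - 1]


def _seq(p: Peptide | str) -> str:
    if isinstance(p, Peptide):
        return p.sequence
    _validate_sequence(p)
    return p


def residue_sum(p: Peptide | str) -> Decimal:
    """Sum of average residue masses (no water, no proton)."""
    return sum((AVERAGE_RESIDUE_MASS[r] for r in _seq(p)), Decimal(0))


def average_mass(p: Peptide | str) -> Decimal:
    """Average mass of the hydrolysed peptide: residue sum + one water."""
    return residue_sum(p) + WATER


def protonate(mass: Decimal | float) -> Decimal:
    """MH+: add one proton at 1.008 Da."""
    m = mass if isinstance(mass, Decimal) else Decimal(str(mass))
    if m < 0:
        raise ValueError("mass must be non-negative")
    return m + PROTON


def btype_mass(p: Peptide | str, n: int) -> Decimal:
    """Mass of the N-terminal n-residue species on the b-type convention.

    Truncated species carry no C-terminal hydroxyl: sum of the first ``n``
    residue masses plus one proton.  This is the convention that regenerates
    the published truncation table; the full-length species is the ordinary
    hydrolysed peptide and must go through :func:`average_mass` instead.
    """
    seq = _seq(p)
    if not 1 <= n < len(seq):
        raise ValueError(
            f"prefix length must satisfy 1 <= n < {len(seq)}, got {n}"
        )
    return residue_sum(seq[:n]) + PROTON


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts of a hydrolysed peptide (residues + one water)."""

    C: int
    H: int
    N: int
    O: int
    S: int

    def __str__(self) -> str:
        return f"C{self.C}H{self.H}N{self.N}O{self.O}S{self.S}"

    def mass(self) -> Decimal:
        """Formula mass from standard atomic weights (cross-check only)."""
        return sum(
            (_ATOMIC_WEIGHT[el] * getattr(self, el) for el in "CHNOS"), Decimal(0)
        )


def molecular_formula(p: Peptide | str) -> MolecularFormula:
    """Elemental composition: sum of residue formulas plus one water."""
    c = h = n = o = s = 0
    for r in _seq(p):
        rc, rh, rn, ro, rs = _RESIDUE_FORMULA[r]
        c += rc
        h += rh
        n += rn
        o += ro
        s += rs
    return MolecularFormula(C=c, H=h + 2, N=n, O=o + 1, S=s)


def net_charge(p: Peptide | str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (Bjellqvist pKa set)."""
    seq = _seq(p)
    pk_n = _PK_NTERM.get(seq[0], _PK_NTERM_DEFAULT)
    pk_c = _PK_CTERM.get(seq[-1], _PK_CTERM_DEFAULT)
    charge = 1.0 / (1.0 + 10.0 ** (ph - pk_n))
    charge -= 1.0 / (1.0 + 10.0 ** (pk_c - ph))
    for r in seq:
        if r in _PK_POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (ph - _PK_POSITIVE[r]))
        elif r in _PK_NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (_PK_NEGATIVE[r] - ph))
    return charge


def isoelectric_point(p: Peptide | str, tolerance: float = 0.005) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so plain bisection
    converges; the returned value is reported to two decimals by callers.
    """
    seq = _seq(p)
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance / 2.0:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def splice_proteoform(
    master: Peptide,
    segments: Sequence[tuple[int, int]],
    name: str | None = None,
) -> Peptide:
    """Concatenate 1-based inclusive master segments into a proteoform.

    The product remembers each residue's master position in ``offsets``, so
    e.g. a 9 + 61 reverse splice keeps both modules addressable in master
    coordinates.
    """
    if not segments:
        raise ValueError("at least one segment is required")
    pieces: list[str] = []
    offsets: list[int] = []
    for start, end in segments:
        if not (1 <= start <= end <= len(master)):
            raise ValueError(
                f"segment ({start}, {end}) outside master bounds 1..{len(master)}"
            )
        pieces.append(master.sequence[start - 1 : end])
        offsets.extend(range(start, end + 1))
    return Peptide("".join(pieces), name=name, offsets=tuple(offsets))


def apply_variants(
    p: Peptide,
    variants: Iterable[tuple[int, str]],
    name: str | None = None,
) -> Peptide:
    """Substitute residues at 1-based positions, returning a copy."""
    residues = list(p.sequence)
    for position, new in variants:
        if not 1 <= position <= len(residues):
            raise ValueError(f"position {position} outside 1..{len(residues)}")
        if new not in AMINO_ACIDS:
            raise ValueError(f"invalid residue {new!r} for position {position}")
        residues[position - 1] = new
    return Peptide("".join(residues), name=name or p.name, offsets=p.offsets)


def read_fasta(path: str | Path) -> list[Peptide]:
    """Read a single- or multi-record FASTA into peptides.

    The first whitespace-delimited token of each header is taken as the name
    (accession token).  Wrapped and unwrapped records are both fine.
    """
    peptides = []
    for record in SeqIO.parse(str(path), "fasta"):
        peptides.append(Peptide(str(record.seq).upper(), name=record.id))
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.name or f"peptide_{i}", description="")
        for i, p in enumerate(peptides, start=1)
    ]
    SeqIO.write(records, str(path), "fasta")
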