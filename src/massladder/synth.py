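"""Seeded generators for artefact-laden peak lists and decoy proteomes.

``simulate_peaklist`` forward-models the artefact taxonomy seen in the
study's spectra: dually decremented truncation species (an n-mer with w
water losses), fragment homodimers and stacked multimers, Gaussian m/z
noise, and uniform contaminant peaks.  Every emitted peak carries a truth
row, so recovery of (mer, waters, species) by the matcher is measurable.

``simulate_proteome`` emits decoy proteins with i.i.d. residues at
controlled frequencies and plants candidate windows at recorded positions,
giving the motif scan a ground-truthed test bed with no database download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Sequence

import numpy as np

from .chem import AVERAGE_RESIDUE_MASS, PROTON, Peptide
from .ladder import Ladder, build_ladder, multimer_mass
from .matching import Peak

__all__ = [
    "SpectrumEvent",
    "SpectrumRecipe",
    "TruthRow",
    "simulate_peaklist",
    "simulate_proteome",
]

_RESIDUES = sorted(AVERAGE_RESIDUE_MASS)


@dataclass(frozen=True)
class SpectrumEvent:
    """One true species in a simulated spectrum."""

    mer: int
    waters: int
    species: str = "monomer"  # "monomer" | "homodimer" | "multimer"
    copies: int = 1  # >1 for multimers (homodimer = 2)
    intensity: float = 100.0


@dataclass(frozen=True)
class SpectrumRecipe:
    peptide: Peptide
    events: tuple[SpectrumEvent, ...]
    mz_sd: float = 0.5
    n_contaminants: int = 0
    contaminant_range: tuple[float, float] = (1000.0, 9000.0)
    water_max: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_sd < 0:
            raise ValueError("mz_sd must be >= 0")
        L = len(self.peptide)
        for e in self.events:
            if not 1 <= e.mer <= L:
                raise ValueError(f"event mer {e.mer} outside 1..{L}")
            if not 0 <= e.waters <= self.water_max:
                raise ValueError(f"event waters {e.waters} outside 0..{self.water_max}")


@dataclass(frozen=True)
class TruthRow:
    mz: Decimal
    contaminant: bool
    mer: int | None = None
    waters: int | None = None
    species: str | None = None
    copies: int | None = None


def _event_mass(ladder: Ladder, event: SpectrumEvent) -> Decimal:
    cell = ladder.cell(event.mer, event.waters, protonated=True)
    if event.species == "monomer":
        return cell.mass
    copies = event.copies if event.copies > 1 else 2
    return multimer_mass(cell, copies)


def simulate_peaklist(recipe: SpectrumRecipe) -> tuple[list[Peak], list[TruthRow]]:
    """Generate an artefact-laden peak list plus its truth table.

    Deterministic under the recipe's seed; with ``mz_sd = 0`` peaks sit
    exactly at the model masses.  Intensities are log-normal around the
    event values (pass-through for matching, used only for base-peak
    identification).
    """
    rng = np.random.default_rng(recipe.seed)
    ladder = build_ladder(recipe.peptide, side="cterm", mer_min=1, water_max=recipe.water_max)
    peaks: list[Peak] = []
    truth: list[TruthRow] = []
    for event in recipe.events:
        mass = float(_event_mass(ladder, event))
        mz = mass + (rng.normal(0.0, recipe.mz_sd) if recipe.mz_sd > 0 else 0.0)
        intensity = float(event.intensity * rng.lognormal(0.0, 0.3))
        mzd = Decimal(f"{mz:.4f}")
        peaks.append(Peak(mz=mzd, intensity=intensity))
        truth.append(
            TruthRow(
                mz=mzd,
                contaminant=False,
                mer=event.mer,
                waters=event.waters,
                species=event.species,
                copies=event.copies if event.species != "monomer" else 1,
            )
        )
    lo, hi = recipe.contaminant_range
    for _ in range(recipe.n_contaminants):
        mz = rng.uniform(lo, hi)
        mzd = Decimal(f"{mz:.4f}")
        peaks.append(Peak(mz=mzd, intensity=float(rng.lognormal(2.0, 1.0))))
        truth.append(TruthRow(mz=mzd, contaminant=True))
    return peaks, truth


def simulate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (120, 600),
    residue_frequencies: dict[str, float] | None = None,
    planted_windows: Sequence[str] = (),
    seed: int = 0,
    ensure_motif: str | None = None,
) -> tuple[list[Peptide], list[tuple[int, int, str]]]:
    """Decoy proteome with i.i.d. residues and planted candidate windows.

    Each planted window goes into a distinct randomly chosen protein at a
    random interior position (never position 1); the return value includes
    the plant log as (protein index, 1-based start, window).  Proteins start
    with an initiator M, as real predicted proteomes do.  When
    ``ensure_motif`` is given, the motif is written into each host protein
    downstream of its planted window, so motif-restricted scans keep the
    hosts in the candidate pool (the real candidate protein carries the
    epitope motif elsewhere in its sequence).
    """
    if n_proteins < 0:
        raise ValueError("n_proteins must be >= 0")
    if n_proteins == 0:
        return [], []
    if residue_frequencies is None:
        freqs = np.full(len(_RESIDUES), 1.0 / len(_RESIDUES))
    else:
        freqs = np.array([residue_frequencies.get(r, 0.0) for r in _RESIDUES])
        if not np.isclose(freqs.sum(), 1.0, atol=1e-6):
            raise ValueError("residue frequencies must sum to 1")
        freqs = freqs / freqs.sum()
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n_proteins)
    proteins: list[list[str]] = []
    for i, L in enumerate(lengths):
        body = rng.choice(list(_RESIDUES), size=int(L), p=freqs)
        body[0] = "M"
        proteins.append(list(body))
    plants: list[tuple[int, int, str]] = []
    if planted_windows:
        if len(planted_windows) > n_proteins:
            raise ValueError("more planted windows than proteins")
        hosts = rng.choice(n_proteins, size=len(planted_windows), replace=False)
        for host, window in zip(hosts, planted_windows):
            L = len(proteins[host])
            need = len(window) + (len(ensure_motif) if ensure_motif else 0) + 2
            if L < need:
                raise ValueError("protein too short for planted window")
            limit = L - len(window) - (len(ensure_motif) if ensure_motif else 0)
            start = int(rng.integers(1, limit))  # 0-based, never 0
            proteins[host][start : start + len(window)] = list(window)
            if ensure_motif:
                proteins[host][L - len(ensure_motif) :] = list(ensure_motif)
            plants.append((int(host), start + 1, window))
    peptides = [
        Peptide("".join(p), name=f"decoy_{i:05d}") for i, p in enumerate(proteins)
    ]
    return peptides, plants
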