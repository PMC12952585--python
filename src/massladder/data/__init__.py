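"""Packaged fixtures: study peptides and published peak lists.

The peptide constants are the published study sequences.  The
canonical 70mer proteoform (``SSGII70``) is the 9 + 61 splice of the sheep
secretogranin II master protein (residues 367-375 followed by 178-238); the
sequence here was reconstructed from the study's printed constraints (tryptic
fragments, the C-terminal-loss column, the charged-residue census and the
Edman coverage map) and reproduces every published mass.  One caveat is
documented in docs/methods.md: position 25 is fixed by mass to an S->N (or
T->Q) substitution relative to the rat/human secretoneurin template, and N25
was chosen on homology grounds.

``load_master()`` returns a *synthetic* 400-residue scaffold whose segments
178-238 and 367-375 are the true proteoform modules; the genuine master
record is figure-only in the source and is not redistributed here.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..chem import Peptide, apply_variants, read_fasta

__all__ = [
    "EPL001",
    "EPL030",
    "EPL120",
    "SSGII14",
    "SSGII70",
    "BSGII70",
    "EDMAN_FACE_VALUES",
    "load_master",
    "fixture_path",
    "TABLE1_PEAKS",
    "MINOR_PEAKS",
    "DIGEST_PEAKS",
    "PRINTED_GRID",
]

#: The 14-residue Edman output sequence obtained from ovine material.
EPL001 = Peptide("MKPLTGKVKEFNNI", name="EPL001")

#: Scrambled-sequence control peptide.
EPL030 = Peptide("KLKMNGKNIEPVFT", name="EPL030")

#: Extended 20mer version of the Edman output.
EPL120 = Peptide("MKPLTGKVKEFNNIKGFGVI", name="EPL120")

#: The tripartite 14mer drawn from the master protein (9mer + FK + NNI); an
#: anagram of EPL001.
SSGII14 = Peptide("MLKTGEKPVFKNNI", name="sSgII-14")

# master positions of the 9 + 61 splice
_OFFSETS_70 = tuple(range(367, 376)) + tuple(range(178, 239))

#: The canonical ovine 70mer proteoform, spliced as master 367-375 + 178-238.
SSGII70 = Peptide(
    "MLKTGEKPVFKRTNEMVEEQYTPQNLATLESVFQELGKLTGPNNQKHERADEEQKLYTDDEDDIYKANNI",
    name="sSgII-70",
    offsets=_OFFSETS_70,
)

#: Bovine equivalent: ovine + M16I, N44S, H47R.
BSGII70 = apply_variants(SSGII70, [(16, "I"), (44, "S"), (47, "R")], name="bSgII-70")

#: Face values of the published shuffle-grid permutation: output (EPL001)
#: position i was read from input (sSgII-14) position EDMAN_FACE_VALUES[i-1].
EDMAN_FACE_VALUES = (1, 7, 8, 2, 4, 5, 11, 9, 3, 6, 10, 12, 13, 14)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture file."""
    return Path(str(resources.files(__package__) / name))


#: Packaged peak-list fixtures (two-column text, '#' comments).
TABLE1_PEAKS = "table1_ovine_peaks.tsv"
MINOR_PEAKS = "ovine_minor_peaks.tsv"
DIGEST_PEAKS = "digest_observed_peaks.tsv"
#: The published 11 x 10 truncation grid (60-70mers), transcribed verbatim.
PRINTED_GRID = "truncation_grid_printed.tsv"


def load_master() -> Peptide:
    """Synthetic master-protein scaffold carrying the true splice modules."""
    (master,) = read_fasta(fixture_path("sgii_master_synthetic.fasta"))
    return master
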