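"""The dual-decrementation ladder: C-terminal truncation x water losses.

Regenerates the published 60-70mer grid and shows a deep cell used by the
low-mass ramp analysis.
"""

import massladder as ml
from massladder.data import SSGII70

ladder = ml.build_ladder(SSGII70, side="cterm", mer_min=60, water_max=8)
print(ladder.to_tsv())
cell = ml.build_ladder(SSGII70, mer_min=7).cell(7, 5, True)
print(f"7mer with five water losses: MH+ {cell.printed} (integer part {cell.integer_part})")
print("Each row steps down by one residue mass; each column by 18.015 Da.")
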