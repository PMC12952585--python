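"""Forward-model a grand-fragment spectrum and recover it with the matcher.

Simulates the eight dually decremented species of an observed spectrum plus
a fragment homodimer and contaminants, then measures recovery.
"""

import massladder as ml
from massladder.data import SSGII70
from massladder.synth import SpectrumEvent, SpectrumRecipe

events = tuple(
    SpectrumEvent(mer=m, waters=w)
    for m, w in [(43, 7), (50, 5), (53, 3), (54, 8), (62, 1), (65, 2), (66, 0), (67, 4)]
) + (SpectrumEvent(43, 7, "homodimer", 2),)
recipe = SpectrumRecipe(peptide=SSGII70, events=events, mz_sd=0.3,
                        n_contaminants=5, seed=11)
peaks, truth = ml.simulate_peaklist(recipe)
ladder = ml.build_ladder(SSGII70, mer_min=7)
ok = total = 0
for peak, row in zip(peaks, truth):
    if row.contaminant or row.species != "monomer":
        continue
    total += 1
    a = ml.best_assignment(peak, ladder)
    hit = a and (a.cell.mer, a.cell.waters) == (row.mer, row.waters)
    ok += bool(hit)
print(f"monomer recovery: {ok}/{total}")
shw = ml.superheavyweight_search(peaks, ladder)
for s in shw:
    print(f"superheavyweight {s.peak.mz} -> {s.label} of {s.cells[0].label()}")
cmp_ = ml.compare_truncation_models(peaks, SSGII70, mer_min=7)
print(f"model verdict: {cmp_.verdict} (the generating side)")
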