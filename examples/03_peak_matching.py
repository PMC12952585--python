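"""Assign the twelve observed peaks and compare truncation models.

C-terminal truncation fits the observed spectrum far better than N-terminal
truncation - the model-comparison verdict printed last.
"""

import massladder as ml
from massladder.data import SSGII70, TABLE1_PEAKS, fixture_path

peaks = ml.read_peaklist(fixture_path(TABLE1_PEAKS))
cmp_ = ml.compare_truncation_models(peaks, SSGII70)

print("observed   mer waters match      diff   class")
for a in cmp_.cterm_assignments:
    print(f"{a.peak.mz:>8}  {a.cell.mer:>4} {a.cell.waters:>5}  {a.match:>8}"
          f"  {a.difference:>6}  {a.match_class}")
rep = cmp_.cterm
print(f"\nC-terminal: mean deviation {rep.round3(rep.mean_deviation)} Da, "
      f"mean error {rep.round3(rep.mean_pct_error)}%, "
      f"{rep.count_integer_or_next}/{rep.n} integer-or-next, "
      f"sum ratio {rep.round3(rep.sum_ratio_pct)}%, "
      f"chi-sq quantity {rep.round3(rep.chi_sq_quantity)}")
print(f"N-terminal: {cmp_.nterm.count_integer_or_next}/{cmp_.nterm.n} integer-or-next")
print(f"verdict: {cmp_.verdict}")
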