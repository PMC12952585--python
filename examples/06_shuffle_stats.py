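"""Riffle-shuffle analysis of the nonsequential Edman read-out.

The machine's output is an anagram of the input 14mer reachable in exactly
two riffle shuffles (cuts 6/8 then 7/7); its rising-sequence signature of 4
matches what two honest riffles of a deck typically produce.
"""

import massladder as ml
from massladder.data import EDMAN_FACE_VALUES, EPL001, SSGII14
from massladder.seqstats import replay_shuffles

print(f"input  (deck)  : {SSGII14.sequence}")
print(f"output (read)  : {EPL001.sequence}")
print(f"anagram        : {ml.is_anagram(SSGII14, EPL001)}")
print(f"bijections     : {len(ml.consistent_bijections(SSGII14, EPL001))}")
print(f"signature      : {ml.rising_sequences(EDMAN_FACE_VALUES)} rising sequences")
trace = ml.riffle_reachable(SSGII14, EPL001, max_shuffles=2)
print(f"riffle trace   : {len(trace)} shuffles, cuts {[s.cut for s in trace]}")
assert replay_shuffles(SSGII14, trace) == EPL001.sequence
print(f"P(4 charged + any uncharged in a 5-draw) = {ml.selection_probability(14, 4, 10)}")
print(f"P(4 charged + proline specifically)      = {ml.selection_probability(14, 4, 1)}")
sim = ml.gsr_signature_simulation(52, 2, 10_000, seed=1)
print(f"GSR null (52 cards, 2 shuffles): modal signature {sim['modal_signature']}")
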