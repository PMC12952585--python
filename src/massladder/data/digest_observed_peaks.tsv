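# Five observed tryptic-digest peaks (m/z) of the 70mer proteoform, as published.
906.3169
1278.4464
1298.0373
2094.4897
872.2498
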