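# Seven ovine minor peaks (m/z) below the 7-8000 range, as published.
6109.35
6070.58
5655.12
5070.90
4785.16
4755.85
4748.66
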