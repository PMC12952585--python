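# Twelve observed ovine MALDI peaks (m/z), 7-8000 range, as published.
7930.24
7878.47
7805.98
7709.72
7709.42
7628.30
7583.64
7565.93
7561.42
7484.53
7161.09
7102.24
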