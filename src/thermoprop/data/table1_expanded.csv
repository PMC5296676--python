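temperature_C,D_min,CI95_half_min
80,896.3,267.7
85,728.8,230.2
90,573.8,196.2
95,384.1,123.4
100,238.2,59.0
110,105.8,24.3
120,47.3,13.5
130,23.6,4.9
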