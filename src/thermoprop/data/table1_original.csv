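temperature_C,D_min,CI95_half_min
80,896.3,45.0
85,728.8,57.2
90,573.8,65.0
95,384.1,41.0
100,238.2,7.6
110,105.8,2.4
120,47.3,2.2
130,23.6,0.6
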