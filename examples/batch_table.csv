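dose_ug,titre_g_per_l,volume_l,batches
100,4,30,13544
100,6,30,9030
0.1,4,1,407
0.1,6,1,271
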