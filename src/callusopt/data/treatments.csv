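treatment_id,conc_24d,conc_bap,conc_kin,conc_naa
1,0.0,0.3,0.0,2.0
2,0.2,0.0,0.0,0.0
3,1.0,0.0,0.0,0.0
4,0.2,0.2,0.0,0.0
5,0.2,0.0,0.2,0.0
6,0.5,0.5,0.0,0.0
7,1.0,0.0,1.0,0.0
8,0.0,0.0,0.0,0.0
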