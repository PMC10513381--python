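# SYNTHETIC stand-in parameter table generated by scripts/make_synthetic_tables.py -- not published force-field values; see docs/methods.md.
key,r0_nm,k2,k3,k4
mrg_bond,0.651914,60.0,-120.0,600.0
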