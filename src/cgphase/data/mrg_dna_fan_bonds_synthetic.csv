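# SYNTHETIC stand-in parameter table generated by scripts/make_synthetic_tables.py -- not published force-field values; see docs/methods.md.
key,delta,r0_nm,k2,k3,k4
fan_-2,-2,1.791018,2.0,0.0,30.0
fan_-1,-1,1.8251,4.0,0.0,30.0
fan_0,0,1.753866,8.0,0.0,30.0
fan_1,1,1.579919,4.0,0.0,30.0
fan_2,2,1.362696,2.0,0.0,30.0
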