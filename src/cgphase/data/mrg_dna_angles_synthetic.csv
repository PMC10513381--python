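# SYNTHETIC stand-in parameter table generated by scripts/make_synthetic_tables.py -- not published force-field values; see docs/methods.md.
key,theta0_deg,k2,k3,k4
mrg_angle,149.4251,0.015,0.0,2e-05
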