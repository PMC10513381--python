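# One-bead-per-nucleotide registry: average nucleotide-monophosphate
# residue mass (amu), bead diameter sigma (nm), charge (e). DNA beads carry
# the full phosphate charge (screening is implicit via Debye-Hueckel); RNA
# beads use the reduced charge conventional for residue-level protein/RNA
# models.
kind,code,mass_amu,sigma_nm,charge_e
dna,A,313.21,0.65,-1.0
dna,C,289.18,0.65,-1.0
dna,G,329.21,0.65,-1.0
dna,T,304.20,0.65,-1.0
rna,A,329.21,0.84,-0.75
rna,C,305.18,0.84,-0.75
rna,G,345.21,0.84,-0.75
rna,U,306.17,0.84,-0.75
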