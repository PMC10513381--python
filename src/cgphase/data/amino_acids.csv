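# One-bead-per-residue amino-acid registry: average residue mass (amu),
# van-der-Waals diameter sigma (nm), charge (e). The HPS and MOFF families
# share mass, size and all charges except histidine.
code,name3,mass_amu,sigma_nm,charge_hps_e,charge_moff_e
A,ALA,71.0788,0.504,0.0,0.0
R,ARG,156.1875,0.656,1.0,1.0
N,ASN,114.1038,0.568,0.0,0.0
D,ASP,115.0886,0.558,-1.0,-1.0
C,CYS,103.1388,0.548,0.0,0.0
Q,GLN,128.1307,0.602,0.0,0.0
E,GLU,129.1155,0.592,-1.0,-1.0
G,GLY,57.0519,0.450,0.0,0.0
H,HIS,137.1411,0.608,0.5,0.25
I,ILE,113.1594,0.618,0.0,0.0
L,LEU,113.1594,0.618,0.0,0.0
K,LYS,128.1741,0.636,1.0,1.0
M,MET,131.1926,0.618,0.0,0.0
F,PHE,147.1766,0.636,0.0,0.0
P,PRO,97.1167,0.556,0.0,0.0
S,SER,87.0782,0.518,0.0,0.0
T,THR,101.1051,0.562,0.0,0.0
W,TRP,186.2132,0.678,0.0,0.0
Y,TYR,163.1760,0.646,0.0,0.0
V,VAL,99.1326,0.586,0.0,0.0
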