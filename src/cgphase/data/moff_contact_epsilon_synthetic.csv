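# SYNTHETIC stand-in parameter table generated by scripts/make_synthetic_tables.py -- not published force-field values; see docs/methods.md.
code,A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V
A,0.196,-0.315,-0.013,-0.05,0.101,0.045,0.006,0.139,0.045,0.366,0.366,0.045,0.272,0.385,0.385,0.101,0.158,0.347,0.29,0.309
R,-0.315,0.206,0.02,0.381,-0.163,-0.072,0.29,-0.224,-0.147,-0.588,-0.588,-0.372,-0.436,-0.619,-0.619,-0.163,-0.254,-0.558,-0.467,-0.497
N,-0.013,0.02,0.001,0.003,-0.007,-0.003,-0.0,-0.009,-0.003,-0.024,-0.024,-0.003,-0.017,-0.025,-0.025,-0.007,-0.01,-0.022,-0.019,-0.02
D,-0.05,0.381,0.003,-0.287,-0.026,-0.012,-0.302,-0.036,0.063,-0.094,-0.094,0.288,-0.07,-0.099,-0.099,-0.026,-0.041,-0.089,-0.075,-0.08
C,0.101,-0.163,-0.007,-0.026,0.053,0.023,0.003,0.072,0.023,0.19,0.19,0.023,0.141,0.199,0.199,0.053,0.082,0.18,0.15,0.16
Q,0.045,-0.072,-0.003,-0.012,0.023,0.01,0.001,0.032,0.01,0.084,0.084,0.01,0.062,0.088,0.088,0.023,0.036,0.079,0.066,0.071
E,0.006,0.29,-0.0,-0.302,0.003,0.001,-0.3,0.004,0.076,0.012,0.012,0.301,0.009,0.012,0.012,0.003,0.005,0.011,0.009,0.01
G,0.139,-0.224,-0.009,-0.036,0.072,0.032,0.004,0.099,0.032,0.26,0.26,0.032,0.193,0.274,0.274,0.072,0.112,0.247,0.206,0.22
H,0.045,-0.147,-0.003,0.063,0.023,0.01,0.076,0.032,-0.009,0.084,0.084,-0.065,0.062,0.088,0.088,0.023,0.036,0.079,0.066,0.071
I,0.366,-0.588,-0.024,-0.094,0.19,0.084,0.012,0.26,0.084,0.684,0.684,0.084,0.507,0.719,0.719,0.19,0.295,0.649,0.543,0.578
L,0.366,-0.588,-0.024,-0.094,0.19,0.084,0.012,0.26,0.084,0.684,0.684,0.084,0.507,0.719,0.719,0.19,0.295,0.649,0.543,0.578
K,0.045,-0.372,-0.003,0.288,0.023,0.01,0.301,0.032,-0.065,0.084,0.084,-0.29,0.062,0.088,0.088,0.023,0.036,0.079,0.066,0.071
M,0.272,-0.436,-0.017,-0.07,0.141,0.062,0.009,0.193,0.062,0.507,0.507,0.062,0.376,0.533,0.533,0.141,0.219,0.481,0.403,0.429
F,0.385,-0.619,-0.025,-0.099,0.199,0.088,0.012,0.274,0.088,0.719,0.719,0.088,0.533,0.756,0.756,0.199,0.311,0.682,0.571,0.608
P,0.385,-0.619,-0.025,-0.099,0.199,0.088,0.012,0.274,0.088,0.719,0.719,0.088,0.533,0.756,0.756,0.199,0.311,0.682,0.571,0.608
S,0.101,-0.163,-0.007,-0.026,0.053,0.023,0.003,0.072,0.023,0.19,0.19,0.023,0.141,0.199,0.199,0.053,0.082,0.18,0.15,0.16
T,0.158,-0.254,-0.01,-0.041,0.082,0.036,0.005,0.112,0.036,0.295,0.295,0.036,0.219,0.311,0.311,0.082,0.128,0.28,0.234,0.25
W,0.347,-0.558,-0.022,-0.089,0.18,0.079,0.011,0.247,0.079,0.649,0.649,0.079,0.481,0.682,0.682,0.18,0.28,0.615,0.515,0.548
Y,0.29,-0.467,-0.019,-0.075,0.15,0.066,0.009,0.206,0.066,0.543,0.543,0.066,0.403,0.571,0.571,0.15,0.234,0.515,0.431,0.459
V,0.309,-0.497,-0.02,-0.08,0.16,0.071,0.01,0.22,0.071,0.578,0.578,0.071,0.429,0.608,0.608,0.16,0.25,0.548,0.459,0.488
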