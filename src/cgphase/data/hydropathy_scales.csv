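# Normalized per-residue hydropathy lambda values: the Kapcha-Rossky (KR)
# scale and the Urry scale, both rescaled to [0, 1]. Dimensionless.
code,lambda_kr,lambda_urry
A,0.730,0.602942
R,0.000,0.558824
N,0.432,0.588236
D,0.378,0.294119
C,0.595,0.647060
Q,0.514,0.558824
E,0.459,0.000000
G,0.649,0.573530
H,0.514,0.764707
I,0.973,0.705883
L,0.973,0.720589
K,0.514,0.382354
M,0.838,0.676471
F,1.000,0.823530
P,1.000,0.758824
S,0.595,0.588236
T,0.676,0.588236
W,0.946,1.000000
Y,0.865,0.897059
V,0.892,0.664707
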