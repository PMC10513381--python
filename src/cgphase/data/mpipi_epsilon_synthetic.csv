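# SYNTHETIC stand-in parameter table generated by scripts/make_synthetic_tables.py -- not published force-field values; see docs/methods.md.
type,p:A,p:R,p:N,p:D,p:C,p:Q,p:E,p:G,p:H,p:I,p:L,p:K,p:M,p:F,p:P,p:S,p:T,p:W,p:Y,p:V,r:A,r:C,r:G,r:U
p:A,0.477,0.453,0.469,0.31,0.501,0.453,0.15,0.461,0.565,0.533,0.541,0.357,0.517,0.597,0.562,0.469,0.469,0.693,0.637,0.511,0.584,0.584,0.584,0.584
p:R,0.453,0.431,0.446,0.298,0.475,0.431,0.15,0.438,0.535,0.505,0.512,0.342,0.49,1.014,0.532,0.446,0.446,1.103,1.051,0.484,0.952,0.952,0.952,0.952
p:N,0.469,0.446,0.461,0.306,0.493,0.446,0.15,0.454,0.555,0.524,0.531,0.352,0.508,0.586,0.552,0.461,0.461,0.679,0.625,0.502,0.574,0.574,0.574,0.574
p:D,0.31,0.298,0.306,0.228,0.321,0.298,0.15,0.302,0.352,0.337,0.341,0.251,0.329,0.368,0.351,0.306,0.306,0.415,0.387,0.326,0.362,0.362,0.362,0.362
p:C,0.501,0.475,0.493,0.321,0.527,0.475,0.15,0.484,0.595,0.561,0.57,0.373,0.544,0.63,0.592,0.493,0.493,0.732,0.672,0.537,0.616,0.616,0.616,0.616
p:Q,0.453,0.431,0.446,0.298,0.475,0.431,0.15,0.438,0.535,0.505,0.512,0.342,0.49,0.564,0.532,0.446,0.446,0.653,0.601,0.484,0.552,0.552,0.552,0.552
p:E,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15,0.15
p:G,0.461,0.438,0.454,0.302,0.484,0.438,0.15,0.446,0.545,0.514,0.522,0.347,0.499,0.575,0.542,0.454,0.454,0.666,0.613,0.493,0.563,0.563,0.563,0.563
p:H,0.565,0.535,0.555,0.352,0.595,0.535,0.15,0.545,0.676,0.636,0.646,0.413,0.616,0.717,0.672,0.555,0.555,0.838,0.767,0.607,0.701,0.701,0.701,0.701
p:I,0.533,0.505,0.524,0.337,0.561,0.505,0.15,0.514,0.636,0.598,0.608,0.393,0.58,0.673,0.632,0.524,0.524,0.785,0.72,0.572,0.658,0.658,0.658,0.658
p:L,0.541,0.512,0.531,0.341,0.57,0.512,0.15,0.522,0.646,0.608,0.617,0.398,0.589,0.684,0.642,0.531,0.531,0.799,0.732,0.581,0.669,0.669,0.669,0.669
p:K,0.357,0.342,0.352,0.251,0.373,0.342,0.15,0.347,0.413,0.393,0.398,0.282,0.383,0.883,0.411,0.352,0.352,0.944,0.909,0.379,0.825,0.825,0.825,0.825
p:M,0.517,0.49,0.508,0.329,0.544,0.49,0.15,0.499,0.616,0.58,0.589,0.383,0.562,0.651,0.612,0.508,0.508,0.759,0.696,0.555,0.637,0.637,0.637,0.637
p:F,0.597,1.014,0.586,0.368,0.63,0.564,0.15,0.575,0.717,0.673,0.684,0.883,0.651,1.36,0.712,0.586,0.586,1.491,1.415,0.643,1.243,1.243,1.243,1.243
p:P,0.562,0.532,0.552,0.351,0.592,0.532,0.15,0.542,0.672,0.632,0.642,0.411,0.612,0.712,0.668,0.552,0.552,0.833,0.763,0.604,0.696,0.696,0.696,0.696
p:S,0.469,0.446,0.461,0.306,0.493,0.446,0.15,0.454,0.555,0.524,0.531,0.352,0.508,0.586,0.552,0.461,0.461,0.679,0.625,0.502,0.574,0.574,0.574,0.574
p:T,0.469,0.446,0.461,0.306,0.493,0.446,0.15,0.454,0.555,0.524,0.531,0.352,0.508,0.586,0.552,0.461,0.461,0.679,0.625,0.502,0.574,0.574,0.574,0.574
p:W,0.693,1.103,0.679,0.415,0.732,0.653,0.15,0.666,0.838,0.785,0.799,0.944,0.759,1.491,0.833,0.679,0.679,1.65,1.557,0.748,1.37,1.37,1.37,1.37
p:Y,0.637,1.051,0.625,0.387,0.672,0.601,0.15,0.613,0.767,0.72,0.732,0.909,0.696,1.415,0.763,0.625,0.625,1.557,1.474,0.687,1.296,1.296,1.296,1.296
p:V,0.511,0.484,0.502,0.326,0.537,0.484,0.15,0.493,0.607,0.572,0.581,0.379,0.555,0.643,0.604,0.502,0.502,0.748,0.687,0.548,0.629,0.629,0.629,0.629
r:A,0.584,0.952,0.574,0.362,0.616,0.552,0.15,0.563,0.701,0.658,0.669,0.825,0.637,1.243,0.696,0.574,0.574,1.37,1.296,0.629,1.026,1.026,1.026,1.026
r:C,0.584,0.952,0.574,0.362,0.616,0.552,0.15,0.563,0.701,0.658,0.669,0.825,0.637,1.243,0.696,0.574,0.574,1.37,1.296,0.629,1.026,1.026,1.026,1.026
r:G,0.584,0.952,0.574,0.362,0.616,0.552,0.15,0.563,0.701,0.658,0.669,0.825,0.637,1.243,0.696,0.574,0.574,1.37,1.296,0.629,1.026,1.026,1.026,1.026
r:U,0.584,0.952,0.574,0.362,0.616,0.552,0.15,0.563,0.701,0.658,0.669,0.825,0.637,1.243,0.696,0.574,0.574,1.37,1.296,0.629,1.026,1.026,1.026,1.026
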