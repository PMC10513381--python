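# SYNTHETIC stand-in parameter table generated by scripts/make_synthetic_tables.py -- not published force-field values; see docs/methods.md.
type,p:A,p:R,p:N,p:D,p:C,p:Q,p:E,p:G,p:H,p:I,p:L,p:K,p:M,p:F,p:P,p:S,p:T,p:W,p:Y,p:V,r:A,r:C,r:G,r:U
p:A,0.504,0.58,0.536,0.531,0.526,0.553,0.548,0.477,0.556,0.561,0.561,0.57,0.561,0.57,0.53,0.511,0.533,0.591,0.575,0.545,0.672,0.672,0.672,0.672
p:R,0.58,0.656,0.612,0.607,0.602,0.629,0.624,0.553,0.632,0.637,0.637,0.646,0.637,0.646,0.606,0.587,0.609,0.667,0.651,0.621,0.748,0.748,0.748,0.748
p:N,0.536,0.612,0.568,0.563,0.558,0.585,0.58,0.509,0.588,0.593,0.593,0.602,0.593,0.602,0.562,0.543,0.565,0.623,0.607,0.577,0.704,0.704,0.704,0.704
p:D,0.531,0.607,0.563,0.558,0.553,0.58,0.575,0.504,0.583,0.588,0.588,0.597,0.588,0.597,0.557,0.538,0.56,0.618,0.602,0.572,0.699,0.699,0.699,0.699
p:C,0.526,0.602,0.558,0.553,0.548,0.575,0.57,0.499,0.578,0.583,0.583,0.592,0.583,0.592,0.552,0.533,0.555,0.613,0.597,0.567,0.694,0.694,0.694,0.694
p:Q,0.553,0.629,0.585,0.58,0.575,0.602,0.597,0.526,0.605,0.61,0.61,0.619,0.61,0.619,0.579,0.56,0.582,0.64,0.624,0.594,0.721,0.721,0.721,0.721
p:E,0.548,0.624,0.58,0.575,0.57,0.597,0.592,0.521,0.6,0.605,0.605,0.614,0.605,0.614,0.574,0.555,0.577,0.635,0.619,0.589,0.716,0.716,0.716,0.716
p:G,0.477,0.553,0.509,0.504,0.499,0.526,0.521,0.45,0.529,0.534,0.534,0.543,0.534,0.543,0.503,0.484,0.506,0.564,0.548,0.518,0.645,0.645,0.645,0.645
p:H,0.556,0.632,0.588,0.583,0.578,0.605,0.6,0.529,0.608,0.613,0.613,0.622,0.613,0.622,0.582,0.563,0.585,0.643,0.627,0.597,0.724,0.724,0.724,0.724
p:I,0.561,0.637,0.593,0.588,0.583,0.61,0.605,0.534,0.613,0.618,0.618,0.627,0.618,0.627,0.587,0.568,0.59,0.648,0.632,0.602,0.729,0.729,0.729,0.729
p:L,0.561,0.637,0.593,0.588,0.583,0.61,0.605,0.534,0.613,0.618,0.618,0.627,0.618,0.627,0.587,0.568,0.59,0.648,0.632,0.602,0.729,0.729,0.729,0.729
p:K,0.57,0.646,0.602,0.597,0.592,0.619,0.614,0.543,0.622,0.627,0.627,0.636,0.627,0.636,0.596,0.577,0.599,0.657,0.641,0.611,0.738,0.738,0.738,0.738
p:M,0.561,0.637,0.593,0.588,0.583,0.61,0.605,0.534,0.613,0.618,0.618,0.627,0.618,0.627,0.587,0.568,0.59,0.648,0.632,0.602,0.729,0.729,0.729,0.729
p:F,0.57,0.646,0.602,0.597,0.592,0.619,0.614,0.543,0.622,0.627,0.627,0.636,0.627,0.636,0.596,0.577,0.599,0.657,0.641,0.611,0.738,0.738,0.738,0.738
p:P,0.53,0.606,0.562,0.557,0.552,0.579,0.574,0.503,0.582,0.587,0.587,0.596,0.587,0.596,0.556,0.537,0.559,0.617,0.601,0.571,0.698,0.698,0.698,0.698
p:S,0.511,0.587,0.543,0.538,0.533,0.56,0.555,0.484,0.563,0.568,0.568,0.577,0.568,0.577,0.537,0.518,0.54,0.598,0.582,0.552,0.679,0.679,0.679,0.679
p:T,0.533,0.609,0.565,0.56,0.555,0.582,0.577,0.506,0.585,0.59,0.59,0.599,0.59,0.599,0.559,0.54,0.562,0.62,0.604,0.574,0.701,0.701,0.701,0.701
p:W,0.591,0.667,0.623,0.618,0.613,0.64,0.635,0.564,0.643,0.648,0.648,0.657,0.648,0.657,0.617,0.598,0.62,0.678,0.662,0.632,0.759,0.759,0.759,0.759
p:Y,0.575,0.651,0.607,0.602,0.597,0.624,0.619,0.548,0.627,0.632,0.632,0.641,0.632,0.641,0.601,0.582,0.604,0.662,0.646,0.616,0.743,0.743,0.743,0.743
p:V,0.545,0.621,0.577,0.572,0.567,0.594,0.589,0.518,0.597,0.602,0.602,0.611,0.602,0.611,0.571,0.552,0.574,0.632,0.616,0.586,0.713,0.713,0.713,0.713
r:A,0.672,0.748,0.704,0.699,0.694,0.721,0.716,0.645,0.724,0.729,0.729,0.738,0.729,0.738,0.698,0.679,0.701,0.759,0.743,0.713,0.84,0.84,0.84,0.84
r:C,0.672,0.748,0.704,0.699,0.694,0.721,0.716,0.645,0.724,0.729,0.729,0.738,0.729,0.738,0.698,0.679,0.701,0.759,0.743,0.713,0.84,0.84,0.84,0.84
r:G,0.672,0.748,0.704,0.699,0.694,0.721,0.716,0.645,0.724,0.729,0.729,0.738,0.729,0.738,0.698,0.679,0.701,0.759,0.743,0.713,0.84,0.84,0.84,0.84
r:U,0.672,0.748,0.704,0.699,0.694,0.721,0.716,0.645,0.724,0.729,0.729,0.738,0.729,0.738,0.698,0.679,0.701,0.759,0.743,0.713,0.84,0.84,0.84,0.84
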