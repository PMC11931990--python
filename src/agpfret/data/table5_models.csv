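# Predicted per-position efficiencies for the candidate Agp1-Agp2 interaction
# models (40 docking poses, 3 manual arrangements, 1 AlphaFold tetramer), the
# published sum-of-squared-differences column as printed (its scale could not
# be reproduced and it is carried verbatim for reference only), and the four
# module-involvement flags.  Empty flags were not reported for that row.
model_id,E122,E362,E517,E535,E554,E603,sum_de2_printed,agp1_pcm,agp1_hk,agp2_pcm,agp2_hk
model.000.00,0.404,0.525,0.211,0.079,0.048,0.057,8.53,Yes,No,Yes,No
model.000.01,0.442,0.467,0.189,0.053,0.025,0.039,9.86,Yes,No,Yes,No
model.000.02,0.428,0.456,0.156,0.045,0.023,0.039,10.37,Yes,No,Yes,No
model.000.03,0.400,0.494,0.182,0.068,0.040,0.047,9.10,Yes,No,Yes,No
model.000.04,0.005,0.091,0.305,0.392,0.350,0.337,0.65,No,Yes,Yes,Yes
model.000.05,0.004,0.075,0.250,0.363,0.338,0.325,0.61,No,Yes,No,Yes
model.000.06,0.005,0.077,0.251,0.358,0.341,0.287,0.57,No,Yes,No,Yes
model.000.07,0.034,0.188,0.134,0.051,0.021,0.079,5.55,No,Yes,Yes,No
model.000.08,0.005,0.128,0.308,0.404,0.376,0.391,0.55,No,Yes,No,Yes
model.000.09,0.004,0.073,0.345,0.600,0.683,0.529,0.67,No,Yes,Yes,No
model.002.00,0.005,0.077,0.251,0.358,0.341,0.287,0.57,No,Yes,No,Yes
model.002.01,0.005,0.091,0.305,0.392,0.350,0.337,0.65,No,Yes,No,Yes
model.002.02,0.004,0.075,0.250,0.363,0.338,0.325,0.61,No,Yes,No,Yes
model.002.03,0.003,0.064,0.297,0.592,0.741,0.559,0.78,No,Yes,Yes,No
model.002.04,0.004,0.073,0.345,0.600,0.683,0.529,0.67,No,Yes,Yes,No
model.002.05,0.004,0.072,0.315,0.541,0.672,0.519,0.67,No,Yes,Yes,No
model.002.06,0.346,0.214,0.062,0.022,0.013,0.012,12.98,Yes,No,Yes,No
model.002.07,0.005,0.128,0.308,0.404,0.376,0.391,0.55,No,Yes,No,Yes
model.002.08,0.357,0.213,0.067,0.027,0.016,0.013,12.58,Yes,No,Yes,No
model.002.09,0.343,0.108,0.049,0.054,0.045,0.018,11.19,Yes,No,Yes,No
model.004.00,0.138,0.328,0.135,0.073,0.039,0.053,7.04,Yes,No,Yes,No
model.004.01,0.186,0.366,0.124,0.034,0.016,0.044,9.92,Yes,No,Yes,No
model.004.02,0.131,0.221,0.142,0.075,0.034,0.044,5.42,Yes,No,Yes,No
model.004.03,0.005,0.113,0.183,0.183,0.151,0.271,1.17,No,Yes,Yes,No
model.004.04,0.019,0.294,0.295,0.311,0.309,0.377,0.81,No,Yes,Yes,No
model.004.05,0.157,0.319,0.091,0.026,0.013,0.036,10.53,Yes,No,Yes,No
model.004.06,0.027,0.348,0.352,0.315,0.294,0.382,1.12,No,Yes,Yes,No
model.004.07,0.005,0.104,0.188,0.184,0.133,0.249,1.27,No,Yes,Yes,No
model.004.08,0.016,0.111,0.098,0.072,0.050,0.163,2.50,Yes,Yes,Yes,Yes
model.004.09,0.014,0.108,0.104,0.079,0.061,0.206,2.61,Yes,Yes,Yes,Yes
model.006.00,0.037,0.400,0.510,0.399,0.304,0.348,1.52,No,Yes,Yes,No
model.006.01,0.036,0.467,0.491,0.384,0.304,0.480,1.60,No,Yes,Yes,No
model.006.02,0.029,0.369,0.534,0.427,0.323,0.472,1.33,No,Yes,Yes,No
model.006.03,0.054,0.349,0.213,0.165,0.149,0.206,2.55,No,Yes,Yes,No
model.006.04,0.055,0.221,0.288,0.234,0.137,0.436,2.03,No,Yes,Yes,No
model.006.05,0.097,0.530,0.344,0.150,0.057,0.217,5.57,Yes,No,Yes,No
model.006.06,0.009,0.173,0.427,0.465,0.396,0.457,0.73,Yes,No,Yes,No
model.006.07,0.034,0.437,0.492,0.396,0.273,0.450,1.67,No,Yes,Yes,No
model.006.08,0.090,0.452,0.318,0.144,0.058,0.211,4.96,Yes,No,Yes,No
model.006.09,0.071,0.514,0.264,0.160,0.109,0.249,4.55,No,Yes,Yes,No
manual.parallel,0.307,0.250,0.191,0.148,0.114,0.101,3.49,,,,
manual.vertical,0.052,0.431,0.316,0.161,0.091,0.301,3.92,,,,
manual.antiparallel,0.087,0.181,0.379,0.400,0.288,0.403,0.72,,,,
alphafold.ranked0,0.400,0.591,0.274,0.166,0.037,0.024,8.08,,,,
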