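patient,1G-BF,1G-BE,2G-BF,2G-EF,2G-BE,2G-EE
P1,0.028,0.289,0.024,0.295,0.441,0.143
P2,0.144,0.425,0.115,0.495,0.698,0.262
P3,0.029,0.327,0.042,0.330,0.498,0.159
P4,0.053,0.356,0.087,0.357,0.534,0.219
P5,0.033,0.444,0.036,0.496,0.653,0.124
P6,0.017,0.484,0.012,0.480,0.663,0.109
P7,0.016,0.463,0.011,0.449,0.658,0.100
P8,0.031,0.401,0.016,0.367,0.565,0.119
P9,0.091,0.662,0.056,0.588,0.783,0.212
P10,0.137,0.489,0.136,0.494,0.649,0.273
P11,0.038,0.230,0.040,0.231,0.373,0.153
P12,0.010,0.416,0.009,0.510,0.672,0.091
P13,0.160,0.658,0.030,0.500,0.743,0.159
P14,0.012,0.442,0.017,0.440,0.621,0.101
P15,0.142,0.515,0.110,0.463,0.657,0.250
P16,0.044,0.335,0.024,0.304,0.481,0.142
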