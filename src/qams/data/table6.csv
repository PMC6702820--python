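sample_type,sample_no,emodin-8-O-glc,physcion-8-O-glc,emodin,physcion,f_printed
radix,001,0.165,0.047,0.013,0.004,12.72
radix,002,0.382,0.116,0.034,0.011,11.07
radix,003,5.255,1.954,0.559,0.17,9.89
radix,004,0.106,0.061,0.012,0.005,9.6
radix,005,0.338,0.102,0.038,0.011,8.87
radix,006,3.593,1.474,0.533,0.17,7.21
radix,007,1.053,0.766,0.189,0.072,6.97
radix,008,4.36,2.128,0.737,0.21,6.85
radix,009,1.768,0.862,0.291,0.099,6.74
radix,010,0.326,0.1,0.057,0.017,5.73
radix,011,1.456,0.622,0.286,0.079,5.69
radix,012,1.301,0.527,0.246,0.079,5.62
radix,013,2.206,0.953,0.45,0.132,5.43
radix,014,1.575,0.714,0.31,0.115,5.39
radix,015,2.153,1.007,0.432,0.158,5.36
radix,016,2.747,0.994,0.528,0.179,5.29
radix,017,1.292,0.415,0.25,0.075,5.25
radix,018,4.585,1.853,0.93,0.317,5.16
radix,019,2.226,0.927,0.483,0.149,4.99
radix,020,1.488,0.781,0.334,0.125,4.94
radix,021,2.335,1.051,0.538,0.195,4.62
radix,022,2.709,1.324,0.686,0.226,4.42
radix,023,1.378,1.309,0.439,0.184,4.31
radix,024,3.601,1.446,0.902,0.286,4.25
radix,025,2.223,0.859,0.584,0.17,4.09
radix,026,0.922,0.589,0.247,0.123,4.08
radix,027,2.15,0.79,0.576,0.246,3.58
radix,028,2.263,1.002,0.709,0.227,3.49
radix,029,1.369,0.808,0.469,0.17,3.41
radix,030,0.068,0.042,0.024,0.009,3.33
radix,031,1.591,0.57,0.432,0.223,3.3
radix,032,2.235,0.836,0.694,0.249,3.26
radix,033,0.188,0.07,0.057,0.024,3.19
radix,034,1.569,1.168,0.33,0.581,3
radix,035,1.911,0.715,0.658,0.226,2.97
radix,036,3.089,1.6,1.204,0.411,2.9
radix,037,3.694,1.407,1.384,0.476,2.74
radix,038,0.971,0.462,0.297,0.23,2.72
radix,039,0.822,0.483,0.333,0.156,2.67
radix,040,0.733,0.284,0.295,0.101,2.57
radix,041,0.67,0.563,0.332,0.166,2.48
radix,042,2.894,1.031,1.325,0.379,2.3
radix,043,2.446,0.916,1.123,0.398,2.21
radix,044,1.662,0.58,0.752,0.276,2.18
radix,045,2.693,1.183,1.421,0.425,2.1
radix,046,1.777,0.735,1.004,0.349,1.86
radix,047,0.747,0.467,0.448,0.215,1.83
radix,048,0.085,0.035,0.043,0.024,1.8
radix,049,1.822,0.585,1.032,0.365,1.72
radix,050,0.063,0.042,0.045,0.018,1.68
radix,051,1.499,0.29,0.818,0.255,1.67
radix,052,0.099,0.039,0.064,0.02,1.65
radix,053,0.106,0.04,0.069,0.022,1.61
radix,054,0.104,0.038,0.071,0.021,1.54
radix,055,1.237,0.447,0.841,0.29,1.49
radix,056,0.59,0.194,0.404,0.124,1.49
radix,057,0.141,0.055,0.089,0.046,1.45
radix,058,1.879,0.712,1.407,0.443,1.4
radix,059,1.328,0.55,1.05,0.313,1.38
radix,060,0.072,0.024,0.054,0.017,1.35
radix,061,1.245,0.481,1.047,0.308,1.27
radix,062,0.365,0.33,0.361,0.218,1.2
radix,063,0.935,0.448,0.771,0.441,1.14
radix,064,0.5,0.185,0.462,0.138,1.14
radix,065,0.06,0.021,0.059,0.019,1.06
radix,066,0.092,0.026,0.091,0.03,0.97
preaparata,001,0.044,0.028,0.008,0.004,5.61
preaparata,002,2.278,0.889,1.002,0.326,2.38
preaparata,003,0.058,0.029,0.031,0.016,1.83
preaparata,004,4.461,1.584,2.528,0.796,1.82
preaparata,005,2.42,0.774,1.69,0.521,1.44
preaparata,006,0.33,0.098,0.228,0.074,1.41
preaparata,007,1.651,0.535,1.083,0.482,1.4
preaparata,008,0.204,0.06,0.181,0.056,1.12
preaparata,009,1.559,0.589,1.387,0.551,1.11
preaparata,010,2.229,0.835,2.173,0.72,1.06
preaparata,011,2.278,0.784,2.511,0.75,0.94
preaparata,012,0.105,0.04,0.109,0.045,0.94
preaparata,013,0.108,0.02,0.12,0.037,0.82
preaparata,014,0.077,0.029,0.107,0.038,0.73
preaparata,015,0.06,0.03,0.089,0.041,0.69
preaparata,016,0.697,0.271,1.056,0.383,0.67
preaparata,017,0.776,0.247,1.173,0.436,0.64
preaparata,018,0.119,0.036,0.188,0.066,0.61
preaparata,019,0.454,0.195,0.749,0.326,0.6
preaparata,020,1.252,0.364,2.138,0.657,0.58
preaparata,021,0.902,0.207,1.391,0.529,0.58
preaparata,022,0.1,0.032,0.173,0.055,0.58
preaparata,023,1.234,0.446,2.333,0.704,0.55
preaparata,024,0.994,0.345,1.897,0.622,0.53
preaparata,025,1.378,0.426,2.585,0.865,0.52
preaparata,026,0.557,0.197,1.083,0.373,0.52
preaparata,027,0.079,0.028,0.152,0.054,0.52
preaparata,028,1.93,0.669,3.834,1.303,0.51
preaparata,029,0.911,0.332,1.635,0.824,0.51
preaparata,030,0.109,0.022,0.194,0.062,0.51
preaparata,031,0.058,0.024,0.112,0.049,0.51
preaparata,032,0.68,0.16,1.292,0.434,0.49
preaparata,033,0.089,0.03,0.183,0.067,0.48
preaparata,034,0.073,0.023,0.151,0.049,0.48
preaparata,035,0.566,0.193,1.163,0.456,0.47
preaparata,036,0.064,0.024,0.14,0.046,0.47
preaparata,037,2.114,0.718,4.527,1.622,0.46
preaparata,038,0.52,0.223,1.211,0.433,0.45
preaparata,039,0.111,0.031,0.236,0.08,0.45
preaparata,040,0.116,0.037,0.251,0.085,0.45
preaparata,041,0.047,0.015,0.103,0.042,0.43
preaparata,042,0.686,0.288,1.699,0.648,0.41
preaparata,043,0.081,0.023,0.188,0.062,0.41
preaparata,044,0.023,0.009,0.052,0.025,0.41
preaparata,045,0.621,0.212,1.648,0.614,0.37
preaparata,046,0.14,0.052,0.389,0.132,0.37
preaparata,047,0.091,0.027,0.245,0.081,0.36
preaparata,048,0.035,0.011,0.09,0.039,0.36
preaparata,049,0.882,0.288,2.576,0.899,0.34
preaparata,050,0.841,0.288,2.495,0.994,0.32
preaparata,051,0.505,0.157,1.545,0.522,0.32
preaparata,052,1.064,0.388,3.429,1.152,0.32
preaparata,053,0.49,0.211,1.715,0.652,0.3
preaparata,054,0.024,0.013,0.079,0.045,0.3
preaparata,055,0.848,0.264,2.932,0.968,0.29
preaparata,056,0.042,0.013,0.135,0.052,0.29
preaparata,057,0.339,0.08,1.1,0.408,0.28
preaparata,058,0.075,0.018,0.249,0.081,0.28
preaparata,059,0.675,0.12,2.241,0.724,0.27
preaparata,060,0.425,0.135,1.571,0.6,0.26
preaparata,061,0.148,0.1,0.663,0.341,0.25
preaparata,062,0.027,0.01,0.106,0.042,0.25
preaparata,063,0.749,0.209,3.037,1.071,0.23
preaparata,064,0.174,0.103,0.842,0.454,0.21
preaparata,065,0.479,0.143,2.105,0.819,0.21
preaparata,066,0.616,0.147,2.67,0.919,0.21
preaparata,067,0.471,0.125,2.041,0.831,0.21
preaparata,068,0.537,0.126,2.536,0.828,0.2
preaparata,069,0.042,0.014,0.2,0.074,0.2
preaparata,070,0.04,0.013,0.208,0.073,0.19
preaparata,071,0.033,0.009,0.158,0.061,0.19
preaparata,072,0.257,0.143,1.331,0.847,0.18
preaparata,073,0.23,0.046,1.156,0.375,0.18
preaparata,074,0.608,0.246,3.583,1.232,0.18
preaparata,075,0.035,0.013,0.196,0.073,0.18
preaparata,076,0.096,0.066,0.594,0.336,0.17
preaparata,077,0.408,0.101,2.114,0.811,0.17
preaparata,078,0.302,0.079,1.714,0.558,0.17
preaparata,079,0.129,0.069,0.735,0.449,0.17
preaparata,080,0.196,0.055,1.072,0.431,0.17
preaparata,081,0.486,0.071,2.493,0.933,0.16
preaparata,082,0.168,0.099,1.179,0.543,0.16
preaparata,083,0.37,0.11,2.244,0.882,0.15
preaparata,084,0.368,0.11,2.331,0.932,0.15
preaparata,085,0.096,0.054,0.724,0.341,0.14
preaparata,086,0.817,0.139,5.137,1.697,0.14
preaparata,087,0.316,0.066,2.107,0.72,0.14
preaparata,088,0.243,0.094,1.802,0.708,0.13
preaparata,089,0.362,0.087,2.529,0.89,0.13
preaparata,090,0.25,0.08,1.788,0.735,0.13
preaparata,091,0.089,0.06,0.781,0.384,0.13
preaparata,092,0.15,0.065,1.362,0.547,0.11
preaparata,093,0.241,0.085,2.075,0.87,0.11
preaparata,094,0.286,0.056,2.316,0.832,0.11
preaparata,095,0.019,0.006,0.157,0.065,0.11
preaparata,096,0.167,0.039,1.451,0.618,0.1
preaparata,097,0.118,0.062,1.035,0.819,0.1
preaparata,098,0.253,0.061,2.401,0.841,0.1
preaparata,099,0.21,0.106,2.884,0.912,0.08
preaparata,100,0.24,0.057,3.181,1.072,0.07
preaparata,101,0.206,0,2.211,0.765,0.07
preaparata,102,0.299,0.045,4.088,1.435,0.06
preaparata,103,0.134,0.064,2.892,1.038,0.05
preaparata,104,0.052,0,1.522,0.601,0.02
preaparata,105,0.083,0,2.913,0.952,0.02
preaparata,106,0.075,0,3.283,1.053,0.02
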