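batch,time_h,emodin-8-O-glc,physcion-8-O-glc,emodin,physcion,f_printed
HS1,0,0.217,0.053,0.039,0.011,5.41
HS1,8,0.029,0.010,0.265,0.081,0.11
HS1,16,0.025,0.009,0.304,0.081,0.09
HS1,24,0.017,0.007,0.187,0.060,0.10
HS2,0,0.319,0.109,0.034,0.010,9.61
HS2,8,0.113,0.040,0.253,0.085,0.45
HS2,16,0.081,0.029,0.283,0.096,0.29
HS2,24,0.074,0.029,0.290,0.102,0.26
HS3,0,0.069,0.026,0.069,0.023,1.03
HS3,8,0.024,0.008,0.105,0.036,0.23
HS3,16,0.010,0.005,0.112,0.041,0.10
HS3,24,0.011,0.005,0.173,0.062,0.07
HS3,30,0.007,0.003,0.140,0.050,0.05
HS3,34,0.007,0.005,0.202,0.076,0.04
HS3,36,0.011,0.006,0.178,0.063,0.07
HS3,38,0.011,0.005,0.177,0.062,0.07
HS3,40,0.011,0.007,0.165,0.062,0.08
HS3,42,0.007,0.005,0.170,0.065,0.05
HS4,0,0.253,0.089,0.062,0.019,4.21
HS4,8,0.047,0.015,0.186,0.066,0.24
HS4,16,0.059,0.018,0.266,0.085,0.22
HS4,24,0.042,0.012,0.234,0.072,0.18
HS4,30,0.045,0.015,0.253,0.083,0.18
HS4,34,0.030,0.011,0.303,0.109,0.10
HS4,36,0.021,0.008,0.311,0.105,0.07
HS5,0,0.181,0.063,0.108,0.037,1.68
HS5,8,0.048,0.012,0.220,0.073,0.20
HS5,16,0.052,0.016,0.160,0.056,0.31
HS5,24,0.027,0.008,0.275,0.086,0.10
HS5,30,0.025,0.008,0.196,0.071,0.12
HS6,0,0.245,0.085,0.045,0.016,5.33
HS6,8,0.086,0.023,0.217,0.074,0.38
HS6,16,0.080,0.024,0.239,0.087,0.32
HS6,24,0.041,0.011,0.266,0.086,0.15
HS6,30,0.029,0.008,0.186,0.066,0.15
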