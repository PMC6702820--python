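sample_type,sample_no,emodin,physcion:qams,physcion:external,emodin-8-O-glc:qams,emodin-8-O-glc:external,physcion-8-O-glc:qams,physcion-8-O-glc:external,f:qams,f:external,note
preaparata,01,82.348,25.770,24.189,53.922,54.958,10.929,11.074,0.60,0.62,
preaparata,02,205.005,74.247,74.110,42.633,42.941,7.903,7.948,0.18,0.18,
preaparata,03,29.817,18.137,18.104,6.834,6.883,3.795,3.816,0.22,0.23,
preaparata,04,1.714,0.562,0.558,0.386,0.301,0.088,0.079,0.17,0.17,
preaparata,05,3.834,1.210,1.303,2.309,1.930,0.684,0.669,0.59,0.51,
preaparata,06,0.246,0.151,0.150,0.566,0.452,0.366,0.363,2.35,2.06,disqualified
radix,07,12.148,5.687,5.677,41.728,42.029,35.911,36.112,4.35,4.38,
radix,08,89.144,36.892,36.824,103.343,104.090,48.844,49.119,1.21,1.22,
radix,09,20.369,11.598,11.577,40.942,41.238,32.344,32.526,2.29,2.32,
radix,10,0.174,0.097,0.096,0.604,0.482,0.370,0.333,3.59,3.02,
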