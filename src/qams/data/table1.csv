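injection_volume_ul,physcion,physcion-8-O-glc,emodin-8-O-glc
2,1.134,0.469,0.428
5,1.127,0.487,0.441
10,1.104,0.486,0.435
20,1.095,0.490,0.438
30,1.096,0.492,0.435
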