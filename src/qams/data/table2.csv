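instrument,column,physcion,physcion-8-O-glc,emodin-8-O-glc
SHIMADZU LC2030 3D HPLC,Phenomenex C18,1.09,0.49,0.44
SHIMADZU LC2030 3D HPLC,SHIMADZU C18,1.09,0.49,0.44
Waters e2695 HPLC,Phenomenex C18,1.09,0.47,0.45
Waters e2695 HPLC,SHIMADZU C18,1.08,0.47,0.42
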