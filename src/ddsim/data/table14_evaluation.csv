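threshold,precision,recall,f1
0.50,0.29,0.67,0.40
0.60,0.35,0.67,0.46
0.70,0.44,0.67,0.53
0.75,0.54,0.58,0.56
0.80,0.40,0.33,0.36
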