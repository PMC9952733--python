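# orientation=similarity
,Carbamazepine,Oxcarbazepine,Gabapentin,Pregabalin,Acetazolamide,Lamotrigine,Levetiracetam,Topiramate,Phenytoin,Diazepam,Clonazepam,Klonopin,Divalproex,Divalproex-ER
Carbamazepine,1.00,0.51,0.37,0.29,0.40,0.24,0.47,0.25,0.47,0.41,0.44,0.32,0.44,0.45
Oxcarbazepine,0.51,1.00,0.40,0.31,0.39,0.27,0.48,0.27,0.46,0.43,0.47,0.34,0.46,0.46
Gabapentin,0.37,0.40,1.00,0.56,0.25,0.46,0.30,0.48,0.31,0.40,0.42,0.51,0.49,0.27
Pregabalin,0.29,0.31,0.56,1.00,0.20,0.52,0.23,0.53,0.24,0.33,0.34,0.51,0.42,0.20
Acetazolamide,0.40,0.39,0.25,0.20,1.00,0.16,0.40,0.17,0.38,0.32,0.33,0.21,0.30,0.42
Lamotrigine,0.24,0.27,0.46,0.52,0.16,1.00,0.19,0.58,0.21,0.27,0.28,0.48,0.39,0.17
Levetiracetam,0.47,0.48,0.30,0.23,0.40,0.19,1.00,0.20,0.47,0.39,0.42,0.27,0.38,0.48
Topiramate,0.25,0.27,0.48,0.53,0.17,0.58,0.20,1.00,0.21,0.27,0.28,0.48,0.39,0.17
Phenytoin,0.47,0.46,0.31,0.24,0.38,0.21,0.47,0.21,1.00,0.38,0.39,0.27,0.38,0.43
Diazepam,0.41,0.43,0.40,0.33,0.32,0.27,0.39,0.27,0.38,1.00,0.53,0.41,0.41,0.36
Clonazepam,0.44,0.47,0.42,0.34,0.33,0.28,0.42,0.28,0.39,0.53,1.00,0.43,0.46,0.40
Klonopin,0.32,0.34,0.51,0.51,0.21,0.48,0.27,0.48,0.27,0.41,0.43,1.00,0.45,0.23
Divalproex,0.44,0.46,0.49,0.42,0.30,0.39,0.38,0.39,0.38,0.41,0.46,0.45,1.00,0.36
Divalproex-ER,0.45,0.46,0.27,0.20,0.42,0.17,0.48,0.17,0.43,0.36,0.40,0.23,0.36,1.00
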