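# orientation=similarity
,Carbamazepine,Oxcarbazepine,Gabapentin,Pregabalin,Acetazolamide,Lamotrigine,Levetiracetam,Topiramate,Phenytoin,Diazepam,Clonazepam,Klonopin,Divalproex,Divalproex-ER
Carbamazepine,1.00,0.65,0.63,0.58,0.45,0.62,0.54,0.58,0.52,0.46,0.54,0.51,0.56,0.56
Oxcarbazepine,0.65,1.00,0.60,0.55,0.47,0.69,0.56,0.59,0.49,0.47,0.57,0.53,0.61,0.62
Gabapentin,0.63,0.60,1.00,0.75,0.46,0.58,0.47,0.56,0.42,0.51,0.56,0.54,0.54,0.54
Pregabalin,0.58,0.55,0.75,1.00,0.44,0.53,0.43,0.53,0.38,0.45,0.49,0.47,0.50,0.51
Acetazolamide,0.45,0.47,0.46,0.44,1.00,0.45,0.38,0.58,0.36,0.34,0.40,0.37,0.42,0.42
Lamotrigine,0.62,0.69,0.58,0.53,0.45,1.00,0.55,0.60,0.48,0.48,0.57,0.55,0.61,0.62
Levetiracetam,0.54,0.56,0.47,0.43,0.38,0.55,1.00,0.47,0.48,0.41,0.48,0.46,0.49,0.49
Topiramate,0.58,0.59,0.56,0.53,0.58,0.60,0.47,1.00,0.43,0.42,0.50,0.47,0.59,0.57
Phenytoin,0.52,0.49,0.42,0.38,0.36,0.48,0.48,0.43,1.00,0.37,0.43,0.41,0.43,0.43
Diazepam,0.46,0.47,0.51,0.45,0.34,0.48,0.41,0.42,0.37,1.00,0.64,0.65,0.41,0.43
Clonazepam,0.54,0.57,0.56,0.49,0.40,0.57,0.48,0.50,0.43,0.64,1.00,0.76,0.49,0.51
Klonopin,0.51,0.53,0.54,0.47,0.37,0.55,0.46,0.47,0.41,0.65,0.76,1.00,0.47,0.49
Divalproex,0.56,0.61,0.54,0.50,0.42,0.61,0.49,0.59,0.43,0.41,0.49,0.47,1.00,0.81
Divalproex-ER,0.56,0.62,0.54,0.51,0.42,0.62,0.49,0.57,0.43,0.43,0.51,0.49,0.81,1.00
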