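# orientation=distance
,Carbamazepine,Oxcarbazepine,Gabapentin,Pregabalin,Acetazolamide,Lamotrigine,Levetiracetam,Topiramate,Phenytoin,Diazepam,Clonazepam,Klonopin,Divalproex,Divalproex-ER
Carbamazepine,0.00,0.36,0.61,0.97,0.55,0.88,0.46,1.16,0.48,0.59,0.52,0.83,0.57,0.43
Oxcarbazepine,0.36,0.00,0.62,0.98,0.55,0.81,0.45,1.14,0.51,0.60,0.50,0.81,0.52,0.39
Gabapentin,0.61,0.62,0.00,0.59,0.77,0.82,0.76,1.05,0.82,0.72,0.66,0.79,0.70,0.69
Pregabalin,0.97,0.98,0.59,0.00,1.10,1.00,1.12,1.11,1.16,1.07,1.02,1.05,0.98,1.04
Acetazolamide,0.55,0.55,0.77,1.10,0.00,1.04,0.61,1.16,0.63,0.72,0.67,0.98,0.71,0.57
Lamotrigine,0.88,0.81,0.82,1.00,1.04,0.00,0.95,0.94,1.02,0.99,0.88,0.89,0.80,0.90
Levetiracetam,0.46,0.45,0.76,1.12,0.61,0.95,0.00,1.26,0.50,0.65,0.58,0.89,0.65,0.49
Topiramate,1.16,1.14,1.05,1.11,1.16,0.94,1.26,0.00,1.30,1.29,1.19,1.19,1.04,1.18
Phenytoin,0.48,0.51,0.82,1.16,0.63,1.02,0.50,1.30,0.00,0.68,0.63,0.94,0.71,0.55
Diazepam,0.59,0.60,0.72,1.07,0.72,0.99,0.65,1.29,0.68,0.00,0.44,0.65,0.76,0.63
Clonazepam,0.52,0.50,0.66,1.02,0.67,0.88,0.58,1.19,0.63,0.44,0.00,0.52,0.66,0.55
Klonopin,0.83,0.81,0.79,1.05,0.98,0.89,0.89,1.19,0.94,0.65,0.52,0.00,0.88,0.86
Divalproex,0.57,0.52,0.70,0.98,0.71,0.80,0.65,1.04,0.71,0.76,0.66,0.88,0.00,0.35
Divalproex-ER,0.43,0.39,0.69,1.04,0.57,0.90,0.49,1.18,0.55,0.63,0.55,0.86,0.35,0.00
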