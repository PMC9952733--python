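drug,CS&ED,ED&MD,CS&MD,CS&JC,ED&JC,MD&JC,AVG
Carbamazepine,0.11,0.99,0.13,0.10,0.95,0.97,0.54
Oxcarbazepine,0.34,0.98,0.33,0.31,0.96,0.95,0.65
Gabapentin,0.64,0.94,0.58,0.60,0.24,0.40,0.57
Pregabalin,0.84,0.78,0.69,0.62,0.52,0.89,0.72
Acetazolamide,0.11,0.96,0.02,-0.01,0.95,1.00,0.51
Lamotrigine,0.84,0.60,0.55,0.32,0.48,0.93,0.62
Levetiracetam,0.56,0.97,0.53,0.46,0.96,0.98,0.74
Topiramate,0.87,0.89,0.65,0.30,0.61,0.86,0.70
Phenytoin,0.51,0.99,0.45,0.56,0.96,0.96,0.74
Diazepam,0.40,0.96,0.27,0.53,0.74,0.71,0.60
Clonazepam,0.57,0.95,0.42,0.51,0.85,0.89,0.70
Klonopin,0.78,0.86,0.73,0.58,0.22,0.49,0.61
Divalproex,0.47,0.98,0.42,0.34,0.23,0.29,0.46
Divalproex-ER,0.35,0.95,0.20,0.02,0.85,0.95,0.55
Average Performance,0.53,0.91,0.43,0.37,0.68,0.80,
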