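# orientation=correlation
,Carbamazepine,Oxcarbazepine,Gabapentin,Pregabalin,Acetazolamide,Lamotrigine,Levetiracetam,Topiramate,Phenytoin,Diazepam,Clonazepam,Divalproex,Divalproex-ER
Carbamazepine,1.00,0.94,0.23,-0.09,0.75,-0.13,0.83,-0.32,0.82,0.52,0.52,0.60,0.85
Oxcarbazepine,0.94,1.00,0.22,-0.10,0.70,-0.01,0.87,-0.25,0.78,0.54,0.58,0.71,0.91
Gabapentin,0.23,0.22,1.00,0.81,-0.02,0.45,-0.04,0.35,-0.09,0.27,0.31,0.55,0.08
Pregabalin,-0.09,-0.10,0.81,1.00,-0.31,0.73,-0.39,0.69,-0.44,-0.08,-0.02,0.31,-0.19
Acetazolamide,0.75,0.70,-0.02,-0.31,1.00,-0.40,0.66,-0.34,0.63,0.28,0.25,0.34,0.72
Lamotrigine,-0.13,-0.01,0.45,0.73,-0.40,1.00,-0.22,0.79,-0.33,-0.16,-0.05,0.35,-0.11
Levetiracetam,0.83,0.87,-0.04,-0.39,0.66,-0.22,1.00,-0.47,0.90,0.40,0.42,0.47,0.84
Topiramate,-0.32,-0.25,0.35,0.69,-0.34,0.79,-0.47,1.00,-0.52,-0.47,-0.38,0.17,-0.30
Phenytoin,0.82,0.78,-0.09,-0.44,0.63,-0.33,0.90,-0.52,1.00,0.37,0.36,0.39,0.71
Diazepam,0.52,0.54,0.27,-0.08,0.28,-0.16,0.40,-0.47,0.37,1.00,0.96,0.41,0.39
Clonazepam,0.52,0.58,0.31,-0.02,0.25,-0.05,0.42,-0.38,0.36,0.96,1.00,0.46,0.42
Divalproex,0.60,0.71,0.55,0.31,0.34,0.35,0.47,0.17,0.39,0.41,0.46,1.00,0.64
Divalproex-ER,0.85,0.91,0.08,-0.19,0.72,-0.11,0.84,-0.30,0.71,0.39,0.42,0.64,1.00
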