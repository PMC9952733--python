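# orientation=distance
,Carbamazepine,Oxcarbazepine,Gabapentin,Pregabalin,Acetazolamide,Lamotrigine,Levetiracetam,Topiramate,Phenytoin,Diazepam,Clonazepam,Klonopin,Divalproex,Divalproex-ER
Carbamazepine,0.00,7.06,11.47,16.41,9.40,19.22,7.38,21.86,7.72,9.99,9.30,15.27,9.36,7.34
Oxcarbazepine,7.06,0.00,10.51,15.60,9.75,17.65,7.46,21.09,8.89,10.38,9.18,14.79,8.72,7.19
Gabapentin,11.47,10.51,0.00,9.43,14.39,15.06,12.64,17.15,13.70,12.32,10.81,12.86,10.74,12.30
Pregabalin,16.41,15.60,9.43,0.00,18.95,14.79,17.75,15.74,18.75,16.92,15.33,15.01,14.46,17.17
Acetazolamide,9.40,9.75,14.39,18.95,0.00,23.12,9.42,22.97,9.98,12.04,11.96,18.56,12.65,8.95
Lamotrigine,19.22,17.65,15.06,14.79,23.12,0.00,20.29,14.70,21.51,20.37,18.59,16.78,16.19,20.03
Levetiracetam,7.38,7.46,12.64,17.75,9.42,20.29,0.00,23.17,7.54,10.10,9.37,15.62,9.96,7.16
Topiramate,21.86,21.09,17.15,15.74,22.97,14.70,23.17,0.00,24.34,23.18,21.39,19.54,18.85,22.79
Phenytoin,7.72,8.89,13.70,18.75,9.98,21.51,7.54,24.34,0.00,10.82,10.52,16.95,11.41,8.29
Diazepam,9.99,10.38,12.32,16.92,12.04,20.37,10.10,23.18,10.82,0.00,6.89,11.64,11.74,9.98
Clonazepam,9.30,9.18,10.81,15.33,11.96,18.59,9.37,21.39,10.52,6.89,0.00,10.15,10.13,9.30
Klonopin,15.27,14.79,12.86,15.01,18.56,16.78,15.62,19.54,16.95,11.64,10.15,0.00,14.29,15.98
Divalproex,9.36,8.72,10.74,14.46,12.65,16.19,9.96,18.85,11.41,11.74,10.13,14.29,0.00,7.86
Divalproex-ER,7.34,7.19,12.30,17.17,8.95,20.03,7.16,22.79,8.29,9.98,9.30,15.98,7.86,0.00
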