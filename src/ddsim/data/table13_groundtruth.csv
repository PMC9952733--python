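drug_1,drug_2,structure,target,pathway,go_cc,go_mf,go_bp,average
Clonazepam,Diazepam,0.47,0.95,1,0.85,0.86,0.85,0.796
Carbamazepine,Phenytoin,0.42,0.65,NA,0.92,0.95,0.9,0.768
Carbamazepine,Oxcarbazepine,0.64,0.48,NA,0.77,0.8,0.78,0.694
Oxcarbazepine,Phenytoin,0.38,0.57,NA,0.79,0.79,0.83,0.672
Diazepam,Topiramate,0,0.86,1,0.84,0.8,0.72,0.644
Diazepam,Lamotrigine,0.22,0.78,NA,0.69,0.75,0.7,0.628
Clonazepam,Lamotrigine,0.2,0.74,NA,0.72,0.7,0.68,0.608
Lamotrigine,Topiramate,0,0.73,NA,0.65,0.82,0.75,0.59
Clonazepam,Topiramate,0,0.83,1,0.64,0.73,0.66,0.572
Phenytoin,Valproic Acid,0,0.57,NA,0.65,0.73,0.61,0.512
Gabapentin,Pregabalin,0.21,0.34,1,0.69,0.67,0.62,0.506
Carbamazepine,Valproic Acid,0.01,0.41,NA,0.74,0.72,0.6,0.496
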