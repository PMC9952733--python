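# orientation=rank
,Carbamazepine,Oxcarbazepine,Gabapentin,Pregabalin,Acetazolamide,Lamotrigine,Levetiracetam,Topiramate,Phenytoin,Diazepam,Clonazepam,Klonopin,Divalproex,Divalproex-ER
Carbamazepine,1,2,10,12,9,14,4,13,3,8,7,11,6,5
Oxcarbazepine,2,1,9,12,10,14,3,13,7,8,4,11,6,5
Gabapentin,10,8,1,2,14,6,12,5,11,9,7,3,4,13
Pregabalin,10,9,2,1,14,4,12,3,11,8,7,5,6,13
Acetazolamide,4,5,10,12,1,14,3,13,6,8,7,11,9,2
Lamotrigine,10,8,5,3,14,1,12,2,11,9,7,4,6,13
Levetiracetam,5,3,10,12,7,14,1,13,4,8,6,11,9,2
Topiramate,10,9,5,3,14,2,12,1,11,8,7,4,6,13
Phenytoin,2,4,10,12,8,14,3,13,1,9,6,11,7,5
Diazepam,6,3,7,11,12,14,8,13,9,1,2,5,4,10
Clonazepam,5,3,7,11,12,14,8,13,10,2,1,6,4,9
Klonopin,10,9,2,3,14,4,12,5,11,8,7,1,6,13
Divalproex,6,3,2,7,14,10,12,9,11,8,4,5,1,13
Divalproex-ER,4,3,10,12,6,14,2,13,5,8,7,11,9,1
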