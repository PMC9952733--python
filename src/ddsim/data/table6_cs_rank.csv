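# orientation=rank
,Carbamazepine,Oxcarbazepine,Gabapentin,Pregabalin,Acetazolamide,Lamotrigine,Levetiracetam,Topiramate,Phenytoin,Diazepam,Clonazepam,Klonopin,Divalproex,Divalproex-ER
Carbamazepine,1,2,3,5,14,4,10,6,11,13,9,12,8,7
Oxcarbazepine,3,1,6,10,14,2,9,7,12,13,8,11,5,4
Gabapentin,3,4,1,2,13,5,12,7,14,11,6,9,10,8
Pregabalin,3,4,2,1,12,6,13,5,14,11,9,10,8,7
Acetazolamide,5,3,4,7,1,6,11,2,13,14,10,12,8,9
Lamotrigine,3,2,7,11,14,1,9,6,13,12,8,10,5,4
Levetiracetam,4,2,10,12,14,3,1,9,7,13,8,11,6,5
Topiramate,5,4,8,9,6,2,11,1,13,14,10,12,3,7
Phenytoin,2,3,10,12,14,5,4,6,1,13,7,11,8,9
Diazepam,7,6,4,8,14,5,12,10,13,1,3,2,11,9
Clonazepam,7,5,6,10,14,4,12,9,13,3,1,2,11,8
Klonopin,7,6,5,9,14,4,12,10,13,3,2,1,11,8
Divalproex,6,3,7,8,13,4,10,5,12,14,9,11,1,2
Divalproex-ER,6,3,7,9,14,4,10,5,13,12,8,11,2,1
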