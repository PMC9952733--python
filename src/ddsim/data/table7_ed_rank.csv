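# orientation=rank
,Carbamazepine,Oxcarbazepine,Gabapentin,Pregabalin,Acetazolamide,Lamotrigine,Levetiracetam,Topiramate,Phenytoin,Diazepam,Clonazepam,Klonopin,Divalproex,Divalproex-ER
Carbamazepine,1,2,10,13,7,12,4,14,5,9,6,11,8,3
Oxcarbazepine,2,1,10,13,8,12,4,14,6,9,5,11,7,3
Gabapentin,3,4,1,2,10,13,9,14,12,8,5,11,7,6
Pregabalin,3,5,2,1,11,6,13,12,14,10,7,9,4,8
Acetazolamide,2,3,10,13,1,12,5,14,6,9,7,11,8,4
Lamotrigine,6,3,4,12,14,1,10,9,13,11,5,7,2,8
Levetiracetam,3,2,10,13,7,12,1,14,5,8,6,11,9,4
Topiramate,8,6,4,5,7,2,12,1,14,13,11,10,3,9
Phenytoin,2,4,10,13,6,12,3,14,1,8,7,11,9,5
Diazepam,3,4,10,13,9,12,6,14,8,1,2,7,11,5
Clonazepam,4,3,9,13,11,12,7,14,8,2,1,5,10,6
Klonopin,6,5,4,13,12,10,9,14,11,3,2,1,8,7
Divalproex,4,3,7,13,9,11,5,14,8,10,6,12,1,2
Divalproex-ER,4,3,10,13,8,12,5,14,6,9,7,11,2,1
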