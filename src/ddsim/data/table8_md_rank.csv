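# orientation=rank
,Carbamazepine,Oxcarbazepine,Gabapentin,Pregabalin,Acetazolamide,Lamotrigine,Levetiracetam,Topiramate,Phenytoin,Diazepam,Clonazepam,Klonopin,Divalproex,Divalproex-ER
Carbamazepine,1,2,10,12,8,13,4,14,5,9,6,11,7,3
Oxcarbazepine,2,1,10,12,8,13,4,14,6,9,7,11,5,3
Gabapentin,6,3,1,2,12,13,9,14,11,8,5,10,4,7
Pregabalin,9,7,2,1,14,4,12,8,13,10,6,5,3,11
Acetazolamide,3,5,10,12,1,14,4,13,6,8,7,11,9,2
Lamotrigine,9,7,4,3,14,1,11,2,13,12,8,6,5,10
Levetiracetam,3,4,10,12,7,13,1,14,5,9,6,11,8,2
Topiramate,9,7,4,3,11,2,12,1,14,13,8,6,5,10
Phenytoin,3,5,10,12,6,13,2,14,1,8,7,11,9,4
Diazepam,4,6,11,12,10,13,5,14,7,1,2,8,9,3
Clonazepam,4,3,10,12,11,13,6,14,9,2,1,8,7,5
Klonopin,8,6,4,7,13,11,9,14,12,3,2,1,5,10
Divalproex,4,3,7,12,10,13,5,14,8,9,6,11,1,2
Divalproex-ER,4,3,10,12,7,13,2,14,6,9,8,11,5,1
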