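table,row_drug,measure,col_drug,printed_value,note
table10,Carbamazepine,CS,Oxcarbazepine,0.98,row duplicates the MD row; symmetric CS cell and recomputation disagree
table10,Carbamazepine,CS,Gabapentin,0.31,row duplicates the MD row; symmetric CS cell and recomputation disagree
table10,Carbamazepine,CS,Pregabalin,-0.48,row duplicates the MD row; symmetric CS cell and recomputation disagree
table10,Carbamazepine,CS,Acetazolamide,0.84,row duplicates the MD row; symmetric CS cell and recomputation disagree
table10,Carbamazepine,CS,Lamotrigine,-0.61,row duplicates the MD row; symmetric CS cell and recomputation disagree
table10,Carbamazepine,CS,Levetiracetam,0.96,row duplicates the MD row; symmetric CS cell and recomputation disagree
table10,Carbamazepine,CS,Topiramate,-0.64,row duplicates the MD row; symmetric CS cell and recomputation disagree
table10,Carbamazepine,CS,Phenytoin,0.90,row duplicates the MD row; symmetric CS cell and recomputation disagree
table10,Carbamazepine,CS,Diazepam,0.72,row duplicates the MD row; symmetric CS cell and recomputation disagree
table10,Carbamazepine,CS,Clonazepam,0.72,row duplicates the MD row; symmetric CS cell and recomputation disagree
table10,Carbamazepine,CS,Klonopin,0.05,row duplicates the MD row; symmetric CS cell and recomputation disagree
table10,Carbamazepine,CS,Divalproex,0.85,row duplicates the MD row; symmetric CS cell and recomputation disagree
table10,Carbamazepine,CS,Divalproex-ER,0.94,row duplicates the MD row; symmetric CS cell and recomputation disagree
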