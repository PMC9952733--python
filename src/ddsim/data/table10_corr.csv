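drug,measure,Carbamazepine,Oxcarbazepine,Gabapentin,Pregabalin,Acetazolamide,Lamotrigine,Levetiracetam,Topiramate,Phenytoin,Diazepam,Clonazepam,Klonopin,Divalproex,Divalproex-ER
Carbamazepine,CS,1.00,0.98,0.31,-0.48,0.84,-0.61,0.96,-0.64,0.90,0.72,0.72,0.05,0.85,0.94
Carbamazepine,ED,1.00,0.99,0.33,-0.07,0.91,0.03,0.96,-0.50,0.93,0.71,0.63,0.28,0.81,0.88
Carbamazepine,MD,1.00,0.98,0.31,-0.48,0.84,-0.61,0.96,-0.64,0.90,0.72,0.72,0.05,0.85,0.94
Carbamazepine,JC,1.00,0.93,-0.56,-0.69,0.76,-0.71,0.89,-0.74,0.97,0.48,0.52,-0.66,0.05,0.89
Oxcarbazepine,CS,0.85,1.00,0.62,0.62,0.39,0.98,0.74,0.69,0.53,0.15,0.27,0.22,0.89,0.90
Oxcarbazepine,ED,0.99,1.00,0.37,-0.02,0.87,0.13,0.96,-0.46,0.89,0.72,0.67,0.34,0.86,0.91
Oxcarbazepine,MD,0.98,1.00,0.36,-0.41,0.81,-0.56,0.93,-0.58,0.85,0.67,0.71,0.07,0.90,0.96
Oxcarbazepine,JC,0.93,1.00,-0.45,-0.58,0.71,-0.62,0.87,-0.64,0.88,0.61,0.68,-0.56,0.20,0.86
Gabapentin,CS,0.86,0.62,1.00,0.95,0.45,0.57,0.12,0.38,0.05,0.48,0.45,0.47,0.49,0.50
Gabapentin,ED,0.33,0.37,1.00,0.78,0.24,0.21,0.26,0.02,0.15,0.30,0.33,0.36,0.44,0.31
Gabapentin,MD,0.31,0.36,1.00,0.54,0.07,0.15,0.21,0.11,0.08,0.23,0.41,0.61,0.55,0.27
Gabapentin,JC,-0.56,-0.45,1.00,0.96,-0.85,0.88,-0.74,0.88,-0.64,0.09,0.06,0.96,0.73,-0.77
Pregabalin,CS,0.87,0.62,0.95,1.00,0.56,0.57,0.06,0.53,0.00,0.30,0.25,0.27,0.59,0.58
Pregabalin,ED,-0.07,-0.02,0.78,1.00,-0.14,0.55,-0.20,0.50,-0.29,-0.11,-0.02,0.21,0.20,0.02
Pregabalin,MD,-0.48,-0.41,0.54,1.00,-0.74,0.85,-0.59,0.80,-0.71,-0.43,-0.22,0.51,-0.13,-0.51
Pregabalin,JC,-0.69,-0.58,0.96,1.00,-0.93,0.94,-0.83,0.95,-0.75,-0.07,-0.10,0.95,0.57,-0.86
Acetazolamide,CS,0.51,0.39,0.45,0.56,1.00,0.36,0.01,0.80,-0.01,-0.27,-0.22,-0.26,0.41,0.33
Acetazolamide,ED,0.91,0.87,0.24,-0.14,1.00,-0.14,0.87,-0.42,0.87,0.59,0.47,0.14,0.70,0.78
Acetazolamide,MD,0.84,0.81,0.07,-0.74,1.00,-0.84,0.89,-0.77,0.87,0.62,0.53,-0.17,0.63,0.85
Acetazolamide,JC,0.76,0.71,-0.85,-0.93,1.00,-0.97,0.89,-0.98,0.79,0.18,0.24,-0.90,-0.39,0.93
Lamotrigine,CS,0.79,0.98,0.57,0.57,0.36,1.00,0.72,0.71,0.49,0.20,0.34,0.29,0.87,0.90
Lamotrigine,ED,0.03,0.13,0.21,0.55,-0.14,1.00,-0.05,0.49,-0.20,-0.01,0.15,0.42,0.39,0.19
Lamotrigine,MD,-0.61,-0.56,0.15,0.85,-0.84,1.00,-0.70,0.97,-0.82,-0.67,-0.49,0.10,-0.35,-0.63
Lamotrigine,JC,-0.71,-0.62,0.88,0.94,-0.97,1.00,-0.86,0.99,-0.78,-0.16,-0.18,0.92,0.49,-0.89
Levetiracetam,CS,0.51,0.74,0.12,0.06,0.01,0.72,1.00,0.34,0.82,-0.16,-0.01,-0.07,0.58,0.58
Levetiracetam,ED,0.96,0.96,0.26,-0.20,0.87,-0.05,1.00,-0.59,0.94,0.72,0.64,0.27,0.75,0.82
Levetiracetam,MD,0.96,0.93,0.21,-0.59,0.89,-0.70,1.00,-0.73,0.94,0.72,0.67,-0.03,0.79,0.96
Levetiracetam,JC,0.89,0.87,-0.74,-0.83,0.89,-0.86,1.00,-0.88,0.92,0.34,0.38,-0.80,-0.24,0.99
Topiramate,CS,0.59,0.69,0.38,0.53,0.80,0.71,0.34,1.00,0.22,-0.24,-0.12,-0.18,0.77,0.71
Topiramate,ED,-0.50,-0.46,0.02,0.50,-0.42,0.49,-0.59,1.00,-0.66,-0.73,-0.68,-0.40,-0.16,-0.33
Topiramate,MD,-0.64,-0.58,0.11,0.80,-0.77,0.97,-0.73,1.00,-0.85,-0.75,-0.56,0.02,-0.39,-0.65
Topiramate,JC,-0.74,-0.64,0.88,0.95,-0.98,0.99,-0.88,1.00,-0.79,-0.14,-0.17,0.92,0.47,-0.91
Phenytoin,CS,0.46,0.53,0.05,0.00,-0.01,0.49,0.82,0.22,1.00,-0.23,-0.09,-0.16,0.33,0.30
Phenytoin,ED,0.93,0.89,0.15,-0.29,0.87,-0.20,0.94,-0.66,1.00,0.64,0.55,0.16,0.66,0.77
Phenytoin,MD,0.90,0.85,0.08,-0.71,0.87,-0.82,0.94,-0.85,1.00,0.67,0.57,-0.13,0.65,0.87
Phenytoin,JC,0.97,0.88,-0.64,-0.75,0.79,-0.78,0.92,-0.79,1.00,0.38,0.42,-0.72,-0.09,0.89
Diazepam,CS,0.16,0.15,0.48,0.30,-0.27,0.20,-0.16,-0.24,-0.23,1.00,0.96,0.98,-0.07,0.07
Diazepam,ED,0.71,0.72,0.30,-0.11,0.59,-0.01,0.72,-0.73,0.64,1.00,0.96,0.71,0.46,0.54
Diazepam,MD,0.72,0.67,0.23,-0.43,0.62,-0.67,0.72,-0.75,0.67,1.00,0.94,0.42,0.60,0.65
Diazepam,JC,0.48,0.61,0.09,-0.07,0.18,-0.16,0.34,-0.14,0.38,1.00,0.99,0.05,0.63,0.30
Clonazepam,CS,0.19,0.27,0.45,0.25,-0.22,0.34,-0.01,-0.12,-0.09,0.96,1.00,0.99,0.05,0.19
Clonazepam,ED,0.63,0.67,0.33,-0.02,0.47,0.15,0.64,-0.68,0.55,0.96,1.00,0.84,0.45,0.50
Clonazepam,MD,0.72,0.71,0.41,-0.22,0.53,-0.49,0.67,-0.56,0.57,0.94,1.00,0.58,0.69,0.63
Clonazepam,JC,0.52,0.68,0.06,-0.10,0.24,-0.18,0.38,-0.17,0.42,0.99,1.00,0.01,0.64,0.35
Klonopin,CS,0.17,0.22,0.47,0.27,-0.26,0.29,-0.07,-0.18,-0.16,0.98,0.99,1.00,0.01,0.14
Klonopin,ED,0.28,0.34,0.36,0.21,0.14,0.42,0.27,-0.40,0.16,0.71,0.84,1.00,0.31,0.26
Klonopin,MD,0.05,0.07,0.61,0.51,-0.17,0.10,-0.03,0.02,-0.13,0.42,0.58,1.00,0.26,-0.02
Klonopin,JC,-0.66,-0.56,0.96,0.95,-0.90,0.92,-0.80,0.92,-0.72,0.05,0.01,1.00,0.63,-0.83
Divalproex,CS,0.71,0.89,0.49,0.59,0.41,0.87,0.58,0.77,0.33,-0.07,0.05,0.01,1.00,0.98
Divalproex,ED,0.81,0.86,0.44,0.20,0.70,0.39,0.75,-0.16,0.66,0.46,0.45,0.31,1.00,0.96
Divalproex,MD,0.85,0.90,0.55,-0.13,0.63,-0.35,0.79,-0.39,0.65,0.60,0.69,0.26,1.00,0.89
Divalproex,JC,0.05,0.20,0.73,0.57,-0.39,0.49,-0.24,0.47,-0.09,0.63,0.64,0.63,1.00,-0.27
Divalproex-ER,CS,0.70,0.90,0.50,0.58,0.33,0.90,0.58,0.71,0.30,0.07,0.19,0.14,0.98,1.00
Divalproex-ER,ED,0.88,0.91,0.31,0.02,0.78,0.19,0.82,-0.33,0.77,0.54,0.50,0.26,0.96,1.00
Divalproex-ER,MD,0.94,0.96,0.27,-0.51,0.85,-0.63,0.96,-0.65,0.87,0.65,0.63,-0.02,0.89,1.00
Divalproex-ER,JC,0.89,0.86,-0.77,-0.86,0.93,-0.89,0.99,-0.91,0.89,0.30,0.35,-0.83,-0.27,1.00
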