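compound,certified,uncertainty,idms,qsar_predicted
PFBS,3.45,0.45,3.76,4.38
PFHxS,5.04,0.63,5.17,4.93
PFOS,6.41,0.93,6.39,6.95
PFOA,4.47,0.61,4.64,3.65
PFNA,4.78,0.36,4.59,5.15
PFDA,4.64,0.49,4.75,4.19
PFUnDA,4.83,0.69,5.00,4.76
PFDoDA,4.27,0.55,4.01,7.24
PFTeDA,3.69,0.51,3.22,3.93
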