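variant,surface,kd,sd,unit
WT,"PC/PS/PI(4,5)P2",100,20,nM
WT,PC/PS/PI(3)P,210,34,nM
WT,PC/PS,560,150,nM
WT,GS peptide,20,6,uM
WT,L45 peptide,66,4,uM
K420A,"PC/PS/PI(4,5)P2",120,12,nM
K420A,GS peptide,200,48,uM
K420A,L45 peptide,100,16,uM
W422A,"PC/PS/PI(4,5)P2",470,96,nM
W422A,GS peptide,21,5,uM
W422A,L45 peptide,67,6,uM
E425K,"PC/PS/PI(4,5)P2",70,7,nM
E425K,GS peptide,8,0.8,uM
E425K,L45 peptide,55,3,uM
Y426A,"PC/PS/PI(4,5)P2",400,44,nM
Y426A,GS peptide,20,3,uM
Y426A,L45 peptide,70,7,uM
R427A/R428A,"PC/PS/PI(4,5)P2",340,53,nM
R427A/R428A,GS peptide,44,4,uM
R427A/R428A,L45 peptide,75,11,uM
Smad3 WT,"PC/PS/PI(4,5)P2",170,15,nM
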