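id,readout,condition_a,condition_b,relation,provenance
atf6a_up,ATF6a,DIO,NCD,greater,qPCR: ATF6a transcript elevated in DIO liver
pire1a_ratio_up,pIRE1a_ratio,DIO,NCD,greater,immunoblot (n=4): pIRE1a/IRE1a elevated in DIO liver
pperk_ratio_up,pPERK_ratio,DIO,NCD,greater,immunoblot (n=4): pPERK/PERK elevated in DIO liver
peif2a_ratio_up,peIF2a_ratio,DIO,NCD,greater,immunoblot (n=4): peIF2a/eIF2a elevated in DIO liver
pjnk_up,pJNK,DIO,NCD,greater,stress-activated JNK phosphorylation elevated in DIO
pikkb_up,pIKKb,DIO,NCD,greater,stress-activated IKKb phosphorylation elevated in DIO
pnfkb_up,pNFkB,DIO,NCD,greater,inflammatory NF-kB phosphorylation elevated in DIO
sens_down,insulin_sensitivity,NCD,DIO,greater,pAkt/total-Akt signal higher in NCD than DIO
irpy_down,IRpY,NCD,DIO,greater,IR tyrosine phosphorylation higher in NCD than DIO
irspy_down,IRSpY,NCD,DIO,greater,IRS tyrosine phosphorylation higher in NCD than DIO
pip3_down,PIP3,NCD,DIO,greater,PIP3 concentration higher in NCD than DIO
pfoxo1_down,pFoxO1,NCD,DIO,greater,FoxO1 phosphorylation higher in NCD than DIO
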