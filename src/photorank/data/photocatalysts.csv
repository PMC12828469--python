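index,name,smiles
0,4CzIPN,N#Cc1c(-n2c3ccccc3c3ccccc32)c(-n2c3ccccc3c3ccccc32)c(C#N)c(-n2c3ccccc3c3ccccc32)c1-n1c2ccccc2c2ccccc21
1,Ir1,c1ccc(-c2ccccn2)cc1.c1ccc(-c2ccccn2)cc1.c1ccc(-c2ccccn2)cc1.[Ir+3]
2,Ir2,CC(C)(C)c1ccnc(-c2cc(C(C)(C)C)ccn2)c1.c1ccc(-c2ccccn2)cc1.c1ccc(-c2ccccn2)cc1.[Ir+3]
3,Ir3,CC(C)(C)c1ccnc(-c2cc(C(C)(C)C)ccn2)c1.FC(F)(F)c1cc(-c2cc(F)cc(F)c2)ncc1.FC(F)(F)c1cc(-c2cc(F)cc(F)c2)ncc1.[Ir+3]
4,Ir4,Fc1ccc(-c2ccccn2)c(F)c1.Fc1ccc(-c2ccccn2)c(F)c1.Fc1ccc(-c2ccccn2)c(F)c1.[Ir+3]
5,Ru1,c1ccc(-c2ccccn2)nc1.c1ccc(-c2ccccn2)nc1.c1ccc(-c2ccccn2)nc1.[Ru+2]
6,Ru2,c1cnc2c(c1)ccc1cccnc12.c1cnc2c(c1)ccc1cccnc12.c1cnc2c(c1)ccc1cccnc12.[Ru+2]
7,Ru3,c1cnc(-c2ccncn2)nc1.c1cnc(-c2ccncn2)nc1.c1cnc(-c2ccncn2)nc1.[Ru+2]
8,Ru4,c1cnc(-c2cnccn2)cn1.c1cnc(-c2cnccn2)cn1.c1cnc(-c2cnccn2)cn1.[Ru+2]
9,Cu1,COc1ccccc1-c1ccc2ccc3c(-c4ccccc4OC)ccnc3c2n1.COc1ccccc1-c1ccc2ccc3c(-c4ccccc4OC)ccnc3c2n1.[Cu+]
10,EY,O=C(O)c1ccccc1-c1c2cc(Br)c(=O)c(Br)c-2oc2c(Br)c(O)c(Br)cc12
11,EosinB,O=C(O)c1ccccc1-c1c2cc([N+](=O)[O-])c(=O)c(Br)c-2oc2c(Br)c(O)c([N+](=O)[O-])cc12
12,RhB,CCN(CC)c1ccc2c(-c3ccccc3C(=O)O)c3ccc(=[N+](CC)CC)cc-3oc2c1
13,RoB,O=C(O)c1c(Cl)c(Cl)c(Cl)c(Cl)c1-c1c2cc(I)c(=O)c(I)c-2oc2c(I)c(O)c(I)cc12
14,FlS,O=C(O)c1ccccc1-c1c2ccc(=O)cc-2oc2cc(O)ccc12
15,MB,CN(C)c1ccc2nc3ccc(=[N+](C)C)cc3sc-2c1
16,ClA,O=C1C(Cl)=C(Cl)C(=O)C(Cl)=C1Cl
17,TPPT,c1ccc(-c2cc(-c3ccccc3)[o+]c(-c3ccccc3)c2)cc1
18,MesAcr,Cc1cc(C)c(-c2c3ccccc3[n+](C)c3ccccc23)c(C)c1
19,Acr,C[n+]1c2ccccc2cc2ccccc21
20,DCA,N#Cc1c2ccccc2c(C#N)c2ccccc12
21,AnQ,O=C1c2ccccc2C(=O)c2ccccc21
22,PTH,c1ccc(N2c3ccccc3Sc3ccccc32)cc1
23,BP,O=C(c1ccccc1)c1ccccc1
24,XO,O=C1c2ccccc2Oc2ccccc21
25,TXO,O=C1c2ccccc2Sc2ccccc21
26,FO,O=C1c2ccccc2-c2ccccc21
27,Benzil,O=C(c1ccccc1)C(=O)c1ccccc1
28,4DPAIPN,N#Cc1c(N(c2ccccc2)c2ccccc2)c(N(c2ccccc2)c2ccccc2)c(C#N)c(N(c2ccccc2)c2ccccc2)c1N(c1ccccc1)c1ccccc1
29,RFTA,CC(=O)OCC(OC(C)=O)C(OC(C)=O)C(OC(C)=O)Cn1c2cc(C)c(C)cc2nc2c1nc(=O)[nH]c2=O
30,Ru0,Cc1ccnc(-c2cc(C)ccn2)c1.Cc1ccnc(-c2cc(C)ccn2)c1.Cc1ccnc(-c2cc(C)ccn2)c1.[Ru+2]
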