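patient,seeg_indication,seeg_outcome,n_clusters,concordance,surgery,histology,outcome,followup_months
1,Lesion-negative,Focal,2,N,TC & laser,n.a.,Seizure-free,4
2,Lesion-negative,Focal,0,N,Y,non-diag,Seizure-free,27
3,Lesion-negative,Focal,3,Y,Y,non-diag,Not seizure-free,8
4,Lesion-negative,Focal,2,N,N,n.a.,n.a.,n.a.
5,Lesion-negative,Focal,0,N,N,n.a.,n.a.,n.a.
6,Lesion-negative,Focal,1,N,Y,FCD IIA,Seizure-free,2
7,Discordance,Focal,4,Y,Y,FCD IIB,Seizure-free,14
8,Discordance,Focal,7,Y,Y,non-diag,Seizure-free,45
9,Discordance,Focal,3,Y,Y,FCD II,Seizure-free,22
10,Discordance,Focal,5,Y,Y,non-diag,Not seizure-free,14
11,Discordance,Focal,1,Y,Y,FCD IIB,Seizure-free,28
12,Discordance,Focal,2,N,Y,Other,Not seizure-free,18
13,Discordance,Focal,2,Y,Y,Other,Not seizure-free,16
14,Discordance,Focal,4,Y,Y,FCD IIB,Seizure-free,7
15,Discordance,Focal,3,N,Y,non-diag,Not seizure-free,7
16,Not definitive,Focal,1,Y,Y,FCD IIB,Seizure-free,12
17,Not definitive,Focal,3,Y,Y,non-diag,Seizure-free,2
18,Not definitive,Focal,2,Y,Y,FCD IIB,Seizure-free,21
19,Lesion-negative,Focal,4,Y,N,n.a.,n.a.,n.a.
20,Discordance,Focal,6,Y,Y,FCD IIA,Seizure-free,2
21,Discordance,Focal,1,N,TC,n.a.,Not seizure-free,10
22,Lesion-negative,mTLE,1,n.a.,Y,non-diag,Seizure-free,13
23,Lesion-negative,mTLE,1,n.a.,Y,non-diag,Seizure-free,20
24,Lesion-negative,mTLE,0,n.a.,Y,Other,Not seizure-free,17
25,Lesion-negative,mTLE,0,n.a.,Y,non-diag,Not seizure-free,14
26,Lesion-negative,mTLE,2,n.a.,Y,non-diag,Seizure-free,7
27,Discordance,mTLE,1,n.a.,Y,HS,Seizure-free,14
28,Lesion-negative,Diffuse,1,n.a.,N,n.a.,n.a.,n.a.
29,Lesion-negative,Diffuse,4,n.a.,N,n.a.,n.a.,n.a.
30,Lesion-negative,Diffuse,4,n.a.,N,n.a.,n.a.,n.a.
31,Not definitive,Diffuse (Rasmussen),1,n.a.,TC,n.a.,Not seizure-free,23
32,Not definitive,Likely focal,2,n.a.,TC,n.a.,Not seizure-free,28
33,Discordance,Likely focal,7,n.a.,N,n.a.,n.a.,n.a.
34,Lesion-negative,Likely focal,6,n.a.,N,n.a.,n.a.,n.a.
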