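rank,code,eff_fold,kcat_fold,opt_flux,opt_force_rt,opt_dissipation_rt,boundary_case
1,CAII,2.85,0.85,516052,4.12,2.1e6,1
2,KSI,2.23,0.78,15963,8.43,134498,0
3,CAII-T200H,3.77,0.67,45786,1.87,85759,0
4,CAI,1.98,0.63,18986,1.81,34328,0
5,Lac1,0.33,1.56,2364,8.27,18719,0
6,RTEM,0.21,2.05,1365,7.74,10570,0
7,sgPPase,0.95,1.02,625,9.95,6218,0
8,GPI,0.75,1.60,931,3.42,3185,0
9,GAL,0.94,2.62,165,7.60,1253,0
10,coliMgPPase,0.44,1.31,145,8.71,1263,0
11,yeastPPase,0.56,1.30,131,7.74,1013,0
12,MR,1.40,0.88,329,2.52,829,0
13,PC1,0.06,2.55,60.6,11.37,1519,0
14,FH,0.88,1.29,513,1.35,694,0
15,KSI-D38E,3.41,1.00,126,11.97,1507,1
16,KIN,1.30,0.85,42.3,13.73,580,0
17,RPE,0.66,2.27,240,2.91,697,0
18,dPGM,0.68,1.77,201,2.37,477,0
19,PMI,1.13,0.77,164,2.27,372,0
20,AROH,2.47,0.71,15.1,22.59,341,0
21,CypC,0.22,2.43,188,2.71,509,0
22,ALF,0.06,16.4,520,5.14,2671,0
23,CypB,0.26,3.43,214,2.73,584,0
24,EpiI,1.06,0.85,93.2,2.65,247,0
25,TPI,0.88,1.39,218,1.16,253,0
26,ALS,0.10,2.50,84.5,6.05,512,0
27,CypA,0.15,8.35,407,2.73,1110,0
28,AR,3.68,0.91,977,1.79,1751,1
29,yPGM,0.88,1.32,95.5,1.03,98.4,0
30,GeoCyp,0.13,21.9,362,2.73,989,0
31,ALaO,0.34,1.07,6.86,9.83,67.5,0
32,EpiT,1.20,0.60,29.6,1.03,30.6,0
33,NSAAR,0.74,1.75,11.2,2.34,26.3,0
34,iPGM,0.89,1.17,8.84,2.32,20.5,0
35,ALiO,1.98,0.98,1.30,10.01,13.0,0
36,API,1.08,0.78,10.9,1.08,11.7,0
37,RPI,1.44,0.58,5.73,2.12,12.1,0
38,RacE2mut,3.18,0.29,6.54,2.24,14.6,0
39,TIProRC,1.68,0.47,2.01,3.54,7.14,0
40,LYSROEN,0.49,2.86,3.50,2.40,8.41,0
41,TIProR,0.39,3.64,3.54,2.26,7.98,0
42,KYNase_66,0.64,1.23,0.637,7.03,4.48,0
43,RacE2,3.45,0.28,1.94,2.84,5.50,0
44,ATAmut2,0.67,1.93,1.15,2.07,2.37,0
45,KYNase_93D9,1.86,0.95,0.438,4.77,2.09,0
46,ATAmut1,0.43,3.55,1.77,1.59,2.82,0
47,TM0831,2.17,0.42,0.317,2.53,0.804,0
48,ATA,0.77,1.66,0.231,2.06,0.475,0
49,FAProR,0.56,1.93,0.180,1.32,0.237,0
50,HcmABwt,0.19,22.0,0.449,3.43,1.54,0
51,SerR,1.28,0.65,0.060,2.62,0.157,0
52,TAM,3.75,1.00,0.0208,10.08,0.210,1
53,HcmAmut,0.49,4.00,0.0302,4.05,0.122,0
54,NSAARN,0.99,1.01,0.023,2.86,0.066,0
55,EpiTmut,1.13,0.35,0.0516,0.94,0.048,0
56,GI,0.98,1.03,0.0097,2.36,0.023,0
57,HcmIcm,0.35,9.00,0.0037,5.21,0.0192,0
58,GI3,2.49,0.48,2.4e-5,2.96,7e-5,0
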