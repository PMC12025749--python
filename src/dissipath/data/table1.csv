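rank,code,generalist,efficiency,kcat,flux,force_rt,dissipation_rt
1,CAII,0,8.36e7,805433,421874,1.81,125000
2,KSI,0,3.02e8,35031,13756,8.43,115900
3,CAII-T200H,0,6.77e7,209682,33593,1.87,62920
4,CAI,0,2.481e7,77746,15691,1.81,28370
5,Lac1,0,26030200,1905,1757,8.27,14526
6,RTEM,0,23513000,975,873,7.74,6757
7,sgPPase,0,70427239,812,625,9.95,6214
8,GPI,1,21721831,1550,855,3.42,2928
9,GAL,0,1918000,730,152,7.6,1154
10,coliMgPPase,0,44481928,147,128,8.71,1116
11,yeastPPase,0,29765749,189,122,7.74,946
12,MR,0,1080105,632,317,2.52,798
13,PC1,0,10100000,60.8,60.6,11.37,689
14,FH,0,6355555,1833,508,1.35,687
15,KSI-D38E,0,2769512,129,73,8.97,655
16,KIN,0,2225553,106,41.4,13.73,569
17,RPE,0,1605047,305,191,2.91,554
18,dPGM,0,1650000,330,179,2.37,423
19,PMI,0,595000,800,161,2.27,365
20,AROH,0,589474,50.4,12.8,22.59,289
21,CypC,0,471129,115,99.6,2.71,270
22,ALF,0,5086315,52.6,51.8,5.14,266
23,CypB,0,379186,103,90.1,2.73,246
24,EpiI,0,100400,502,92.6,2.65,245
25,TPI,0,542518,714,209,1.16,242
26,ALS,0,3255879,40.2,39.4,6.05,239
27,CypA,0,936569,97.3,87.0,2.73,238
28,AR,0,172197,1692,127.2,1.80,229
29,yPGM,0,747211,380,93.4,1.03,96.2
30,GeoCyp,0,847000,36.85,33.75,2.73,92.19
31,ALaO,0,295908,6.8,6.58,9.83,64.72
32,EpiT,0,10333,341,28,1.03,28.9
33,NSAAR,0,2857,20,10.1,2.34,23.67
34,iPGM,0,104762,22,8.75,2.32,20.29
35,ALiO,0,8890,1.602,1.276,10.01,12.77
36,API,0,50333,100,10.7,1.08,11.58
37,RPI,0,15143,33.3,5.16,2.12,10.93
38,RacE2mut,0,14081,81.67,4.36,2.24,9.76
39,TIProRC,1,1996,12.13,1.64,3.54,5.82
40,LYSROEN,0,318,3.5,2.39,2.4,5.73
41,TIProR,1,2300,2.783,1.989,2.26,4.485
42,KYNase_66,0,34526,0.74,0.602,7.03,4.233
43,RacE2,0,5311,32.4,1.39,2.84,3.958
44,ATAmut2,0,1427,1.87,0.986,2.07,2.037
45,KYNase_93D9,1,38565,0.67,0.424,4.77,2.022
46,ATAmut1,0,4875,1.95,1.123,1.59,1.785
47,TM0831,1,17.9,2.156,0.244,2.53,0.618
48,ATA,0,217,0.5,0.216,2.06,0.444
49,FAProR,1,18.9,0.597,0.164,1.32,0.216
50,HcmABwt,0,481,0.05,0.048,3.43,0.163
51,SerR,0,31,0.31,0.056,2.62,0.148
52,TAM,0,37.8,0.0209,0.0135,8.47,0.114
53,HcmAmut,0,10.9,0.02,0.0165,4.05,0.0666
54,NSAARN,0,3.89,0.07,0.023,2.86,0.0659
55,EpiTmut,0,15.9,4.9,0.0474,0.94,0.044
56,GI,1,0.0365,0.029,0.0097,2.36,0.023
57,HcmIcm,0,1.8182,0.001,0.00094,5.21,0.0049
58,GI3,1,0.00018,0.00012,1.5e-5,2.96,4.4e-5
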