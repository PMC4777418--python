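gene,log_fold_change,pct_survival_cddp,survival_index,potentiation,gene_score,whole_genome_rank,validated
C2orf88,-0.3592,62.44,114.18,78.33,6722,453,0
RRM2B,-0.4104,59.76,94.82,65.64,6224,706,1
CABYR,-0.4351,53.57,92.93,66.97,6224,708,1
NINJ1,-0.3639,42.73,85.34,71.76,6124,785,1
ALDH3A1,-0.3329,69.26,97.65,60.96,5952,888,1
DUSP4,-0.2266,68.01,109.70,64.92,5862,973,1
TNFSF9,-0.3108,69.10,105.17,61.46,5829,1006,0
FHL2,-0.2346,52.60,89.14,60.43,5387,1429,1
TSPAN1,-0.4008,72.71,100.22,51.35,5124,1739,0
DDB2,-0.6643,62.56,93.72,49.26,4617,2587,0
SESN2,-0.4943,66.86,97.66,46.64,4555,2724,0
CCDC90B,-0.2574,74.40,103.39,46.90,4531,2763,0
KITLG,-0.4051,68.77,94.81,44.52,4221,3608,0
BAX,-0.4733,68.23,93.70,43.74,4099,3973,0
ARRDC1,-0.2196,68.00,94.14,41.89,3943,4504,0
AEN,-0.3286,67.75,94.33,41.75,3938,4525,0
HINT1,-0.4087,41.92,72.42,54.07,3916,4600,0
NPC2,-0.2917,78.04,99.92,37.23,3720,5322,0
PPM1D,-0.5798,72.78,93.52,39.22,3667,5564,0
TP53I11,-0.2545,87.94,106.40,38.59,3612,5791,0
TNFRSF10B,-0.3096,56.58,82.16,43.91,3608,5804,0
RHOD,-0.2825,80.37,97.97,36.78,3604,5822,0
XPC,-0.4428,72.92,95.88,36.85,3533,6141,0
C12orf5,-0.4646,78.23,99.59,35.28,3514,6234,0
MFGE8,-0.2832,52.17,78.63,44.56,3504,6278,0
SHPK,-0.3421,80.07,103.23,36.07,3491,6320,0
CYFIP2,-0.7552,84.53,105.99,36.70,3450,6510,0
NADSYN1,-0.2884,58.95,82.90,41.06,3404,6744,0
UGT2B17,-0.3809,72.83,92.62,36.74,3403,6749,0
MDM2,-0.5886,61.43,82.95,40.70,3376,6876,0
TNFRSF10D,-0.2391,37.02,65.58,51.30,3364,6937,0
ACTA2,-0.7726,30.92,61.29,51.68,3168,7813,0
HSPB8,-0.2878,52.81,78.30,39.69,3108,8122,0
BTG2,-0.7545,66.15,86.55,35.30,3055,8364,0
NTPCR,-0.4198,57.97,82.44,37.04,3054,8367,0
PI4K2A,-0.2796,54.92,76.84,38.30,2943,8878,0
TRIM5,-0.3209,59.14,82.27,35.68,2935,8907,0
SERTAD1,-0.3994,68.39,88.36,32.04,2830,9420,0
TCP11L1,-0.3789,57.80,78.43,34.87,2735,9872,0
PCED1B,-0.3562,46.91,70.76,38.21,2704,10006,0
TBC1D2,-0.3271,70.00,88.12,30.62,2698,10032,0
RABGGTA,-0.2780,17.62,47.69,56.30,2685,10096,0
NUPR1,-0.3616,34.06,60.69,43.49,2639,10286,0
CMBL,-0.4166,53.44,72.52,35.72,2590,10505,0
EDA2R,-1.0228,65.80,83.91,30.87,2590,10508,0
FGFBP1,-0.3289,31.41,57.59,41.40,2384,11382,0
GSS,-0.2515,41.98,62.37,38.10,2376,11422,0
ISCU,-0.3629,41.17,62.38,37.18,2319,11659,0
FDXR,-0.9802,56.96,71.61,31.47,2254,11942,0
DGKA,-0.5798,49.71,70.06,31.68,2220,12083,0
C20orf72,-0.2415,70.29,86.02,25.20,2168,12317,0
PHLDA3,-0.5223,59.41,75.74,27.78,2104,12608,0
TNS4,-0.3638,32.81,56.39,36.39,2052,12825,0
SESN1,-0.7338,83.88,96.92,20.92,2027,12919,0
KIAA0247,-0.2461,74.13,86.15,23.19,1998,13047,0
TTYH3,-0.2870,28.18,50.94,38.90,1982,13113,0
POLH,-0.6136,38.26,56.83,34.69,1971,13155,0
HHAT,-0.2507,61.36,76.39,25.40,1940,13292,0
RNF19B,-0.3950,71.21,85.59,21.83,1869,13579,0
HSPA4L,-0.4323,53.17,69.28,25.47,1764,13984,0
RETSAT,-0.4176,46.47,62.79,27.98,1757,14013,0
EI24,-0.2226,66.46,77.29,22.64,1750,14048,0
STOM,-0.3936,37.41,55.85,29.58,1652,14413,0
WDR63,-0.5033,38.08,56.45,27.88,1574,14710,0
SULF2,-0.7130,57.93,69.61,21.88,1523,14901,0
THSD1,-0.3759,65.18,76.60,19.29,1478,15079,0
AKR1C1,-0.5096,49.53,62.18,23.63,1469,15107,0
DSC3,-0.4999,46.02,61.19,23.99,1468,15111,0
TP53INP1,-0.8497,42.09,54.77,26.50,1451,15161,0
EPS8L2,-0.4071,20.11,41.02,32.84,1347,15544,0
TUFT1,-0.2533,26.18,42.84,30.92,1325,15617,0
ABCA12,-0.4541,46.15,57.56,21.95,1263,15791,0
APOBEC3C,-0.4432,60.06,68.74,18.14,1247,15854,0
SLC48A1,-0.2010,39.53,52.25,21.50,1124,16277,0
MR1,-0.5546,32.07,46.61,24.04,1120,16287,0
PLK3,-0.3604,20.62,38.04,27.12,1032,16570,0
SPDYE1,-0.7914,46.79,54.66,18.35,1003,16651,0
CEP85L,-0.2833,62.93,69.92,14.10,986,16703,0
CDKN1A,-1.1354,87.25,93.56,9.81,918,16898,0
RTN4RL1,-0.4497,53.24,60.96,13.86,845,17105,0
PIM2,-0.2468,32.77,42.94,17.77,763,17314,0
PPP1R3C,-0.3134,36.28,43.26,13.21,572,17768,0
ZNF226,-0.2011,39.15,45.85,12.44,570,17773,0
FAS,-0.9781,33.66,39.88,12.99,518,17888,0
PMAIP1,-0.3623,63.15,67.00,6.55,439,18065,0
HSDL2,-0.2368,45.87,50.81,7.47,380,18176,0
GDF15,-0.8717,36.87,42.01,8.79,369,18193,0
TRIM32,-0.2046,30.69,34.49,7.19,248,18403,0
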