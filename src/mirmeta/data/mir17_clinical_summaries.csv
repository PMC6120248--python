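characteristic,group,n,mean,sd
tissue_unmatched,normal,41,333.692,159.356
tissue_unmatched,tumor,412,1224.398,1092.287
age_years,lt60,124,1086.228,999.872
age_years,ge60,283,1288.305,1132.681
gender,male,266,1254.781,1148.808
gender,female,146,1169.042,982.366
histological_type,IA-TT,75,1489.868,889.374
histological_type,IA-PT,8,1559.301,723.730
histological_type,IA-NOS,78,1292.949,1076.012
histological_type,IA-MT,22,913.999,814.966
histological_type,A-NOS,147,1165.330,1137.682
histological_type,A-DT,69,918.369,770.191
histological_type,A-SRT,10,1626.048,1917.403
pathological_stage,I,58,1357.578,1038.064
pathological_stage,II,128,1122.297,835.139
pathological_stage,III,183,1285.011,1259.853
pathological_stage,IV,43,1090.728,1065.495
ajcc_t,T1,21,1192.815,531.405
ajcc_t,T2,87,1193.633,1021.903
ajcc_t,T3,188,1179.104,865.113
ajcc_t,T4,116,1326.595,1483.968
ajcc_n,N0,129,1232.097,932.042
ajcc_n,N1,109,1225.825,1224.321
ajcc_n,N2,82,1153.218,806.988
ajcc_n,N3,86,1243.926,1343.528
ajcc_n,Nx,6,1725.801,1351.577
ajcc_m,M0,364,1221.083,1037.290
ajcc_m,M1,29,1160.069,1267.692
ajcc_m,Mx,19,1386.078,1734.700
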