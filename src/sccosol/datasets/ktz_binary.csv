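T_K,P_MPa,rho_kg_m3,y2,sd_mean,U_expanded,S_g_per_L
308,12,768.42,1.700000e-06,1.000000e-08,8.000000e-08,0.016
308,15,816.06,3.400000e-06,3.000000e-08,1.600000e-07,0.034
308,18,848.87,4.400000e-06,1.700000e-07,3.900000e-07,0.045
308,21,874.40,6.200000e-06,1.700000e-07,4.400000e-07,0.066
308,24,895.54,8.000000e-06,3.400000e-07,7.700000e-07,0.087
308,27,913.69,9.400000e-06,1.700000e-07,5.400000e-07,0.104
308,30,929.68,1.090000e-05,5.100000e-07,1.140000e-06,0.122
318,12,659.73,7.000000e-07,3.000000e-08,7.000000e-08,0.006
318,15,743.17,3.200000e-06,1.000000e-07,2.700000e-07,0.036
318,18,790.18,8.500000e-06,3.400000e-07,7.900000e-07,0.081
318,21,823.70,1.310000e-05,3.500000e-07,9.000000e-07,0.130
318,24,850.10,1.680000e-05,6.900000e-07,1.570000e-06,0.173
318,27,872.04,2.110000e-05,3.500000e-07,1.150000e-06,0.222
318,30,890.92,2.590000e-05,8.600000e-07,2.070000e-06,0.279
328,12,506.85,4.000000e-07,1.000000e-08,3.000000e-08,0.003
328,15,654.94,3.000000e-06,2.000000e-08,1.500000e-07,0.026
328,18,724.13,9.800000e-06,3.500000e-07,8.200000e-07,0.086
328,21,768.74,1.820000e-05,5.200000e-07,1.310000e-06,0.169
328,24,801.92,2.760000e-05,5.000000e-07,1.600000e-06,0.267
328,27,828.51,4.020000e-05,8.700000e-07,2.470000e-06,0.402
328,30,850.83,4.810000e-05,6.800000e-07,2.520000e-06,0.494
338,12,384.17,2.000000e-07,6.000000e-09,1.000000e-08,0.001
338,15,555.23,2.200000e-06,1.000000e-07,2.300000e-07,0.015
338,18,651.18,9.000000e-06,1.700000e-07,5.600000e-07,0.077
338,21,709.69,2.290000e-05,5.200000e-07,1.450000e-06,0.196
338,24,751.17,4.200000e-05,3.200000e-07,1.980000e-06,0.381
338,27,783.29,6.020000e-05,8.500000e-07,3.160000e-06,0.569
338,30,809.58,8.020000e-05,1.210000e-06,4.270000e-06,0.784
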