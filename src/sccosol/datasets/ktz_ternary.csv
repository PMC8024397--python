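T_K,P_MPa,rho_kg_m3,y2,y3,sd_mean,U_expanded,e_printed
308,12,768.42,2.700000e-05,1.640000e-02,3.000000e-07,1.400000e-06,16.1
308,15,816.06,3.800000e-05,1.732000e-02,1.000000e-07,1.700000e-06,9.7
308,18,848.87,4.300000e-05,1.869000e-02,3.000000e-07,2.000000e-06,9.4
308,21,874.40,4.600000e-05,1.943000e-02,5.000000e-07,2.200000e-06,9.7
308,24,895.54,5.400000e-05,2.043000e-02,3.000000e-07,2.400000e-06,6.8
308,27,913.69,5.900000e-05,2.217000e-02,2.000000e-07,2.600000e-06,5.3
308,30,929.68,6.200000e-05,2.363000e-02,8.000000e-07,3.200000e-06,4.9
318,12,659.73,2.100000e-05,1.470000e-02,1.000000e-07,1.000000e-06,30.6
318,15,743.17,3.900000e-05,1.632000e-02,3.000000e-07,1.900000e-06,12.3
318,18,790.18,5.300000e-05,1.734000e-02,8.000000e-07,2.900000e-06,11.1
318,21,823.70,6.900000e-05,1.942000e-02,3.000000e-07,3.100000e-06,7.7
318,24,850.10,8.700000e-05,2.109000e-02,3.000000e-07,3.900000e-06,5.2
318,27,872.04,1.020000e-04,2.434000e-02,7.000000e-07,4.700000e-06,4.0
318,30,890.92,1.110000e-04,2.636000e-02,9.000000e-07,5.100000e-06,3.3
328,12,506.85,1.800000e-05,1.236000e-02,5.000000e-07,1.300000e-06,45.9
328,15,654.94,4.100000e-05,1.584000e-02,6.000000e-07,2.300000e-06,16.6
328,18,724.13,6.300000e-05,1.845000e-02,5.000000e-07,3.000000e-06,11.5
328,21,768.74,9.000000e-05,1.994000e-02,8.000000e-07,4.300000e-06,5.9
328,24,801.92,1.120000e-04,2.234000e-02,4.000000e-07,5.000000e-06,3.9
328,27,828.51,1.310000e-04,2.634000e-02,9.000000e-07,6.000000e-06,3.5
328,30,850.83,1.650000e-04,2.970000e-02,1.700000e-06,8.000000e-06,2.9
338,12,384.17,1.200000e-05,1.209000e-02,3.000000e-07,8.000000e-07,61.2
338,15,555.23,4.500000e-05,1.612000e-02,1.000000e-07,2.000000e-06,34.4
338,18,651.18,7.600000e-05,1.918000e-02,3.000000e-07,3.400000e-06,11.6
338,21,709.69,1.010000e-04,2.533000e-02,1.500000e-06,5.400000e-06,5.5
338,24,751.17,1.340000e-04,2.459000e-02,2.000000e-06,7.200000e-06,3.7
338,27,783.29,1.700000e-04,3.082000e-02,1.700000e-06,8.200000e-06,2.8
338,30,809.58,1.960000e-04,3.287000e-02,2.500000e-06,1.000000e-05,2.4
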