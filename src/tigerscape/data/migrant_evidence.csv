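individual,sex,sampled_locality,home_cluster,exclusion_statistic,exclusion_p,q_mst,q_p,q_ka,q_b,cluster_migrant_prob,cluster_gen1,cluster_gen2,ancestry_migrant_prob,ancestry_gen1,ancestry_gen2,parentage_lod
D955,M,PTR,P,3.234,0.005,0.035,0.009,0.889,0.067,0.996,0.978,0.018,0.999,0.990,0.009,-0.360
D958,F,PTR,P,2.959,0.005,0.033,0.016,0.936,0.015,0.982,0.964,0.018,0.997,0.987,0.010,5.320
D954,M,PTR,P,3.883,0.005,0.009,0.019,0.963,0.009,0.863,0.774,0.089,0.962,0.825,0.137,0.760
D1399,M,PTR,P,3.222,0.005,0.087,0.022,0.885,0.007,0.868,0.552,0.316,0.998,0.702,0.296,
D1843,M,MTR,MST,2.343,0.005,0.275,0.527,0.186,0.013,0.590,0.502,0.088,0.986,0.842,0.144,4.210
D1297,F,KPC,KA,6.444,0.005,0.075,0.683,0.215,0.026,0.610,0.130,0.480,0.559,0.124,0.436,2.490
D1987,M,STR,MST,2.407,0.005,0.481,0.325,0.180,0.014,0.311,0.005,0.306,0.550,0.006,0.544,0.300
D525,M,TATR,MST,2.562,0.005,0.664,0.023,0.300,0.013,0.170,0.031,0.139,0.617,0.086,0.531,
D2154,F,TATR,MST,1.000,0.030,0.460,0.158,0.358,0.024,0.007,0.001,0.006,0.188,0.056,0.132,
D1892,M,MTR,MST,1.000,0.030,0.658,0.289,0.042,0.011,0.584,0.113,0.471,0.996,0.011,0.985,0.070
D2058,F,MTR,MST,0.000,0.500,0.147,0.758,0.019,0.076,0.508,0.173,0.335,0.895,0.036,0.859,
D1140,F,KTR,KA,1.000,0.030,0.070,0.556,0.344,0.030,0.124,0.016,0.108,0.241,0.035,0.206,3.540
D1075,M,PTR,P,1.000,0.030,0.065,0.237,0.663,0.034,0.096,0.012,0.084,0.509,0.161,0.348,2.473
D1381,M,PTR,P,1.000,0.030,0.213,0.466,0.316,0.004,0.190,0.000,0.190,0.832,0.012,0.820,0.351
D1383,M,PTR,P,0.000,0.500,0.068,0.510,0.420,0.003,0.159,0.001,0.158,0.926,0.009,0.917,4.471
D1393,M,PTR,P,1.000,0.030,0.089,0.083,0.807,0.021,0.188,0.013,0.175,0.872,0.264,0.608,1.066
D1400,M,PTR,P,0.000,0.500,0.146,0.110,0.738,0.006,0.229,0.015,0.214,0.829,0.201,0.628,-2.155
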