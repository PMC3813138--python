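ligand_id,IDE,MATS7v,DP09,Mor14m,Mor30p,G2e,E2e,Tp,R5u,BELp6,SeaC2C3aa,pIC50_obs,pIC50_pred,residual
1,3.551,-0.107,9.455,1.209,-0.032,0.165,0.415,18.765,0.031,1.478,12,3.071,2.511,0.560
2,3.64,0.027,10.342,0.029,0.028,0.142,0.45,21.391,0.025,1.478,12,3.155,3.236,-0.081
3,3.707,0.017,11.604,-0.689,-0.117,0.149,0.404,22.48,0.03,1.478,12,3.009,2.803,0.206
4,3.566,-0.059,10.281,-0.078,0.154,0.15,0.282,20.91,0.032,1.515,12,2.983,2.936,0.047
5,3.593,-0.09,10.593,0.033,0.154,0.167,0.377,22.84,0.033,1.555,12,3.149,3.019,0.130
6,3.394,-0.027,8.432,-0.047,-0.133,0.151,0.517,15.905,0.027,1.248,10,2.955,2.806,0.150
7,3.394,-0.027,9.424,-0.994,-0.102,0.151,0.647,17.59,0.027,1.248,10,2.658,2.842,-0.184
8,3.113,-0.156,7.799,0.2,-0.012,0.163,0.464,15.146,0.029,1.223,8,1.42,1.145,0.275
9,3.191,-0.162,7.992,0.486,-0.154,0.16,0.506,15.639,0.026,1.232,10,1.876,1.826,0.050
10,3.287,-0.166,8.95,0.064,0.015,0.166,0.61,18.711,0.032,1.389,10,2.125,2.271,-0.146
11,3.35,-0.17,9.216,0.823,-0.142,0.147,0.49,19.924,0.027,1.412,10,1.745,2.119,-0.374
12,3.191,-0.162,8.596,-0.068,0.118,0.173,0.662,16.791,0.029,1.223,10,2.602,2.287,0.315
13,3.504,-0.043,8.75,-1.098,0.031,0.168,0.432,15.764,0.029,1.357,10,2.879,2.890,-0.011
14,3.175,-0.062,8.281,-0.203,0.015,0.156,0.457,16.098,0.024,1.301,8,0.903,0.493,0.410
15,3.281,0.071,8.697,-0.369,-0.157,0.151,0.496,17.12,0.03,1.276,10,1.347,1.594,-0.247
16,3.191,-0.162,8.611,0.469,0.013,0.158,0.369,17.544,0.027,1.236,8,1.194,1.260,-0.066
17,3.27,-0.188,8.866,0.735,0.047,0.167,0.37,19.087,0.037,1.298,8,1.854,2.118,-0.264
18,3.326,-0.197,8.812,0.842,0.13,0.147,0.363,17.767,0.025,1.325,8,1.921,1.919,0.002
19,3.294,-0.181,9.724,-0.902,-0.231,0.188,0.567,19.389,0.029,1.224,10,1.921,1.967,-0.046
20,3.263,-0.172,9.12,0.405,0.109,0.169,0.323,19.086,0.026,1.226,12,2.799,2.655,0.144
21,3.412,-0.178,9.676,0.648,0.074,0.175,0.332,21.844,0.024,1.402,12,2.81,2.536,0.274
22,3.457,-0.181,8.038,0.767,-0.041,0.161,0.355,16.094,0.024,1.409,12,2.644,3.168,-0.524
23,3.457,-0.042,9.973,-0.727,-0.051,0.151,0.467,17.533,0.027,1.237,12,3.174,3.002,0.172
24,3.263,-0.041,9.113,0.254,0.258,0.172,0.352,18.119,0.026,1.223,12,1.783,1.997,-0.214
25,3.263,-0.172,8.089,-0.436,0.07,0.163,0.326,15.73,0.023,1.223,12,3.377,3.134,0.243
26,3.263,-0.249,9.22,-0.433,-0.088,0.163,0.413,18.672,0.024,1.223,12,3.208,3.063,0.145
27,3.446,-0.042,9.62,-0.84,0.082,0.16,0.35,18.476,0.026,1.248,12,3.208,3.326,-0.118
28,3.549,-0.059,9.634,0.031,-0.071,0.16,0.52,17.239,0.031,1.357,12,3.119,3.098,0.021
29,3.223,-0.162,8.958,-0.578,0.207,0.153,0.333,17.8,0.025,1.223,12,2.569,3.050,-0.481
30,3.197,-0.16,7.767,-0.256,0.096,0.183,0.351,14.796,0.026,1.223,10,1.699,1.767,-0.068
31,3.234,-0.185,8.014,-0.299,0.068,0.173,0.46,14.406,0.028,1.253,10,1.83,2.113,-0.283
32,3.315,-0.172,8.436,-0.219,0.1,0.158,0.301,16.152,0.028,1.401,12,2.824,2.484,0.340
33,3.352,-0.159,8.837,-0.078,0.192,0.156,0.317,17.405,0.029,1.412,12,2.991,2.775,0.216
34,3.381,-0.148,9.993,-0.42,0.122,0.157,0.365,21.164,0.026,1.416,12,2.644,2.657,-0.013
35,3.263,-0.186,9.034,-0.838,0.194,0.153,0.302,16.222,0.023,1.236,12,2.815,2.727,0.088
36,3.263,-0.192,8.902,-1.076,0.013,0.163,0.498,15.55,0.029,1.231,12,3.013,3.010,0.003
37,3.24,-0.195,8.036,-0.692,0.035,0.168,0.372,14.139,0.031,1.252,10,2.201,2.398,-0.197
38,3.266,-0.172,8.297,0.308,0.16,0.158,0.356,15.762,0.032,1.223,10,3.155,2.908,0.247
39,3.315,-0.2,8.874,-0.679,0.098,0.15,0.332,15.685,0.03,1.367,12,2.481,2.746,-0.265
40,3.387,0.022,8.081,-0.806,0.027,0.148,0.509,15.319,0.022,1.41,12,2.62,2.605,0.015
41,3.437,0.002,9.481,-0.689,0.197,0.196,0.31,17.995,0.028,1.423,12,0.903,1.181,-0.278
42,3.315,-0.2,9.572,-0.557,0.218,0.172,0.392,16.828,0.024,1.316,12,1.83,1.880,-0.050
43,3.315,-0.172,9.301,-1.091,0.231,0.166,0.342,17.812,0.03,1.337,12,3.06,2.949,0.111
44,3.263,-0.121,8.121,0.392,0.256,0.174,0.34,15.488,0.033,1.223,11,2.833,2.758,0.075
45,3.263,-0.102,9.158,0.138,-0.057,0.153,0.399,18.089,0.025,1.223,11,2.131,2.052,0.079
46,3.277,-0.106,8.706,-0.81,-0.062,0.16,0.416,16.839,0.022,1.406,11,1.26,1.254,0.006
47,3.319,-0.187,8.964,-0.322,-0.14,0.177,0.538,17.723,0.026,1.367,12,2.102,2.144,-0.042
48,3.551,-0.107,10.267,-0.359,0.172,0.155,0.506,20.493,0.026,1.478,12,3.068,3.197,-0.129
49,3.537,-0.083,9.321,1.053,0.073,0.142,0.413,18.866,0.025,1.497,12,2.569,2.806,-0.237
50,3.537,-0.083,10.834,0.97,0.222,0.162,0.408,23.122,0.029,1.497,12,2.204,2.327,-0.123
51,3.543,-0.033,10.826,-0.034,0.286,0.148,0.405,23.239,0.029,1.499,12,3.435,3.068,0.367
52,3.543,-0.033,11.07,0.938,0.449,0.166,0.378,23.406,0.026,1.499,12,1.883,1.939,-0.056
53,3.581,-0.061,10.664,0.938,0.257,0.163,0.416,23.293,0.027,1.511,12,2.622,2.667,-0.045
54,3.581,-0.061,10.691,0.493,0.024,0.143,0.394,22.118,0.02,1.511,12,1.903,2.164,-0.261
55,3.585,-0.018,9.081,-0.211,0.084,0.149,0.457,18.393,0.02,1.512,12,3.405,3.077,0.328
56,3.581,0.001,9.405,-0.376,0.145,0.139,0.501,19.113,0.018,1.571,12,3.104,2.798,0.306
57,3.711,-0.019,8.968,0.722,0.136,0.15,0.444,18.373,0.019,1.578,12,3.263,3.336,-0.073
58,3.533,-0.035,10.559,-0.253,0.223,0.156,0.37,21.596,0.025,1.494,12,2.268,2.319,-0.051
59,3.54,0.002,9.656,-0.41,0.218,0.141,0.489,19.593,0.025,1.507,12,2.81,3.208,-0.398
I,3.577,-0.133,9.438,0.207,0.253,0.154,0.46,19.523,0.022,1.617,14,,3.451,
II,3.565,-0.06,9.274,0.328,0.323,0.147,0.414,18.497,0.022,1.617,14,,3.025,
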