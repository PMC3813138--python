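ligand_id,LogD,Num_RotatableBonds,Num_StereoAtoms,V_DIST_equ,CHI_1,Dipole_X,Shadow_Xlength,Shadow_XZ,pIC50_obs,pIC50_pred,residual
1,5.968,8,1,4724.72,17.24,2.226,16.104,112.169,3.071,2.995,0.076
2,6.346,8,2,4975.41,17.668,-0.232,17.246,106.927,3.155,3.099,0.056
3,6.624,9,3,5948.66,18.879,8.911,17.044,105.934,3.009,2.878,0.131
4,7.801,10,3,6357,19.352,17.426,17.251,102.209,2.983,3.388,-0.404
5,6.869,8,2,5267.12,18.206,4.827,16.575,100.892,3.149,3.140,0.009
6,6.819,9,2,5586.73,18.706,0.525,16.594,112.033,2.955,2.960,-0.005
7,4.35,5,3,4029.76,16.074,-9.636,14.335,88.627,2.658,2.206,0.452
8,2.993,4,2,2898.37,14.469,-6.569,13.227,84.085,1.42,1.444,-0.024
9,3.367,4,2,3165.49,14.863,-9.403,13.429,87.255,1.876,1.837,0.039
10,3.823,5,2,3466.24,15.401,-12.116,13.102,86.975,2.125,1.967,0.158
11,4.602,5,3,3750.51,15.774,-11.525,13.018,88.293,1.745,1.759,-0.014
12,3.544,4,2,3165.49,14.863,-4.633,15.806,86.259,2.602,2.260,0.342
13,4.929,6,3,4399.17,16.548,-4.988,15.714,85.661,2.879,2.800,0.079
14,3.935,5,3,3784.06,16.091,-3.582,14.318,84.767,0.903,1.175,-0.272
15,3.618,5,3,3903.07,16.074,-10.055,13.477,89.093,1.347,1.377,-0.030
16,3.866,4,3,3165.49,14.863,-7.035,14.801,88.055,1.194,1.538,-0.344
17,4,7,2,3034.57,14.329,-5.412,17.163,98.372,1.854,2.298,-0.444
18,4.251,7,3,3290.34,14.684,-2.954,18.145,106.53,1.921,1.765,0.156
19,3.909,5,2,3473.35,15.346,-2.056,13.726,83.834,1.921,1.872,0.049
20,4.659,4,2,3442.8,15.257,-11.197,14.262,90.403,2.799,2.712,0.087
21,5.371,5,3,4050.07,16.168,-3.294,17.258,99.523,2.81,2.538,0.272
22,5.191,5,3,4342.96,16.468,-3.431,18.061,100.242,2.644,3.015,-0.371
23,5.116,5,3,4342.96,16.468,-9.904,15.338,90.364,3.174,2.989,0.185
24,3.117,4,2,3442.8,15.257,-3.545,16.27,87.575,1.783,2.306,-0.523
25,4.793,4,2,3442.8,15.257,-7.81,15.663,92.037,3.377,2.872,0.505
26,4.333,4,2,3442.8,15.257,-5.83,17.149,91.669,3.208,2.954,0.254
27,5.071,5,3,4329.62,16.468,-8.796,16.683,97.357,3.208,2.962,0.246
28,5.593,6,3,4709.4,16.941,-7.532,17.39,98.783,3.119,3.425,-0.306
29,4.316,4,2,3402.78,15.257,-7.623,14.344,90.543,2.569,2.313,0.256
30,4.222,4,2,3377.34,15.274,-2.818,14.732,85.308,1.699,2.216,-0.517
31,3.531,4,2,3204.98,14.863,11.824,17.042,94.786,1.83,1.594,0.236
32,4.869,5,2,3713.52,15.795,-1.206,16.846,93.799,2.824,2.612,0.212
33,5.121,5,3,3982.18,16.168,-9.203,16.697,96.658,2.991,2.495,0.496
34,5.327,5,3,4252.1,16.468,-8.908,16.416,95.685,2.644,2.845,-0.201
35,4.919,4,2,3442.8,15.257,-8.057,16.867,94.102,2.815,3.142,-0.327
36,4.419,4,2,3442.8,15.257,-5.742,16.661,89.394,3.013,2.946,0.067
37,4.53,4,2,3419.09,15.274,-7.345,15.007,89.47,2.201,2.592,-0.391
38,5.109,4,2,3662.15,15.684,-8.063,14.67,91.643,3.155,2.784,0.371
39,3.322,5,2,3713.52,15.795,-11.792,16.856,94.882,2.481,2.477,0.004
40,3.643,6,2,4021.16,16.295,-12.178,16.612,96.058,2.62,2.490,0.130
41,3.127,5,2,4319.03,16.651,20.781,15.821,96.509,0.903,1.020,-0.117
42,4.171,4,2,3713.52,15.795,-7.892,16.853,93.853,1.83,2.822,-0.992
43,5.008,4,2,3713.52,15.795,-4.955,16.946,95.986,3.06,2.960,0.100
44,2.627,4,2,3442.8,15.257,-7.775,15.555,90.193,2.833,2.065,0.768
45,3.847,4,2,3442.8,15.257,-7.717,15.455,90.231,2.131,2.512,-0.381
46,3.901,4,2,3897.87,16.346,16.632,17.378,98.099,1.26,1.259,0.001
47,4.649,4,2,3944.98,16.329,-9.054,15.086,94.999,2.102,2.490,-0.388
48,6.346,8,2,4975.41,17.668,12.051,15.952,92.366,3.068,2.701,0.367
49,4.11,6,2,5227,18.329,-0.345,15.151,94.6,2.569,2.234,0.335
50,4.11,6,2,5227,18.329,0.53,15.821,90.138,2.204,2.493,-0.289
51,4.382,6,2,5512.31,18.74,-0.688,18.153,106.981,3.435,2.837,0.598
52,4.382,6,2,5512.31,18.74,-0.869,15.882,107.351,1.883,2.312,-0.429
53,5.581,9,2,5015.05,17.812,-0.683,17.066,100.792,2.622,2.718,-0.096
54,5.581,9,2,5015.05,17.812,-1.101,17.187,113.343,1.903,2.354,-0.451
55,4.803,9,2,5294.3,18.222,-0.456,19.139,102.328,3.405,3.013,0.392
56,5.404,7,2,6151.45,19.778,0.656,18.773,117.298,3.104,3.082,0.022
57,3.694,7,2,6364.86,19.634,-0.715,16.251,99.847,3.263,3.276,-0.013
58,2.553,5,2,5791.5,19.151,-0.666,17.56,107.372,2.268,2.323,-0.055
59,3.913,5,2,5791.5,19.151,-0.321,15.988,93.512,2.81,2.929,-0.119
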