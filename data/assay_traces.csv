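time_min,fraction_released,composition,replicate
0,0.01375508745,chi=0.000,1
2,0.01406172281,chi=0.000,1
4,0.05081427614,chi=0.000,1
6,0.03833969696,chi=0.000,1
8,0.07072818981,chi=0.000,1
10,0.09598336143,chi=0.000,1
12,0.1275357416,chi=0.000,1
14,0.1123301128,chi=0.000,1
16,0.1612600626,chi=0.000,1
18,0.151192823,chi=0.000,1
20,0.1683805186,chi=0.000,1
22,0.2096157051,chi=0.000,1
24,0.2257810195,chi=0.000,1
26,0.23152646,chi=0.000,1
28,0.2383123838,chi=0.000,1
30,0.2803909537,chi=0.000,1
32,0.2947157738,chi=0.000,1
34,0.2719080575,chi=0.000,1
36,0.3031251292,chi=0.000,1
38,0.3186343231,chi=0.000,1
40,0.3359578208,chi=0.000,1
42,0.3467372566,chi=0.000,1
44,0.3531889097,chi=0.000,1
46,0.3760446228,chi=0.000,1
48,0.3751643218,chi=0.000,1
50,0.3970115108,chi=0.000,1
52,0.4154207695,chi=0.000,1
54,0.4089258086,chi=0.000,1
56,0.4339722812,chi=0.000,1
58,0.4343596989,chi=0.000,1
60,0.4473272846,chi=0.000,1
0,0.006184590051,chi=0.125,1
2,0.1009679837,chi=0.125,1
4,0.18248129,chi=0.125,1
6,0.2550163671,chi=0.125,1
8,0.3348534698,chi=0.125,1
10,0.3982705898,chi=0.125,1
12,0.4553875641,chi=0.125,1
14,0.4991382099,chi=0.125,1
16,0.5609269487,chi=0.125,1
18,0.5987626285,chi=0.125,1
20,0.6611257244,chi=0.125,1
22,0.6704774741,chi=0.125,1
24,0.7210734941,chi=0.125,1
26,0.7342675797,chi=0.125,1
28,0.7695106913,chi=0.125,1
30,0.7861878287,chi=0.125,1
32,0.8049474071,chi=0.125,1
34,0.8135997055,chi=0.125,1
36,0.824798105,chi=0.125,1
38,0.8616256248,chi=0.125,1
40,0.8765298264,chi=0.125,1
42,0.8707034277,chi=0.125,1
44,0.8889482537,chi=0.125,1
46,0.9058559661,chi=0.125,1
48,0.9129107658,chi=0.125,1
50,0.9227428037,chi=0.125,1
52,0.9371374067,chi=0.125,1
54,0.9295771527,chi=0.125,1
56,0.9445242126,chi=0.125,1
58,0.9431962687,chi=0.125,1
60,0.9571974342,chi=0.125,1
0,0,chi=0.250,1
2,0.163373069,chi=0.250,1
4,0.2690473973,chi=0.250,1
6,0.3767056552,chi=0.250,1
8,0.4704556484,chi=0.250,1
10,0.5503631581,chi=0.250,1
12,0.6137938865,chi=0.250,1
14,0.6771809093,chi=0.250,1
16,0.7334223751,chi=0.250,1
18,0.7660387801,chi=0.250,1
20,0.8033832597,chi=0.250,1
22,0.8326302833,chi=0.250,1
24,0.857757343,chi=0.250,1
26,0.8895054843,chi=0.250,1
28,0.9008270892,chi=0.250,1
30,0.9018991303,chi=0.250,1
32,0.9425288881,chi=0.250,1
34,0.9419841013,chi=0.250,1
36,0.9571181224,chi=0.250,1
38,0.9481171719,chi=0.250,1
40,0.9775255657,chi=0.250,1
42,0.948762427,chi=0.250,1
44,0.9738337918,chi=0.250,1
46,0.9678140761,chi=0.250,1
48,0.9794420969,chi=0.250,1
50,0.9846373206,chi=0.250,1
52,0.98999917,chi=0.250,1
54,0.9981031347,chi=0.250,1
56,0.9772785267,chi=0.250,1
58,0.9893142661,chi=0.250,1
60,1,chi=0.250,1
0,0.01260206611,chi=0.375,1
2,0.1835010318,chi=0.375,1
4,0.3430054409,chi=0.375,1
6,0.4370063175,chi=0.375,1
8,0.5479430657,chi=0.375,1
10,0.6327883386,chi=0.375,1
12,0.7013159596,chi=0.375,1
14,0.7561298844,chi=0.375,1
16,0.7804984333,chi=0.375,1
18,0.8455808128,chi=0.375,1
20,0.8590394066,chi=0.375,1
22,0.8950381226,chi=0.375,1
24,0.9131298847,chi=0.375,1
26,0.9302165705,chi=0.375,1
28,0.9400441551,chi=0.375,1
30,0.9635395915,chi=0.375,1
32,0.9502610861,chi=0.375,1
34,0.9618204854,chi=0.375,1
36,0.9645062281,chi=0.375,1
38,1,chi=0.375,1
40,0.9935571022,chi=0.375,1
42,0.9798699342,chi=0.375,1
44,0.9676401775,chi=0.375,1
46,0.990583294,chi=0.375,1
48,1,chi=0.375,1
50,0.9919039075,chi=0.375,1
52,0.9773575064,chi=0.375,1
54,0.9948583714,chi=0.375,1
56,0.9844836,chi=0.375,1
58,0.9936749712,chi=0.375,1
60,0.9894952253,chi=0.375,1
0,0,chi=0.500,1
2,0.185781959,chi=0.500,1
4,0.3403037172,chi=0.500,1
6,0.4845211754,chi=0.500,1
8,0.5750366379,chi=0.500,1
10,0.6524349563,chi=0.500,1
12,0.7226860127,chi=0.500,1
14,0.7502081691,chi=0.500,1
16,0.8112631787,chi=0.500,1
18,0.8388423898,chi=0.500,1
20,0.8868902811,chi=0.500,1
22,0.9010905684,chi=0.500,1
24,0.9328794558,chi=0.500,1
26,0.9418947285,chi=0.500,1
28,0.9377688202,chi=0.500,1
30,0.961288277,chi=0.500,1
32,0.9603292435,chi=0.500,1
34,0.9722462707,chi=0.500,1
36,0.9807978417,chi=0.500,1
38,0.9759382338,chi=0.500,1
40,0.9941012832,chi=0.500,1
42,0.9907839208,chi=0.500,1
44,0.9906767842,chi=0.500,1
46,0.9786560025,chi=0.500,1
48,0.9894868357,chi=0.500,1
50,0.9879810597,chi=0.500,1
52,1,chi=0.500,1
54,1,chi=0.500,1
56,0.9981773694,chi=0.500,1
58,0.9762224555,chi=0.500,1
60,0.9861476642,chi=0.500,1
0,0.02676415289,chi=0.750,1
2,0.1504344411,chi=0.750,1
4,0.3132693132,chi=0.750,1
6,0.3896080348,chi=0.750,1
8,0.5033878657,chi=0.750,1
10,0.5779893862,chi=0.750,1
12,0.6210835922,chi=0.750,1
14,0.6984291432,chi=0.750,1
16,0.7553484016,chi=0.750,1
18,0.759920089,chi=0.750,1
20,0.8083132542,chi=0.750,1
22,0.8516682912,chi=0.750,1
24,0.8804254742,chi=0.750,1
26,0.9111724846,chi=0.750,1
28,0.8998471184,chi=0.750,1
30,0.9232551233,chi=0.750,1
32,0.9421806663,chi=0.750,1
34,0.9573868277,chi=0.750,1
36,0.9467483984,chi=0.750,1
38,0.9493210078,chi=0.750,1
40,0.9888270273,chi=0.750,1
42,0.9817287566,chi=0.750,1
44,0.9823664856,chi=0.750,1
46,0.9830430112,chi=0.750,1
48,0.9770057135,chi=0.750,1
50,0.9779140871,chi=0.750,1
52,0.9726959289,chi=0.750,1
54,0.9820172908,chi=0.750,1
56,0.9834755227,chi=0.750,1
58,0.99904208,chi=0.750,1
60,0.9831613054,chi=0.750,1
0,0.006017212937,chi=1.000,1
2,0.05072675055,chi=1.000,1
4,0.06328903006,chi=1.000,1
6,0.1153001166,chi=1.000,1
8,0.1400975356,chi=1.000,1
10,0.189356305,chi=1.000,1
12,0.2113858563,chi=1.000,1
14,0.2284293199,chi=1.000,1
16,0.26755807,chi=1.000,1
18,0.2984461045,chi=1.000,1
20,0.3301818158,chi=1.000,1
22,0.3468931425,chi=1.000,1
24,0.3825379891,chi=1.000,1
26,0.4195284769,chi=1.000,1
28,0.4328319566,chi=1.000,1
30,0.4408142296,chi=1.000,1
32,0.4652895496,chi=1.000,1
34,0.5060180021,chi=1.000,1
36,0.5063545038,chi=1.000,1
38,0.5394137207,chi=1.000,1
40,0.5503205607,chi=1.000,1
42,0.5599113116,chi=1.000,1
44,0.5778919089,chi=1.000,1
46,0.611954784,chi=1.000,1
48,0.602869102,chi=1.000,1
50,0.645660969,chi=1.000,1
52,0.6425943923,chi=1.000,1
54,0.6511123175,chi=1.000,1
56,0.6781608323,chi=1.000,1
58,0.6879359953,chi=1.000,1
60,0.7124931952,chi=1.000,1
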