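time,pdcm,sdcm
0,0,0
1,0,0
2,0,0
3,0,0
4,0,0
5,0,0
6,0,0
7,0,0
8,0,0
9,0,0
10,0,0
11,0.07864249663,-0.009244816498
12,0.8170132876,0.4963522944
13,2.518019861,3.025104383
14,4.551897196,6.917256233
15,6.21156912,10.00444173
16,7.271367151,11.71502538
17,7.811405721,12.52033742
18,7.983676303,12.86277283
19,7.923452646,12.97688918
20,7.735453768,12.97964499
21,7.497618503,12.93629417
22,7.264638761,12.88573754
23,7.06981652,12.84849982
24,6.927487598,12.83088228
25,6.837320808,12.82986741
26,6.789974298,12.83848031
27,6.772601179,12.84993876
28,6.77291172,12.85973311
29,6.781344791,12.86593642
30,6.791645902,12.8685485
31,6.800465462,12.8685805
32,6.806551051,12.86728724
33,6.8099161,12.86569611
34,6.811174234,12.86442341
35,6.811093152,12.86369441
36,6.81034733,12.86346586
37,6.809418433,12.86356768
38,6.808588304,12.86381376
39,6.807978579,12.86406432
40,6.807604708,12.86424472
41,6.807425551,12.86433627
42,6.807380164,12.86435496
43,6.807410398,12.86433028
44,6.807471613,12.86429024
45,6.807535212,12.86425388
46,6.807586543,12.86423006
47,6.80762094,12.86421976
48,6.807639667,12.86421951
49,6.807646659,12.8642246
50,6.807646346,12.86423099
51,6.761809836,12.85788714
52,6.358140875,12.71251553
53,5.371124004,12.22744381
54,3.869746698,11.29651661
55,2.115715803,9.885786429
56,0.4129783795,8.066981295
57,-1.042347839,6.037326321
58,-2.108037293,3.995226334
59,-2.642530568,2.10073743
60,-2.634488463,0.6265988632
61,-2.245040192,-0.1895839788
62,-1.694184352,-0.3901268534
63,-1.15190315,-0.2332655734
64,-0.7071709087,0.01839726862
65,-0.3857058388,0.2110287522
66,-0.1775666651,0.296207606
67,-0.05805447657,0.2874781102
68,2.099681887e-05,0.2223034553
69,0.02030880932,0.1388515381
70,0.0206620453,0.06466025712
71,0.01299423983,0.01340156486
72,0.004205061541,-0.0131224585
73,-0.002484481458,-0.02040102149
74,-0.006201150893,-0.01645343568
75,-0.00732316406,-0.008433732985
76,-0.00670608164,-0.001044855592
77,-0.00521934313,0.003593121086
78,-0.003527832971,0.005272829231
79,-0.002036529673,0.004809132984
80,-0.0009244278673,0.003290686593
81,-0.0002132566927,0.00161838166
82,0.000162582156,0.0003239223109
83,0.0003011999423,-0.0004145180428
84,0.0002980785589,-0.0006591677918
85,0.0002284840757,-0.0005821360259
86,0.0001425485472,-0.0003643067469
87,6.783836927e-05,-0.0001394143162
88,1.520320899e-05,2.176553386e-05
89,-1.491110905e-05,0.0001015444716
90,-2.720652866e-05,0.0001148443902
91,-2.788185126e-05,8.910052329e-05
92,-2.253122483e-05,5.01845908e-05
93,-1.524431372e-05,1.554952165e-05
94,-8.486337493e-06,-6.872628723e-06
95,-3.386733429e-06,-1.645690016e-05
96,-1.675609518e-07,-1.659108288e-05
97,1.450364437e-06,-1.178066062e-05
98,1.938799376e-06,-5.808021268e-06
99,1.767335998e-06,-9.798431566e-07
100,1.306581831e-06,1.8372601e-06
101,8.00559186e-07,2.779431728e-06
102,3.794218055e-07,2.465664312e-06
103,8.960003604e-08,1.586051442e-06
104,-7.369221663e-08,6.663459099e-07
105,-1.395867621e-07,-6.923098228e-09
106,-1.431252012e-07,-3.557470255e-07
107,-1.148790759e-07,-4.337945268e-07
108,-7.674795258e-08,-3.478926948e-07
109,-4.170486021e-08,-2.015259213e-07
110,-1.555303196e-08,-6.630095994e-08
111,6.902946259e-10,2.366895147e-08
112,8.601181714e-09,6.377561247e-08
113,1.071335747e-08,6.61514002e-08
114,9.503854157e-09,4.812944201e-08
115,6.900865843e-09,2.470522064e-08
116,4.154568636e-09,5.283155815e-09
117,1.915632466e-09,-6.39222451e-09
118,4.001483278e-10,-1.062264002e-08
119,-4.369336803e-10,-9.734563786e-09
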