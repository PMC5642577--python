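id,sequence,activity,predicted,difference
1,LLGCAANWI,5.301,5.1708,0.1302
2,SAANDPIFV,5.342,4.8592,0.4828
3,TTAEEAAGI,5.380,5.4678,-0.0878
4,LTVILGVLL,5.580,5.3216,0.2584
5,HLLVGSSGL,5.792,6.4811,-0.6891
6,GIGILTVIL,6.000,5.7321,0.2679
7,TVILGVLLL,6.072,5.4662,0.6058
8,WTDQVPFSV,6.145,6.8930,-0.7480
9,AIAKAAAAV,6.176,6.4480,-0.2720
10,ILTVILGVL,6.419,7.0160,-0.5970
11,AVAKAAAAV,6.495,5.9131,0.5819
12,ILDEAYVMA,6.623,7.4445,-0.8215
13,LLWFHISCL,6.682,6.3594,0.3226
14,TLDSQVMSL,6.793,7.2566,-0.4636
15,HLYQGCQVV,6.832,7.6799,-0.8479
16,QLFHLCLII,6.886,7.6475,-0.7615
17,ITDQVPFSV,6.947,6.6320,0.3150
18,ALCRWGLLL,7.000,7.2766,-0.2766
19,NLGNLNVSI,7.119,7.0974,0.02160
20,HLYSHPIIL,7.131,7.5663,-0.4353
21,ITFQVPFSV,7.179,7.3750,-0.1960
22,FTDQVPFSV,7.212,6.8379,0.3741
23,RLMKQDFSV,7.342,7.5681,-0.2261
24,KLHLYSHPI,7.352,6.6450,0.7070
25,ITMQVPFSV,7.398,7.2641,0.1340
26,KIFGSLAFL,7.478,6.7818,0.6962
27,ALVGLFVLL,7.585,7.3852,0.1998
28,YLSPGPVTV,7.642,7.2387,0.4033
29,GLYSSTVPV,7.699,7.6303,0.0687
30,YLYPGPVTA,7.772,8.6335,-0.8615
31,YLAPGPVTV,7.818,7.3184,0.4996
32,VVLGVVFGI,7.845,7.4509,0.3941
33,MMWYWGPSL,7.921,7.4007,0.5203
34,ILAQVPFSV,7.939,7.7270,0.2120
35,FLLSLGIHL,8.053,8.1578,-0.1048
36,ILMQVPFSV,8.125,8.3225,-0.1975
37,YLFPGPVTV,8.237,8.0249,0.2121
38,YLMPGPVTA,8.367,8.2363,0.1307
39,YLWPGPVTA,8.495,8.4140,0.0810
40,FLDQVPFSV,8.658,7.8964,0.7616
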