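id,sequence,activity,predicted,difference
1,VALVGLFVL,5.148,5.7543,-0.6063
2,GTLVALVGL,5.342,5.9368,-0.5948
3,LQTTIHDII,5.501,5.8143,-0.3133
4,SLHVGTQCA,5.842,6.1580,-0.3160
5,ALPYWNFAT,5.869,6.6416,-0.7726
6,SLNFMGYVI,5.881,5.9560,-0.0750
7,NLQSLTNLL,6.000,6.6992,-0.6992
8,FVTWHRYHL,6.025,5.7230,0.3020
9,DPKVKQWPL,6.176,5.7407,0.4354
10,ITSQVPFSV,6.196,6.5888,-0.3928
11,ALAKAAAAI,6.211,6.2433,-0.0323
12,GLGQVPLIV,6.301,6.5651,-0.2641
13,MLDLQPETT,6.335,6.8570,-0.5220
14,LLSSNLSWL,6.342,6.3502,-0.0082
15,GLACHQLCA,6.380,6.0594,0.3206
16,LIGNESFAL,6.415,7.0559,-0.6409
17,ALAKAAAAV,6.419,6.4857,-0.0667
18,LLAVGATKV,6.477,6.5115,-0.0344
19,ALAKAAAAL,6.511,6.2262,0.2848
20,WILRGTSFV,6.556,6.9084,-0.3524
21,IISCTCPTV,6.580,6.6649,-0.0849
22,FLGGTPVCL,6.623,6.8756,-0.2526
23,ALIHHNTHL,6.623,6.7908,-0.1677
24,NLSWLSLDV,6.639,6.0466,0.5924
25,YMIMVKCWM,6.663,6.6427,0.02035
26,VLQAGFFLL,6.682,7.0412,-0.3592
27,GTLGIVCPI,6.714,6.5233,0.1907
28,VILGVLLLI,6.785,7.4728,-0.6878
29,VTWHRYHLL,6.793,6.5597,0.2333
30,PLLPIFFCL,6.796,7.5217,-0.7257
31,TLGIVCPIC,6.815,5.9499,0.8651
32,CLTSTVQLV,6.832,7.1061,-0.2741
33,ILLLCLIFL,6.845,6.7815,0.0635
34,FAFRDLCIV,6.886,6.6689,0.2171
35,FLEPGPVTA,6.898,7.4940,-0.5960
36,ALAKAAAAA,6.947,6.8081,0.1389
37,LMAVVLASL,6.954,7.4908,-0.5368
38,YVITTQHWL,6.983,6.3410,0.6420
39,LLCLIFLLV,6.996,7.5015,-0.5055
40,ITAQVPFSV,7.020,6.6685,0.3515
41,YLEPGPVTL,7.058,7.1483,-0.0903
42,YTDQVPFSV,7.066,7.0742,-0.0082
43,NLYVSLLLL,7.114,6.9769,0.1371
44,ILHNGAYSL,7.127,7.3493,-0.2223
45,SIISAVVGI,7.159,7.3048,-0.1458
46,VVMGTLVAL,7.174,7.3163,-0.1423
47,YLEPGPVTI,7.187,7.1654,0.0216
48,GLSRYVARL,7.248,7.4620,-0.2131
49,LLAQFTSAI,7.301,7.4302,-0.1292
50,VLLDYQGML,7.328,7.5911,-0.2631
51,YLEPGPVTV,7.342,7.4078,-0.0658
52,ILSPFMPLL,7.3470,7.1400,0.2070
53,YLSPGPVTA,7.383,7.5610,-0.1780
54,IIDQVPFSV,7.398,7.6528,-0.2548
55,SVYDFFVWL,7.444,7.3654,0.0786
56,ITWQVPFSV,7.463,7.4417,0.0213
57,ITYQVPFSV,7.480,7.6613,-0.1813
58,GLYSSTVPV,7.481,7.6303,-0.1493
59,VMGTLVALV,7.553,7.2369,0.3161
60,LLLCLIFLL,7.585,7.1406,0.4444
61,SLDDYNHLV,7.585,7.1764,0.4086
62,VLIQRNPQL,7.644,6.9473,0.6967
63,SLYADSPSV,7.658,7.7106,-0.0526
64,ILSQVPFSV,7.699,7.6472,0.0518
65,IMDQVPFSV,7.719,8.0305,-0.3115
66,QLFEDNYAL,7.764,7.4713,0.2927
67,ALMDKSLHV,7.770,7.5250,0.2450
68,YAIDLPVSV,7.796,7.6075,0.1885
69,FVWLHYYSV,7.824,8.1149,-0.2909
70,MLGTHTMEV,7.845,7.3180,0.5270
71,LLFGYPVYV,7.886,8.0253,-0.1393
72,ILKEPVHGV,7.921,7.5915,0.3295
73,YLMPGPVTV,7.932,7.9139,0.0181
74,WLDQVPFSV,7.939,7.9514,-0.0124
75,KTWGQYWQV,7.955,7.6934,0.2616
76,ALMPLYACI,8.000,7.4383,0.5617
77,YLAPGPVTA,8.032,7.6408,0.3912
78,YLYPGPVTV,8.051,8.3112,-0.2602
79,LLMGTLGIV,8.097,7.6769,0.4201
80,YLWPGPVTV,8.125,8.0916,0.0334
81,FLLTRILTI,8.149,7.8796,0.2694
82,GLLGWSPQA,8.237,8.2184,0.0185
83,ILYQVPFSV,8.310,8.7197,-0.4097
84,GILTVILGV,8.347,7.8414,0.5056
85,NMVPFFPPV,8.398,8.0854,0.3126
86,ILDQVPFSV,8.481,7.6904,0.7906
87,YLFPGPVTA,8.495,8.3473,0.1477
88,YLDQVPFSV,8.638,8.1326,0.5054
89,ILFQVPFSV,8.699,8.4335,0.2655
90,ILWQVPFSV,8.770,8.5002,0.2698
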