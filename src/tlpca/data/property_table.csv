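residue,Lip,Hyd,S_L,S_H,P_alpha,P_beta,P_c,Vol
L,1.2906,0.0000,84.5476,0.0000,1.21,1.30,0.68,166.7
I,1.1046,0.0000,88.6055,0.0000,1.08,1.60,0.66,166.7
V,0.5324,0.0000,77.8108,0.0000,1.06,1.70,0.62,140.0
F,0.4412,-0.1195,105.7054,11.2472,1.13,1.38,0.71,189.9
M,1.0768,-0.3068,70.3631,23.2299,1.45,1.05,0.58,162.9
W,0.8364,-0.4310,133.6980,14.8820,1.08,1.37,0.75,227.8
A,0.1744,0.0000,34.7760,0.0000,1.42,0.83,0.70,88.6
C,0.2479,-0.2402,23.5563,30.4540,0.70,1.19,1.18,108.5
G,0.0208,0.0000,3.7616,0.0000,0.57,0.75,1.50,60.1
Y,0.4534,-0.5896,80.9646,42.7160,0.69,1.47,1.06,193.6
T,1.4265,-0.4369,46.7285,16.0490,0.83,1.19,1.07,116.1
S,0.2346,-0.6040,26.0681,15.9613,0.77,0.75,1.32,89.0
H,0.8124,-0.7766,82.1701,13.8631,1.00,0.87,1.06,153.2
Q,1.0036,-0.7211,70.0876,17.8662,1.11,1.10,0.86,143.9
K,1.4600,-0.6229,97.7144,8.0786,1.16,0.74,0.98,168.7
N,0.6396,-0.7211,50.5075,17.7804,0.67,0.89,1.35,117.7
E,1.0315,-0.9298,57.1582,25.5726,1.51,0.37,0.84,138.4
D,0.6058,-0.9298,37.4173,25.2736,1.01,0.54,1.20,111.1
R,1.2424,-1.4797,90.8008,35.3095,0.98,0.93,1.04,173.4
P,0.3226,0.0000,69.2297,0.0000,0.57,0.55,1.59,122.7
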