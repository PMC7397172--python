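locus,common9,n,md_pct,na,ne,nar,he,ho,f,hw,fnull,pic,pid_unrelated,pid_sib
VVS2,1,127,0,12,4.65,10.51,0.79,0.78,0.007,NS,0.0063,0.758,0.073,0.376
VVMD7,1,127,0,10,3.66,8.70,0.73,0.80,-0.095,NS,-0.0436,0.685,0.116,0.416
VVMD27,1,127,0,8,3.49,6.94,0.71,0.80,-0.115,NS,-0.0583,0.67,0.126,0.425
ssrVrZAG62,1,127,0,10,5.34,8.97,0.81,0.89,-0.095,NS,-0.0484,0.789,0.058,0.358
ssrVrZAG79,1,127,0,11,5.76,10.45,0.83,0.86,-0.039,NS,-0.0205,0.804,0.053,0.35
VVMD5,1,127,0,10,5.08,9.36,0.80,0.84,-0.049,NS,-0.0258,0.78,0.062,0.364
VVMD25,1,127,0,10,3.77,8.07,0.74,0.74,-0.007,NS,-0.0024,0.691,0.115,0.411
VVMD28,1,127,0,12,8.20,11.09,0.88,0.94,-0.067,ND,-0.0329,0.866,0.027,0.318
VVMD32,1,127,0,9,5.07,8.47,0.80,0.91,-0.128,NS,-0.0627,0.778,0.064,0.365
VViq52,0,126,0.79,5,2.78,4.71,0.64,0.71,-0.103,NS,-0.0544,0.57,0.2,0.48
VVIp31,0,127,0,12,7.18,11.18,0.86,0.95,-0.098,ND,-0.0476,0.845,0.035,0.328
VVip60,0,124,2.36,12,4.74,10.61,0.79,0.82,-0.032,NS,-0.0184,0.76,0.074,0.374
VMC1b11,0,125,1.57,10,4.88,9.62,0.80,0.85,-0.066,NS,-0.0362,0.774,0.063,0.368
VMC4f3,0,127,0,15,4.27,12.38,0.77,0.76,0.013,NS,0.0066,0.741,0.079,0.387
VVih54,0,126,0.79,12,4.11,10.15,0.76,0.81,-0.07,NS,-0.0341,0.732,0.084,0.393
VViv67,0,126,0.79,12,5.25,10.28,0.81,0.83,-0.03,NS,-0.0152,0.785,0.061,0.361
VVib01,0,127,0,5,2.79,5.00,0.64,0.67,-0.044,NS,-0.0205,0.58,0.19,0.477
VVMD24,0,127,0,6,2.55,5.92,0.61,0.61,0.003,NS,0.0046,0.559,0.202,0.496
VVMD21,0,126,0.79,7,2.60,5.92,0.62,0.71,-0.148,NS,-0.0712,0.57,0.193,0.491
VVIn16,0,127,0,5,2.45,4.98,0.59,0.58,0.03,NS,0.0116,0.523,0.235,0.513
VVIn73,0,127,0,7,1.47,5.14,0.32,0.32,0.011,ND,0.0095,0.287,0.496,0.715
VViv37,0,106,16.54,13,3.93,11.33,0.75,0.79,-0.063,NS,-0.0422,0.721,0.09,0.399
Vchr8b,0,125,1.57,15,7.41,13.59,0.87,0.69,0.205,**,0.1177,0.852,0.031,0.325
Vchr10b,0,126,0.79,3,2.45,3.00,0.59,0.66,-0.112,NS,-0.0525,0.505,0.254,0.517
Vchr14b,0,125,1.57,13,4.09,11.63,0.76,0.32,0.576,***,0.4073,0.728,0.087,0.394
Vchr4a,0,115,9.45,6,2.67,5.08,0.63,0.64,-0.03,NS,-0.0106,0.552,0.214,0.491
Vchr9a,0,126,0.79,8,4.26,7.36,0.77,0.83,-0.079,NS,-0.0355,0.73,0.09,0.39
Vchr16a,0,127,0,8,1.98,7.32,0.50,0.49,0.014,NS,0.012,0.457,0.293,0.576
Vchr19a,0,118,7.09,8,3.13,7.27,0.68,0.71,-0.047,NS,-0.0305,0.639,0.144,0.446
Vchr17a,0,119,6.3,2,1.83,2.00,0.45,0.38,0.168,NS,0.0914,0.351,0.401,0.623
Vchr18a,0,122,3.94,10,4.72,8.28,0.79,0.75,0.043,NS,0.0211,0.761,0.072,0.374
Vchr1b,0,122,3.94,4,2.85,3.97,0.65,0.61,0.065,NS,0.0277,0.578,0.194,0.474
Vchr7b,0,121,4.72,4,3.74,4.00,0.73,0.80,-0.094,NS,-0.0447,0.683,0.122,0.414
Vchr11b,0,109,14.17,6,4.05,5.38,0.75,0.78,-0.036,NS,-0.0188,0.708,0.106,0.4
Vchr12a,0,121,4.72,6,2.98,5.40,0.67,0.72,-0.082,NS,-0.0417,0.605,0.172,0.461
Vchr2b,0,62,51.18,4,1.64,4.00,0.39,0.37,0.047,ND,0.0171,0.348,0.414,0.659
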