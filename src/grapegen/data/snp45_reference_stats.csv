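locus,n,md_pct,na,ne,nar,ho,he,f,hw,maf_allele,maf,pic,pid_unrelated,pid_sib,fnull
SNP1003_336,124,0,2,1.78,2.00,0.42,0.44,0.04,NS,A,0.323,0.342,0.412,0.635,0.0207
SNP1015_67,124,0,2,1.46,2.00,0.35,0.32,-0.094,ND,C,0.476,0.267,0.517,0.721,-0.0447
SNP1027_69,124,0,2,1.96,2.00,0.51,0.49,-0.036,NS,G,0.266,0.37,0.38,0.6,-0.0175
SNP1035_226,124,0,2,1.39,2.00,0.31,0.28,-0.089,ND,T,0.48,0.242,0.556,0.748,-0.0427
SNP1079_58,124,0,2,1.96,2.00,0.60,0.49,-0.219,NS,A,0.246,0.37,0.38,0.6,-0.0988
SNP1119_176,124,0,2,1.98,2.00,0.48,0.49,0.02,NS,C,0.375,0.372,0.378,0.598,0.01
SNP1127_70,124,0,2,1.64,2.00,0.44,0.39,-0.115,NS,A,0.198,0.314,0.448,0.667,-0.0543
SNP1157_64,124,0,2,1.08,2.00,0.07,0.07,-0.038,ND,G,0.266,0.068,0.867,0.932,-0.0097
SNP1215_138,124,0,2,2.00,2.00,0.53,0.50,-0.067,NS,C,0.117,0.374,0.376,0.594,-0.0324
SNP1229_219,124,0,2,1.64,2.00,0.47,0.39,-0.197,NS,C,0.016,0.314,0.448,0.667,-0.0899
SNP1323_155,124,0,2,1.69,2.00,0.48,0.41,-0.164,NS,G,0.44,0.325,0.433,0.654,-0.0759
SNP1347_100,124,0,2,1.87,2.00,0.56,0.47,-0.198,NS,A,0.351,0.357,0.395,0.616,-0.09
SNP1349_174,124,0,2,1.99,2.00,0.56,0.50,-0.116,NS,T,0.431,0.374,0.376,0.595,-0.055
SNP1399_81,124,0,2,1.06,2.00,0.06,0.06,-0.029,ND,A,0.286,0.053,0.895,0.946,-0.0062
SNP1411_565,124,0,2,1.32,2.00,0.27,0.24,-0.098,ND,C,0.351,0.213,0.603,0.78,-0.0466
SNP1453_40,124,0,2,1.64,2.00,0.44,0.39,-0.115,NS,T,0.379,0.314,0.448,0.667,-0.0543
SNP1471_179,124,0,2,1.26,2.00,0.23,0.21,-0.132,ND,C,0.395,0.185,0.651,0.809,-0.0569
SNP1513_153,124,0,2,1.84,2.00,0.56,0.46,-0.222,NS,T,0.302,0.352,0.4,0.622,-0.0998
SNP191_100,124,0,2,1.07,2.00,0.07,0.06,-0.033,ND,C,0.169,0.06,0.881,0.939,-0.0079
SNP197_82,124,0,2,2.00,2.00,0.51,0.50,-0.016,NS,A,0.367,0.375,0.375,0.594,-0.008
SNP227_191,124,0,2,1.85,2.00,0.48,0.46,-0.034,NS,T,0.032,0.354,0.397,0.619,-0.0167
SNP259_199,123,0.81,2,1.76,2.00,0.46,0.43,-0.051,NS,G,0.488,0.339,0.415,0.637,-0.025
SNP269_308,124,0,2,1.92,2.00,0.45,0.48,0.055,NS,C,0.302,0.364,0.387,0.608,0.0284
SNP325_65,124,0,2,2.00,2.00,0.40,0.50,0.208,NS,A,0.427,0.375,0.375,0.594,0.1163
SNP425_205,124,0,2,1.03,2.00,0.03,0.03,-0.016,ND,G,0.472,0.031,0.938,0.969,-0.0023
SNP447_244,124,0,2,1.89,2.00,0.45,0.47,0.041,NS,A,0.496,0.36,0.391,0.612,0.0207
SNP581_114,124,0,2,1.97,2.00,0.70,0.49,-0.424,***,A,0.44,0.371,0.379,0.598,-0.1749
SNP593_149,124,0,2,1.84,2.00,0.51,0.46,-0.115,NS,T,0.379,0.352,0.4,0.622,-0.0546
SNP613_315,124,0,2,1.34,2.00,0.27,0.25,-0.048,ND,A,0.306,0.222,0.589,0.77,-0.0236
SNP697_296,124,0,2,1.30,2.00,0.25,0.23,-0.084,ND,A,0.444,0.204,0.618,0.789,-0.0401
SNP819_210,124,0,2,1.59,2.00,0.44,0.37,-0.196,NS,G,0.028,0.302,0.465,0.681,-0.0892
SNP829_281,124,0,2,1.97,2.00,0.57,0.49,-0.162,NS,C,0.359,0.371,0.379,0.598,-0.075
SNP873_244,124,0,2,1.92,2.00,0.50,0.48,-0.046,NS,C,0.351,0.364,0.387,0.608,-0.0225
SNP879_308,124,0,2,2.00,2.00,0.57,0.50,-0.146,NS,A,0.488,0.375,0.375,0.594,-0.068
SNP895_382,124,0,2,1.89,2.00,0.52,0.47,-0.096,NS,A,0.113,0.36,0.391,0.612,-0.046
SNP945_88,124,0,2,2.00,2.00,0.52,0.50,-0.049,NS,T,0.266,0.375,0.375,0.594,-0.0239
SNP947_288,124,0,2,1.99,2.00,0.63,0.50,-0.263,NS,A,0.141,0.374,0.376,0.595,-0.1163
VVI_10113,124,0,2,1.89,2.00,0.40,0.47,0.143,NS,A,0.317,0.36,0.391,0.612,0.0772
VVI_10329,124,0,2,1.88,2.00,0.27,0.47,0.432,***,T,0.149,0.359,0.392,0.614,0.2757
VVI_10353,124,0,2,1.84,2.00,0.49,0.46,-0.08,NS,A,0.468,0.352,0.4,0.622,-0.0385
VVI_10992,124,0,2,1.73,2.00,0.41,0.42,0.025,NS,G,0.387,0.333,0.423,0.645,0.0128
VVI_12882,124,0,2,1.73,2.00,0.35,0.42,0.178,NS,A,0.036,0.333,0.423,0.645,0.0978
VVI_1617,124,0,2,1.74,2.00,0.52,0.43,-0.214,NS,G,0.395,0.335,0.421,0.643,-0.0967
VVI_9227,124,0,2,1.25,2.00,0.19,0.20,0.034,ND,G,0.133,0.18,0.66,0.815,0.0172
VVI_9920,124,0,2,1.90,2.00,0.48,0.48,-0.02,NS,G,0.379,0.362,0.389,0.61,-0.0098
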