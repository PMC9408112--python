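region,2020,2021,2022,2023,2024,average
Beijing,0.6186,0.6353,0.6407,0.6443,0.6281,0.6334
Tianjin,0.4243,0.4178,0.4189,0.4176,0.4302,0.4218
Hebei,0.6131,0.6224,0.6181,0.6383,0.6314,0.6247
Shanxi,0.3841,0.3954,0.3878,0.3973,0.3901,0.3909
Inner Mongoria,0.3968,0.4039,0.3926,0.4086,0.4006,0.4005
Liaoning,0.5317,0.5346,0.5096,0.5324,0.5347,0.5286
Jilin,0.4435,0.4476,0.4298,0.4408,0.4283,0.4380
Heilongjiang,0.4329,0.4559,0.4399,0.4602,0.4608,0.4499
Shanghai,0.7021,0.7049,0.7008,0.7145,0.7161,0.7077
Jiangsu,0.7783,0.8069,0.7885,0.8241,0.8272,0.8050
Zhejiang,0.6878,0.6906,0.6661,0.6741,0.6915,0.6820
Anhui,0.5757,0.5840,0.5670,0.5938,0.5870,0.5815
Fujian,0.4209,0.4369,0.4312,0.4429,0.4365,0.4337
Jiangxi,0.4871,0.4977,0.4905,0.5112,0.5088,0.4991
Shandong,0.7407,0.7456,0.7416,0.7625,0.7653,0.7511
Henan,0.6262,0.6468,0.6686,0.7229,0.7040,0.6737
Hubei,0.6239,0.6263,0.6162,0.6499,0.6392,0.6311
Hunan,0.5719,0.5886,0.5759,0.5987,0.5826,0.5835
Guangdong,0.6869,0.7199,0.7000,0.7246,0.7157,0.7094
Guangxi,0.3907,0.3999,0.3890,0.3949,0.3921,0.3933
Hainan,0.2560,0.2941,0.2920,0.3140,0.2956,0.2903
Chongqing,0.4785,0.4752,0.4649,0.4807,0.4917,0.4782
Sichuan,0.7036,0.7183,0.6820,0.7039,0.6900,0.6996
Guizhou,0.4261,0.4290,0.4044,0.4110,0.4213,0.4184
Yunnan,0.3501,0.3764,0.3641,0.3805,0.3683,0.3679
Tibet,0.0510,0.1905,0.0670,0.0710,0.0659,0.0891
Shaanxi,0.5007,0.5016,0.4701,0.4877,0.4872,0.4895
Gansu,0.2635,0.2693,0.3045,0.3087,0.3414,0.2975
Qinghai,0.3370,0.2944,0.3056,0.2909,0.3141,0.3084
Ningxia,0.1758,0.2305,0.2419,0.2377,0.2479,0.2268
Xinjiang,0.4015,0.3517,0.3361,0.3150,0.3548,0.3518
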