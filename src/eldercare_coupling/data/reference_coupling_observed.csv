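region,2010,2011,2012,2013,2014,2015,2016,2017,2018,2019,average
Beijing,0.6171,0.6162,0.5946,0.6075,0.5594,0.6172,0.6342,0.6312,0.6192,0.6455,0.6142
Tianjin,0.4328,0.4147,0.4171,0.3823,0.3677,0.3985,0.3857,0.3929,0.4367,0.4574,0.4086
Hebei,0.5573,0.5516,0.5824,0.6522,0.6368,0.6470,0.6189,0.6313,0.6437,0.6425,0.6164
Shanxi,0.3941,0.3823,0.3842,0.3675,0.3687,0.3908,0.4232,0.3838,0.4051,0.4090,0.3909
Inner Mongoria,0.3971,0.4063,0.3988,0.4011,0.4440,0.4289,0.4142,0.4365,0.4321,0.4171,0.4176
Liaoning,0.5365,0.5235,0.5397,0.5369,0.5314,0.5675,0.5363,0.5558,0.5684,0.5558,0.5452
Jilin,0.3621,0.3567,0.3374,0.3260,0.3059,0.3803,0.4199,0.4442,0.4562,0.4674,0.3856
Heilongjiang,0.3973,0.3945,0.3889,0.3834,0.3947,0.4436,0.4402,0.4764,0.4842,0.4763,0.4280
Shanghai,0.6962,0.6484,0.6519,0.6328,0.5963,0.6684,0.7225,0.7396,0.7514,0.7615,0.6869
Jiangsu,0.8455,0.8624,0.8904,0.8561,0.8643,0.8839,0.8568,0.8571,0.8678,0.8478,0.8632
Zhejiang,0.7020,0.7304,0.7231,0.6911,0.7175,0.7217,0.7128,0.7440,0.7576,0.7342,0.7234
Anhui,0.6421,0.6234,0.6298,0.6286,0.5901,0.5750,0.5520,0.5889,0.6011,0.5991,0.6030
Fujian,0.4133,0.4246,0.4532,0.4228,0.4109,0.4288,0.4248,0.4366,0.4438,0.4532,0.4312
Jiangxi,0.5487,0.5261,0.4997,0.5135,0.4901,0.5054,0.4325,0.5138,0.5240,0.5293,0.5083
Shandong,0.8767,0.8566,0.8292,0.8093,0.8188,0.8053,0.7711,0.7351,0.7822,0.7810,0.8065
Henan,0.6554,0.6386,0.6328,0.6361,0.5958,0.5576,0.5382,0.5509,0.5673,0.6744,0.6047
Hubei,0.5944,0.6003,0.6097,0.5921,0.5801,0.6390,0.6269,0.6297,0.6471,0.6571,0.6176
Hunan,0.5745,0.5713,0.5839,0.5675,0.5465,0.5911,0.5757,0.5836,0.5880,0.6126,0.5795
Guangdong,0.6478,0.6591,0.6960,0.6747,0.6753,0.7002,0.7022,0.7305,0.7331,0.7243,0.6943
Guangxi,0.4428,0.4431,0.4191,0.4447,0.5025,0.4746,0.4459,0.4430,0.4335,0.4178,0.4467
Hainan,0.3138,0.3149,0.3250,0.3038,0.2657,0.3102,0.3110,0.2712,0.2364,0.2855,0.2938
Chongqing,0.5240,0.5367,0.5362,0.5054,0.4556,0.4953,0.4805,0.4864,0.4937,0.5079,0.5022
Sichuan,0.6983,0.7056,0.7095,0.7110,0.6492,0.7612,0.7377,0.7404,0.7361,0.7299,0.7179
Guizhou,0.3331,0.3519,0.4020,0.4270,0.3720,0.4631,0.4448,0.4434,0.4634,0.4438,0.4145
Yunnan,0.4568,0.4513,0.4402,0.4134,0.3528,0.4305,0.4197,0.3942,0.3886,0.3950,0.4143
Tibet,0.1660,0.1412,0.1303,0.0884,0.0796,0.1115,0.1424,0.1306,0.1473,0.0789,0.1216
Shaanxi,0.4415,0.4638,0.5136,0.5126,0.4471,0.4632,0.4925,0.4938,0.5042,0.5155,0.4848
Gansu,0.3080,0.3366,0.3440,0.3445,0.2879,0.3064,0.3443,0.3512,0.3581,0.3315,0.3313
Qinghai,0.2170,0.2193,0.1912,0.2117,0.1851,0.2047,0.2095,0.2230,0.2136,0.2229,0.2098
Ningxia,0.2203,0.1951,0.1853,0.1837,0.1721,0.2034,0.2163,0.2420,0.2318,0.2279,0.2078
Xinjiang,0.2856,0.3294,0.3043,0.3299,0.2811,0.3029,0.3027,0.3026,0.3246,0.3034,0.3067
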