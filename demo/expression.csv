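files,prot_0,prot_1,prot_2,prot_3,prot_4,prot_5,prot_6,prot_7,prot_8,prot_9,prot_10,prot_11,class
sample_0.raw,15.0614,8.1665,12.6271,11.1483,11.3210,11.6766,8.9700,11.6521,10.7022,16.9845,12.3387,11.4711,HD
sample_1.raw,11.5781,10.9979,10.4173,11.4138,12.7229,11.6422,13.4366,11.7003,12.0364,14.3187,12.8177,11.2422,HD
sample_2.raw,11.7257,12.8108,14.9026,11.5956,11.6347,13.5035,10.6703,11.5624,13.3238,12.8705,12.1373,13.0052,HD
sample_3.raw,7.7578,13.5320,10.5605,9.4971,12.4147,,11.3328,10.3854,12.0392,11.9209,14.1084,13.1211,HD
sample_4.raw,12.2907,13.6674,11.6917,10.6112,12.8761,12.8738,11.6778,10.8258,12.3437,8.2592,13.0352,12.7371,HD
sample_5.raw,9.5417,12.0920,10.5539,13.1358,8.9487,10.6283,13.0644,13.7346,8.7630,11.2529,12.4920,11.0862,HD
sample_6.raw,14.3860,10.2132,12.5318,10.4274,14.1089,11.9675,11.4416,9.4227,14.5227,13.1292,13.1303,13.7068,HD
sample_7.raw,12.5238,11.0411,10.7996,10.7997,14.0551,9.8094,11.1054,11.5181,12.3369,12.8630,10.1264,9.4050,HD
sample_8.raw,11.9934,13.8203,13.1356,12.3235,11.5243,12.4399,11.6350,13.2258,10.8083,12.2014,11.8338,12.8150,HD
sample_9.raw,12.3370,15.8251,14.2480,14.2451,8.9407,11.4895,11.0871,12.7991,8.5815,13.7617,13.6005,10.0469,HD
sample_10.raw,10.5322,10.7982,12.0649,12.9615,15.0718,,13.1513,12.2331,14.6399,13.1132,14.0528,10.3835,HD
sample_11.raw,11.7116,10.7793,14.2574,12.9865,11.5423,11.3213,12.7270,10.9478,10.6041,12.7219,15.6947,11.6308,HD
sample_12.raw,15.1662,12.7433,9.9975,12.7875,13.2762,12.0138,12.4989,12.1739,12.2080,9.7108,11.3128,12.1672,MF
sample_13.raw,14.8252,13.7854,10.7713,11.4998,13.2797,11.3901,11.7692,13.2206,12.9672,14.5428,8.8643,13.2853,MF
sample_14.raw,15.2766,14.7020,13.2566,13.6249,13.5590,12.2327,14.4145,11.5755,11.7885,13.1990,11.1729,15.2414,MF
sample_15.raw,17.5288,17.7634,11.9601,11.4254,12.2506,13.1019,11.1189,12.5696,11.9748,14.4235,11.0059,13.5692,MF
sample_16.raw,15.0342,13.0590,10.9346,10.2147,12.2195,13.5469,12.2465,12.9365,14.4483,12.4050,12.2927,11.5874,MF
sample_17.raw,13.5876,15.6396,9.3653,12.9790,11.9785,,11.8983,10.7652,12.5369,11.1596,11.7286,12.0628,MF
sample_18.raw,15.7982,14.2168,10.7513,11.7163,8.7925,11.7640,10.2029,13.6804,13.9049,9.0735,12.2174,11.8105,MF
sample_19.raw,14.4299,15.2975,11.3075,9.3486,11.6000,11.7776,12.1596,10.1532,12.9235,13.1032,10.2813,11.0117,MF
sample_20.raw,15.8795,13.6511,14.6156,12.3126,10.4841,10.8178,11.9138,15.4437,11.7326,12.1912,12.7711,11.9398,MF
sample_21.raw,19.4210,13.7027,13.1163,12.2407,12.9318,10.2350,14.6522,11.8177,12.0512,10.5975,10.9055,12.8464,MF
sample_22.raw,17.4797,15.6299,13.8135,13.0717,12.0427,13.2548,12.8904,11.8491,13.0891,13.9285,12.3519,11.4657,MF
sample_23.raw,17.0781,17.3511,11.6842,11.8615,11.7954,13.8345,9.2442,12.5488,13.7884,10.7799,14.2335,12.8030,MF
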