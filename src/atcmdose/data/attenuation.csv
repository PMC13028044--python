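material,energy_keV,mu_pe_cm2g,mu_incoh_cm2g,mu_total_cm2g,mu_en_cm2g
air,10,4.61,0.192542,5.12,4.742
air,15,1.27,0.189082,1.614,1.334
air,20,0.52,0.185783,0.7779,0.5389
air,30,0.144,0.179622,0.3538,0.1537
air,40,0.0575,0.173983,0.2485,0.0683
air,50,0.028,0.168803,0.208,0.041
air,60,0.0154,0.164027,0.1875,0.0304
air,80,0.00597,0.155509,0.1662,0.0241
air,100,0.00287,0.148133,0.1541,0.0234
air,150,0.000768,0.133359,0.1356,0.025
lung,10,4.88,0.212135,5.367,4.99
lung,15,1.31,0.208323,1.693,1.396
lung,20,0.525,0.204688,0.8205,0.5638
lung,30,0.143,0.197901,0.3783,0.161
lung,40,0.0553,0.191688,0.2688,0.0718
lung,50,0.0263,0.185981,0.2264,0.0434
lung,60,0.0142,0.180719,0.2048,0.0325
lung,80,0.00541,0.171334,0.1823,0.0264
lung,100,0.00257,0.163207,0.1693,0.0256
lung,150,0.000674,0.14693,0.1492,0.0275
adipose,10,2.68,0.214372,3.268,2.912
adipose,15,0.694,0.21052,1.083,0.8211
adipose,20,0.269,0.206847,0.5877,0.3328
adipose,30,0.0715,0.199988,0.3164,0.09873
adipose,40,0.0272,0.19371,0.2427,0.04796
adipose,50,0.0128,0.187942,0.2123,0.03153
adipose,60,0.00687,0.182625,0.1966,0.02562
adipose,80,0.00258,0.173141,0.1784,0.02249
adipose,100,0.00122,0.164752,0.1668,0.02263
adipose,150,0.000317,0.146348,0.1474,0.02511
soft_tissue,10,4.88,0.212135,5.367,4.99
soft_tissue,15,1.31,0.208323,1.693,1.396
soft_tissue,20,0.525,0.204688,0.8205,0.5638
soft_tissue,30,0.143,0.197901,0.3783,0.161
soft_tissue,40,0.0553,0.191688,0.2688,0.0718
soft_tissue,50,0.0263,0.185981,0.2264,0.0434
soft_tissue,60,0.0142,0.180719,0.2048,0.0325
soft_tissue,80,0.00541,0.171334,0.1823,0.0264
soft_tissue,100,0.00257,0.163207,0.1693,0.0256
soft_tissue,150,0.000674,0.14693,0.1492,0.0275
water,10,4.78,0.214102,5.329,4.944
water,15,1.28,0.210255,1.673,1.374
water,20,0.512,0.206586,0.8096,0.5503
water,30,0.139,0.199736,0.3756,0.1557
water,40,0.0537,0.193466,0.2683,0.0695
water,50,0.0255,0.187706,0.2269,0.0422
water,60,0.0138,0.182395,0.2059,0.0319
water,80,0.00524,0.172923,0.1837,0.0262
water,100,0.00249,0.16472,0.1707,0.0256
water,150,0.000651,0.148293,0.1505,0.0277
bone,10,27.5,0.198558,28.51,26.8
bone,15,8.2,0.194991,9.032,8.388
bone,20,3.48,0.191588,4.001,3.601
bone,30,1,0.185235,1.331,1.07
bone,40,0.406,0.17942,0.6655,0.4507
bone,50,0.2,0.174078,0.4242,0.2336
bone,60,0.111,0.169153,0.3148,0.14
bone,80,0.0445,0.160369,0.2229,0.06896
bone,100,0.0219,0.152762,0.1855,0.04585
bone,150,0.00597,0.137527,0.148,0.03183
aluminium,10,25.6,0.18583,26.23,25.43
aluminium,15,7.43,0.182491,7.955,7.487
aluminium,20,3.01,0.179307,3.441,3.094
aluminium,30,0.826,0.173361,1.128,0.8778
aluminium,40,0.33,0.167919,0.5685,0.3601
aluminium,50,0.161,0.162919,0.3681,0.184
aluminium,60,0.0893,0.15831,0.2778,0.1099
aluminium,80,0.0356,0.150089,0.2018,0.05511
aluminium,100,0.0174,0.142969,0.1704,0.03794
aluminium,150,0.00474,0.128711,0.1378,0.02827
pmma,10,2.75,0.208047,3.357,3.026
pmma,15,0.72,0.204309,1.101,0.8324
pmma,20,0.282,0.200743,0.5714,0.3328
pmma,30,0.0748,0.194087,0.3032,0.0963
pmma,40,0.0285,0.187994,0.235,0.0478
pmma,50,0.0134,0.182397,0.2074,0.0321
pmma,60,0.00722,0.177236,0.1924,0.0264
pmma,80,0.00272,0.168032,0.1751,0.0235
pmma,100,0.00129,0.160062,0.1641,0.0236
pmma,150,0.000335,0.144098,0.1456,0.026
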