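locus,pic,hom,het,pe,pi,pd_f,pd_m,mec_kruger,mec_kishida,mec_desmarais,mec_desmarais_duo
DXS8378,0.5558,0.3896,0.6104,0.3036,0.1948,0.7936,0.6104,0.3608,0.5558,0.5558,0.4079
DXS10135,0.9070,0.0866,0.9134,0.8228,0.0433,0.9862,0.9134,0.8256,0.9070,0.9070,0.8363
DXS10148,0.9043,0.0889,0.9111,0.8181,0.0445,0.9853,0.9111,0.8201,0.9041,0.9043,0.8317
DXS7132,0.6975,0.2590,0.7410,0.4945,0.1295,0.8895,0.7410,0.5081,0.6975,0.6975,0.5583
DXS10074,0.7444,0.2213,0.7787,0.5600,0.1107,0.9167,0.7787,0.5693,0.7442,0.7444,0.6130
DXS10079,0.8032,0.1738,0.8262,0.6486,0.0869,0.9467,0.8262,0.6538,0.8032,0.8032,0.6867
DXS10101,0.8889,0.1026,0.8974,0.7901,0.0513,0.9810,0.8974,0.7944,0.8889,0.8889,0.8083
DXS10103,0.7496,0.2180,0.7820,0.5660,0.1090,0.9201,0.7820,0.5779,0.7496,0.7496,0.6194
HPRTB,0.6594,0.2926,0.7074,0.4398,0.1463,0.8663,0.7074,0.4643,0.6594,0.6594,0.5158
DXS7423,0.4597,0.4732,0.5268,0.2121,0.2366,0.7090,0.5268,0.2728,0.4596,0.4597,0.3181
DXS10134,0.8323,0.1505,0.8495,0.6939,0.0753,0.9602,0.8495,0.7017,0.8323,0.8323,0.7268
DXS10146,0.8670,0.1209,0.8791,0.7530,0.0605,0.9733,0.8791,0.7561,0.8670,0.8670,0.7753
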