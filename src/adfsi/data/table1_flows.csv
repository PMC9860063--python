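printed_label,scenario,total_flow,BT,LCCA,LSA,CA,SMA,RA_L,RA_R,CIA_L,CIA_R,inlets
AC at 3 L/min,AC,3,3.000,0.424,0.781,0.236,0.152,0.090,0.086,0.309,0.923,BT
AC at 4 L/min,AC,4,4.000,0.553,1.030,0.309,0.204,0.118,0.122,0.421,1.261,BT
AC at 5 L/min,AC,5,5.000,0.688,1.266,0.351,0.240,0.140,0.147,0.526,1.601,BT
AC at 6 L/min,AC,6,6.000,0.875,1.600,0.392,0.279,0.167,0.172,0.573,1.862,BT
AC at 7 L/min,AC,7,7.000,1.044,1.919,0.445,0.324,0.199,0.201,0.674,2.219,BT
AFC at 3 L/min,AFC,3,1.500,0.449,0.840,0.475,0.302,0.165,0.165,0.616,1.500,BT;CIA_R
AFC at 4 L/min,AFC,4,2.000,0.594,1.112,0.640,0.406,0.226,0.227,0.804,2.000,BT;CIA_R
AFC at 5 L/min,AFC,5,2.500,0.739,1.401,0.808,0.513,0.288,0.290,0.986,2.500,BT;CIA_R
ACF at 6 L/min,AFC,6,3.000,0.891,16.651,0.979,0.620,0.353,0.354,1.161,3.000,BT;CIA_R
AFC at 7 L/min,AFC,7,3.500,1.055,1.885,1.139,0.731,0.428,0.424,1.353,3.500,BT;CIA_R
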