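printed_label,scenario,total_flow,branch,mean,sd,inlet
AC at 3 L/min,AC,3,BT,2.99,0.14,1
AC at 3 L/min,AC,3,LCCA,0.38,0.05,0
AC at 3 L/min,AC,3,LSA,0.70,0.06,0
AC at 3 L/min,AC,3,CA,0.25,0.02,0
AC at 3 L/min,AC,3,SMA,0.13,0.01,0
AC at 3 L/min,AC,3,CIA_L,0.17,0.13,0
AC at 3 L/min,AC,3,CIA_R,1.00,0.08,0
AC at 4 L/min,AC,4,BT,4.01,0.14,1
AC at 4 L/min,AC,4,LCCA,0.51,0.08,0
AC at 4 L/min,AC,4,LSA,0.96,0.08,0
AC at 4 L/min,AC,4,CA,0.38,0.03,0
AC at 4 L/min,AC,4,SMA,0.20,0.02,0
AC at 4 L/min,AC,4,CIA_L,0.23,0.13,0
AC at 4 L/min,AC,4,CIA_R,1.38,0.14,0
AC at 5 L/min,AC,5,BT,5.06,0.16,1
AC at 5 L/min,AC,5,LCCA,0.69,0.08,0
AC at 5 L/min,AC,5,LSA,1.32,0.12,0
AC at 5 L/min,AC,5,CA,0.62,0.04,0
AC at 5 L/min,AC,5,SMA,0.23,0.04,0
AC at 5 L/min,AC,5,CIA_L,0.14,0.17,0
AC at 5 L/min,AC,5,CIA_R,1.50,0.12,0
AC at 6 L/min,AC,6,BT,6.02,0.17,1
AC at 6 L/min,AC,6,LCCA,0.89,0.08,0
AC at 6 L/min,AC,6,LSA,1.62,0.10,0
AC at 6 L/min,AC,6,CA,0.81,0.05,0
AC at 6 L/min,AC,6,SMA,0.13,0.02,0
AC at 6 L/min,AC,6,CIA_L,0.18,0.14,0
AC at 6 L/min,AC,6,CIA_R,1.56,0.05,0
AC at 7 L/min,AC,7,BT,7.06,0.30,1
AC at 7 L/min,AC,7,LCCA,1.03,0.08,0
AC at 7 L/min,AC,7,LSA,1.88,0.12,0
AC at 7 L/min,AC,7,CA,1.02,0.03,0
AC at 7 L/min,AC,7,SMA,0.07,0.02,0
AC at 7 L/min,AC,7,CIA_L,0.42,0.24,0
AC at 7 L/min,AC,7,CIA_R,1.29,0.16,0
AFC at 3 L/min,AFC,3,BT,1.59,0.05,1
AFC at 3 L/min,AFC,3,LCCA,0.45,0.05,0
AFC at 3 L/min,AFC,3,LSA,0.83,0.10,0
AFC at 3 L/min,AFC,3,CA,0.55,0.03,0
AFC at 3 L/min,AFC,3,SMA,0.31,0.07,0
AFC at 3 L/min,AFC,3,CIA_L,0.44,0.12,0
AFC at 3 L/min,AFC,3,CIA_R,0.65,0.45,1
AFC at 4 L/min,AFC,4,BT,2.02,0.07,1
AFC at 4 L/min,AFC,4,LCCA,0.59,0.04,0
AFC at 4 L/min,AFC,4,LSA,1.08,0.15,0
AFC at 4 L/min,AFC,4,CA,0.66,0.05,0
AFC at 4 L/min,AFC,4,SMA,0.44,0.06,0
AFC at 4 L/min,AFC,4,CIA_L,0.86,0.17,0
AFC at 4 L/min,AFC,4,CIA_R,1.45,0.30,1
AFC at 5 L/min,AFC,5,BT,2.53,0.07,1
AFC at 5 L/min,AFC,5,LCCA,0.75,0.04,0
AFC at 5 L/min,AFC,5,LSA,1.37,0.15,0
AFC at 5 L/min,AFC,5,CA,0.84,0.04,0
AFC at 5 L/min,AFC,5,SMA,0.58,0.06,0
AFC at 5 L/min,AFC,5,CIA_L,1.07,0.18,0
AFC at 5 L/min,AFC,5,CIA_R,2.07,0.19,1
ACF at 6 L/min,AFC,6,BT,3.00,0.07,1
ACF at 6 L/min,AFC,6,LCCA,0.92,0.08,0
ACF at 6 L/min,AFC,6,LSA,1.67,0.25,0
ACF at 6 L/min,AFC,6,CA,1.12,0.04,0
ACF at 6 L/min,AFC,6,SMA,0.76,0.05,0
ACF at 6 L/min,AFC,6,CIA_L,1.22,0.30,0
ACF at 6 L/min,AFC,6,CIA_R,3.04,0.32,1
AFC at 7 L/min,AFC,7,BT,3.52,0.13,1
AFC at 7 L/min,AFC,7,LCCA,1.06,0.10,0
AFC at 7 L/min,AFC,7,LSA,1.95,0.27,0
AFC at 7 L/min,AFC,7,CA,1.36,0.05,0
AFC at 7 L/min,AFC,7,SMA,0.83,0.07,0
AFC at 7 L/min,AFC,7,CIA_L,1.38,0.27,0
AFC at 7 L/min,AFC,7,CIA_R,3.42,0.36,1
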