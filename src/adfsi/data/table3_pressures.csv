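scenario,total_flow,region,FL,TL,diff
AC,3,CA,1.19,0.37,0.82
AC,3,SMA,1.18,0.38,0.80
AC,4,CA,1.79,0.58,1.21
AC,4,SMA,1.79,0.63,1.16
AC,5,CA,2.64,0.72,1.92
AC,5,SMA,2.63,0.82,1.81
AC,6,CA,4.08,0.88,3.20
AC,6,SMA,4.09,1.02,3.07
AC,7,CA,5.54,1.04,4.50
AC,7,SMA,5.53,1.27,4.26
AFC,3,CA,1.10,0.96,0.14
AFC,3,SMA,1.10,0.98,0.12
AFC,4,CA,1.81,1.58,0.23
AFC,4,SMA,1.81,1.62,0.19
AFC,5,CA,2.73,2.33,0.40
AFC,5,SMA,2.73,2.42,0.31
AFC,6,CA,3.86,3.29,0.57
AFC,6,SMA,3.85,3.32,0.53
AFC,7,CA,4.88,4.31,0.57
AFC,7,SMA,4.88,4.44,0.44
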