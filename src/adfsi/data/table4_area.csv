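scenario,method,total_flow,CA,SMA
AC,4D flow MRI,3,87,75
AC,4D flow MRI,4,80,74
AC,4D flow MRI,5,75,72
AC,4D flow MRI,6,73,72
AC,4D flow MRI,7,72,71
AC,FSI,3,94,95
AC,FSI,4,91,93
AC,FSI,5,87,89
AC,FSI,6,80,84
AC,FSI,7,75,79
AFC,4D flow MRI,3,99,99
AFC,4D flow MRI,4,100,100
AFC,4D flow MRI,5,100,101
AFC,4D flow MRI,6,102,103
AFC,4D flow MRI,7,103,104
AFC,FSI,3,99,99
AFC,FSI,4,98,99
AFC,FSI,5,98,98
AFC,FSI,6,96,97
AFC,FSI,7,97,98
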