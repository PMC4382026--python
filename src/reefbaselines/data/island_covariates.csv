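region,island,lat,lon,atoll,forereef_ha,pop,distant_pop,chl,wv,sstl
N. Mariana,Farallon de Pajaros,20.542,144.895,0,138,0,0,0.04,21.00,25.09
N. Mariana,Maug,20.023,145.222,0,314,0,0,0.04,19.55,25.46
N. Mariana,Asuncion,19.693,145.401,0,249,0,0,0.04,19.55,25.58
N. Mariana,Agrihan,18.775,145.668,0,851,0,0,0.04,21.82,25.97
N. Mariana,Pagan,18.105,145.760,0,1513,0,0,0.05,20.33,26.09
N. Mariana,Sarigan-Guguan-Alamagan,17.249,145.816,0,267,0,15080,0.04,20.24,26.27
S. Mariana,Saipan,15.191,145.735,0,3539,48220,21336,0.05,18.05,26.72
S. Mariana,Tinian,15.025,145.627,0,1414,3136,173919,0.04,18.05,26.75
S. Mariana,Aguijan,14.850,145.553,0,406,0,212599,0.04,18.36,26.81
S. Mariana,Rota,14.149,145.193,0,1331,2527,210714,0.03,16.89,26.84
S. Mariana,Guam,13.451,144.773,0,7296,162810,10785,0.04,15.54,26.98
NWHI,Kure,28.413,-178.339,1,2438,0,0,0.09,45.51,18.98
NWHI,Midway,28.235,-177.367,1,3294,40,0,0.09,45.80,19.31
NWHI,Pearl & Hermes,27.876,-175.799,1,8498,0,0,0.12,46.10,19.69
NWHI,Lisianski,26.016,-173.941,0,30955,0,0,0.10,42.01,21.33
NWHI,Laysan,25.773,-171.730,0,3400,0,0,0.08,42.26,21.53
NWHI,Maro,25.401,-170.557,1,25607,0,0,0.10,40.56,21.73
NWHI,French Frigate,23.767,-166.228,1,8873,0,0,0.09,39.17,22.78
MHI,Kauai,22.037,-159.568,0,18127,65689,665687,0.09,34.81,23.56
MHI,Niihau,21.917,-160.157,0,9266,170,68021,0.07,34.81,23.65
MHI,Oahu,21.471,-157.956,0,25119,953207,199685,0.08,28.56,23.87
MHI,Molokai,21.102,-157.058,0,12730,7404,1147664,0.09,28.56,23.89
MHI,Lanai,20.850,-156.900,0,3004,3102,1182900,0.08,28.56,24.10
MHI,Maui,20.834,-156.369,0,11122,144444,930397,0.08,29.73,23.85
MHI,Hawaii,19.683,-155.548,0,16840,185079,96224,0.07,26.48,24.12
PRIA,Wake,19.299,166.625,1,280,150,0,0.04,28.03,25.39
PRIA,Johnston,16.746,-169.510,1,713,0,0,0.05,34.03,25.04
PRIA,Kingman,6.405,-162.405,1,351,0,0,0.13,30.32,27.37
PRIA,Palmyra,5.877,-162.092,1,2793,20,0,0.12,30.32,27.30
PRIA,Howland,0.807,-176.620,0,173,0,0,0.18,21.49,27.34
PRIA,Baker,0.194,-176.474,0,390,0,0,0.19,20.85,27.46
PRIA,Jarvis,-0.374,-159.993,0,366,0,0,0.21,24.90,26.52
Am. Samoa,Swains,-11.056,-171.080,0,281,17,0,0.05,21.15,27.91
Am. Samoa,Ofu & Olosega,-14.172,-169.649,0,1055,353,55149,0.04,23.40,27.11
Am. Samoa,Tau,-14.240,-169.464,0,1003,790,54712,0.04,23.40,27.15
Am. Samoa,Tutuila,-14.295,-170.681,0,4888,55149,353,0.06,22.34,27.12
Am. Samoa,Rose,-14.543,-168.156,1,110,0,1143,0.04,27.12,26.94
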