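time_h,plasma_ngml,plasma_sd,milk_ngml,milk_sd
12,NA,NA,1791.4,672.02
24,NA,NA,1167.0,264.23
36,NA,NA,763.7,226.64
48,NA,NA,364.8,109.83
60,NA,NA,281.1,103.50
72,NA,NA,140.3,30.71
84,NA,NA,154.1,45.25
96,NA,NA,107.1,23.03
108,NA,NA,131.4,39.94
120,NA,NA,90.6,23.20
132,NA,NA,56.7,15.54
144,NA,NA,59.2,14.50
156,NA,NA,50.2,9.61
168,NA,NA,41.0,11.11
180,152.5,39.03,1392.8,363.32
192,105.8,44.82,1096.9,151.09
204,75.1,36.48,789.3,292.69
216,61.9,20.64,424.9,168.10
228,39.3,19.24,230.1,101.49
240,46.2,18.20,164.0,68.47
252,39.3,10.90,131.2,41.73
264,29.1,12.87,105.3,33.04
276,20.1,8.77,74.7,24.81
288,22.5,5.94,78.3,21.99
300,20.0,5.20,91.6,29.83
312,12.6,4.34,88.9,26.16
324,11.7,3.66,85.2,28.94
336,28.5,18.61,68.4,16.72
348,12.9,5.94,52.5,26.43
360,NA,NA,64.3,20.39
372,NA,NA,26.9,8.23
384,NA,NA,47.7,16.54
396,NA,NA,46.7,18.93
408,NA,NA,45.9,16.43
420,NA,NA,37.0,15.74
432,NA,NA,32.8,10.11
444,NA,NA,30.3,10.55
456,NA,NA,24.0,7.51
468,NA,NA,23.9,7.56
480,NA,NA,22.1,10.49
492,NA,NA,23.3,14.07
504,NA,NA,25.4,12.87
540,NA,NA,20.6,6.28
588,NA,NA,12.0,4.25
636,NA,NA,8.3,3.55
684,NA,NA,8.0,4.91
732,NA,NA,6.5,1.42
780,NA,NA,6.0,2.21
828,NA,NA,4.1,3.06
876,NA,NA,1.9,2.12
948,NA,NA,4.1,1.98
1020,NA,NA,2.0,2.21
1092,NA,NA,0.9,1.66
1164,NA,NA,1.5,2.11
1284,NA,NA,1.2,1.71
1380,NA,NA,0.5,1.40
1452,NA,NA,0.0,0.00
1524,NA,NA,0.0,0.00
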