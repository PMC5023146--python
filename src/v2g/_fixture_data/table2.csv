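patient,1G-BF,1G-BE,2G-BF,2G-EF,2G-BE,2G-EE
P1,2.914,56.92,4.19,29.32,76.16,27.41
P2,9.034,65.35,8.66,43.46,109.90,29.65
P3,1.551,41.03,2.62,21.21,58.93,17.46
P4,3.655,64.06,5.53,33.56,89.91,30.62
P5,9.564,82.41,9.58,55.91,127.76,30.45
P6,2.314,61.89,2.59,34.02,92.17,16.02
P7,2.160,33.45,2.09,17.13,46.03,9.82
P8,2.042,41.97,2.25,21.68,62.14,13.19
P9,7.880,172.05,7.43,57.61,161.20,35.88
P10,13.229,82.90,13.19,52.42,121.48,36.46
P11,15.832,82.42,16.63,50.78,109.86,46.13
P12,2.638,83.11,2.86,56.68,146.04,25.21
P13,17.799,191.73,10.30,59.89,151.85,33.71
P14,3.232,65.36,4.75,34.79,89.98,24.25
P15,15.027,154.31,13.90,77.69,182.61,53.04
P16,8.307,76.18,8.17,43.40,108.53,32.93
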