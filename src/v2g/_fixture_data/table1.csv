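patient,sex,age,EDV_pre,ESV_pre,EF_pre,EDV_post,ESV_post,EF_post,dEF
P1,M,22.5,406.9,254.5,37.5,188.3,115.0,38.9,1.4
P2,F,38.5,328.8,196.0,40.4,168.3,106.0,37.0,-3.4
P3,M,47.7,408.8,254.8,37.7,327.2,212.3,35.1,-2.6
P4,M,50.0,364.6,239.5,34.3,220.0,150.9,31.4,-2.9
P5,F,42.0,323.3,177.8,45.0,222.2,113.3,49.0,4.0
P6,F,14.3,204.0,104.3,48.8,136.5,62.3,54.4,5.6
P7,F,15.3,193.7,105.1,45.7,177.9,84.8,52.3,6.6
P8,M,17.0,188.3,108.3,42.5,135.5,75.2,44.5,2.0
P9,F,56.9,385.1,184.6,52.1,216.4,142.6,34.1,-18.0
P10,M,11.6,204.2,121.3,40.6,156.3,106.0,32.2,-8.4
P11,M,43.5,665.1,464.0,30.2,391.0,332.4,15.0,-15.2
P12,M,54.1,334.8,170.8,49.0,306.2,177.6,41.0,-7.0
P13,F,49.5,277.2,151.3,45.4,244.8,145.9,40.4,-5.0
P14,M,17.8,365.0,178.0,51.2,292.1,170.2,41.7,-9.5
P15,F,44.6,299.0,186.0,37.8,218.7,163.0,25.5,-12.3
P16,F,45.3,571.1,371.3,35.0,398.7,312.6,21.6,-13.4
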