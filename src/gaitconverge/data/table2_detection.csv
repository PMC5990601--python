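patient_id,locomotion_type,tp,tn,fp,fn,sensitivity,specificity,annotated_days,recorded_days
1,wheelchair,1.49,96.15,0.44,1.92,40.22,99.54,4,11
2,walker,4.79,87.04,5.92,2.25,69.99,93.64,5,8
3,wheelchair,0.27,96.30,3.25,0.18,63.11,96.74,3,10
4,walker,1.81,94.03,3.02,1.14,76.17,96.94,6,7
5,walker,2.60,92.52,4.06,0.83,72.30,95.80,10,10
6,walker,3.76,88.68,6.72,0.84,86.80,93.02,10,11
7,wheelchair,0.06,99.01,0.90,0.02,75.88,99.10,3,9
8,walker,2.07,89.23,8.56,0.15,88.83,91.28,8,11
9,walker,4.73,90.38,3.82,1.07,80.91,95.95,7,7
10,wheelchair,0.70,96.64,0.30,2.36,23.55,99.69,5,9
11,walker,4.12,88.21,6.86,0.81,84.29,92.82,8,9
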