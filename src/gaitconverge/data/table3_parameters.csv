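patient_id,locomotion_type,manual_dur_aff,manual_dur_nonaff,manual_cad_aff,manual_cad_nonaff,manual_count_aff,manual_count_nonaff,algo_dur_aff,algo_dur_nonaff,algo_cad_aff,algo_cad_nonaff,algo_count_aff,algo_count_nonaff,relerr_dur_aff,relerr_dur_nonaff,relerr_cad_aff,relerr_cad_nonaff,relerr_count_aff,relerr_count_nonaff
1,wheelchair,2.09,2.10,32.37,28.78,9,8,1.72,1.51,28.40,31.80,8,9,17.70,28.10,12.26,-10.49,11.11,-12.50
2,walker,1.17,1.18,50.96,51.46,103,104,1.14,1.13,53.26,53.41,104,105,2.56,4.24,-4.51,-3.79,-0.97,-0.96
3,wheelchair,1.24,1.24,46.36,46.36,53,53,1.23,1.24,45.94,46.20,50,51,0.81,0.00,0.91,0.35,5.66,3.77
4,walker,1.06,1.06,56.76,56.76,76,76,1.07,1.06,56.42,56.82,75,76,-0.94,0.00,0.60,-0.11,1.32,0.00
5,walker,1.34,1.34,45.21,44.73,93,92,1.38,1.36,44.23,44.46,88,89,-2.99,-1.49,2.17,0.60,5.38,3.26
6,walker,1.30,1.27,46.19,47.37,39,40,1.28,1.23,49.34,49.76,40,41,1.54,3.15,-6.82,-5.05,-2.56,-2.50
7,wheelchair,1.92,1.92,32.48,32.48,11,11,1.91,1.92,34.17,35.33,10,11,0.52,0.00,-5.20,-8.77,9.09,0.00
8,walker,1.14,1.14,50.63,51.71,47,48,1.07,1.07,61.17,61.38,48,49,6.14,6.14,-20.82,-18.70,-2.13,-2.08
9,walker,1.26,1.27,47.60,47.60,86,86,1.29,1.29,47.75,48.05,83,84,-2.38,-1.57,-0.32,-0.95,3.49,2.33
10,wheelchair,2.76,2.73,21.96,21.96,10,10,2.73,2.68,22.80,23.89,9,10,1.09,1.83,-3.83,-8.79,10.00,0.00
11,walker,1.26,1.27,47.12,47.60,98,99,1.25,1.23,49.40,49.40,98,99,0.79,3.15,-4.84,-3.78,0.00,0.00
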