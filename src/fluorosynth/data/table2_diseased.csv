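day,mu_f0_h,sigma_f0_h,mu_fm_h,sigma_fm_h,mu_f0_d,sigma_f0_d,mu_fm_d,sigma_fm_d
0,62.86,15.25,418.49,88.84,56.08,18.36,257.26,89.57
2,64.76,16.33,432.51,95.46,66.99,21.06,299.42,93.2
5,67.17,16.79,438.92,96.36,74.87,21.67,302.2,89.98
6,67.4,17.14,444.77,99.07,77.42,21.81,308.15,89.77
7,68.79,17.4,447.74,99.96,75.1,22.18,305.9,91.56
8,67.26,16.99,441.19,98.53,71.9,22.34,304.12,92.37
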