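day,mu_f0,sigma_f0,mu_fm,sigma_fm
1,92.48,33.89,636.95,217.8
5,104.84,33.24,711.33,200.27
6,106.67,32.88,735.35,195.82
7,101.21,31.11,735.91,192.7
8,104.88,33.19,710.82,199.74
11,107.99,29.46,785.74,183.04
12,111.12,29.5,800.9,179.16
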