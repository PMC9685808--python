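delta,min,max
d_mu_f0,0.07,0.12
d_sigma_f0,0.27,0.32
d_mu_fm,0.3,0.32
d_sigma_fm,0.06,0.09
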