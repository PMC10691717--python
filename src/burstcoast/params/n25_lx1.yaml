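label: 1.0
alpha: 0.67
l_c: 2.0
k: 2
d_ali: 30.0
d_att: 30.0
v_bar: 133.0
l_m: 46.0
gamma_m: 0.6
d_m: 30.0
gamma_R: 0.08
gamma_w: 0.2
l_w: 32.0
tau0: 0.63
tau_bar: 0.397
tau_min: 0.194
gamma_att: 0.035
l_att: 60.0
gamma_ali: 0.68
l_ali: 33.0
l_bar: 32.0
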