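label: 1.5
alpha: 0.67
l_c: 2.0
k: 2
d_ali: 30.0
d_att: 30.0
v_bar: 140.0
l_m: 56.0
gamma_m: 0.6
d_m: 30.0
gamma_R: 0.4
gamma_w: 0.24
l_w: 38.0
tau0: 0.76
tau_bar: 0.397
tau_min: 0.194
gamma_att: 0.6
l_att: 120.0
gamma_ali: 0.44
l_ali: 67.0
l_bar: 48.0
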