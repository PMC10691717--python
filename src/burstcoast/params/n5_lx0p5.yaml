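label: 0.5
alpha: 0.67
l_c: 2.0
k: 2
d_ali: 30.0
d_att: 25.0
v_bar: 155.0
l_m: 34.0
gamma_m: 0.6
d_m: 30.0
gamma_R: 0.06
gamma_w: 0.2
l_w: 25.0
tau0: 0.39
tau_bar: 0.274
tau_min: 0.134
gamma_att: 0.27
l_att: 38.0
gamma_ali: 0.55
l_ali: 38.0
l_bar: 8.0
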