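label: 5.0
alpha: 0.67
l_c: 2.0
k: 2
d_ali: 30.0
d_att: 30.0
v_bar: 153.0
l_m: 64.0
gamma_m: 0.6
d_m: 30.0
gamma_R: 0.1
gamma_w: 0.2
l_w: 44.0
tau0: 0.71
tau_bar: 0.512
tau_min: 0.25
gamma_att: 0.045
l_att: 72.0
gamma_ali: 0.62
l_ali: 38.0
l_bar: 46.0
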