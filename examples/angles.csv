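label,theta_f_deg,theta_s_deg
alpha,4,13
beta,4,38
gamma,23,30
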