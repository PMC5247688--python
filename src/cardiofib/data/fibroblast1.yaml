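C_F: 6.3
g_Kv: 0.25
g_K1: 0.4822
g_bNa: 0.0095
P_NaK: 2.002
K_mK: 1.0
K_mNa: 10.0
kv_shift: 0.0
V_FR_target: -49.7
K_o: 5.4
Na_o: 130.011
K_i: 129.4349
Na_i: 8.5547
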