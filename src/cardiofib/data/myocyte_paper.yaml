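g_Na: 14.838
g_CaL: 3.98e-05
g_to: 0.294
g_Kr: 0.153
g_Ks: 0.392
g_K1: 5.405
g_pCa: 0.1238
g_pK: 0.0146
g_bNa: 0.00029
g_bCa: 0.000592
P_NaK: 2.724
k_NaCa: 1000.0
x: 1.0
y: 1.0
tau_f_scale: 0.5
g_cal_ead_scale: 2.0
K_o: 5.4
Na_o: 140.0
Ca_o: 2.0
C_m_total: 185.0
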