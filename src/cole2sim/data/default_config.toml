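[post_transcriptional]
alpha_M = 20.0
alpha_A = 58.52
alpha_S = 2.6136363636363638
N = 22.0
delta_M = 0.2
delta_A = 0.002
delta_S = 0.2
k_M = 4.0
k_S = 4.0
p_M = 1.0
p_S = 1.0
n_sos = 20
cell_volume = 0.65

[sos]
alpha_lexA = 0.125
delta_lexA_mrna = 0.2
beta_lexA = 20.0
delta_lexA = 0.025
alpha_recA = 0.25
delta_recA_mrna = 0.2
beta_recA = 8.0
delta_recA = 0.004
k_on_lexA = 0.01
k_off_lexA = 1.0
k_on_recA = 0.01
k_off_recA = 1.0
k_on_sos = 0.05
k_off_sos = 0.05
alpha_Ml = 1.2
alpha_Ms = 5.0
delta_Ms = 0.2
gamma_cleave = 0.002
beta_L = 0.1
delta_L = 0.02
lexA_promoters = 1
recA_promoters = 1

[schedule]
breakpoints = [[0.0, 0.0], [200.0, 6.0], [500.0, 0.0]]

[run]
t_max = 700.0
n_realizations = 500
seed = 0
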