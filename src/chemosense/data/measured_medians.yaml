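# Population-median parameters of typical E. coli cells (aspartate sensing),
# one background block per measured c0. Units: um, s, uM; g in 1/mm.
# Swim and noise parameters vary only weakly with background; the 1 uM medians
# are reused at 0.1 and 10 uM. kD here is the rounded literature value 1.2e5
# (first-principles 4*D*l gives 1.156e5).
D_um2_per_s: 800.0
l_um: 0.06
kD: 1.2e5
sigma_v2: 146.0       # (um/s)^2
tau_v: 1.19           # s
P_run: 0.85
tau_1: 0.0            # s (delta-function fast lobe)
tau_2: 7.4            # s
D_n: 8.1e-4           # 1/s
tau_n: 8.7            # s
a0: 0.3
G_inf: 3.5
K_i: 0.81             # uM
g_per_mm: 0.05
uncertainty:          # SEMs of the population-median values (c0 = 1 uM)
  sigma_v2: 5.0
  tau_v: 0.01
  tau_2: 0.3
  G_r_times_kD: 0.05
  D_n: 0.9e-4
  tau_n: 0.9
backgrounds:
  - c0_uM: 0.1
    G_r_times_kD: 3.2
  - c0_uM: 1.0
    G_r_times_kD: 2.28
  - c0_uM: 10.0
    G_r_times_kD: 0.251
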