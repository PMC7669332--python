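# Randomly connected heterogeneous variant: 70% connection probability,
# noisy heterogeneous background to the inhibitory population, slower
# excitatory and faster inhibitory synaptic decay, weaker mean stimulus.
m_s: 3.0
delta_s: 0.5
sigma_n_s: 0.5
m_b: 2.4
delta_b: 0.1
sigma_n_b: 0.5
n_e: 450
n_i: 150
rho: 0.7
g_ee: 0.005                  # 3 / (n_e + n_i)
g_ei: 0.005                  # 3 / (n_e + n_i)
g_ie: 0.03333333333333333    # 20 / (n_e + n_i)
g_ii: 0.03333333333333333    # 20 / (n_e + n_i)
tau_m_e: 50.0
tau_m_i: 25.0
r_e: 1.0
r_i: 1.0
v_leak: -65.0
v_thresh: -63.0
v_reset: -65.0
tau_d_e: 20.0
tau_r_e: 0.1
e_syn_e: 0.0
tau_d_i: 5.0
tau_r_i: 0.1
e_syn_i: -75.0
delay: 3.5
dt: 0.05
duration: 300.0
init_policy: at-reset
noise_scaling: none
bin_width: 0.01
log_base: 2.0
seed: 0
n_repeats: 20
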