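# Fully connected E/I baseline: 450 excitatory / 150 inhibitory neurons,
# all-to-all coupling, homogeneous constant background to the inhibitory
# population.  This is the noise condition (sigma_n_s = 0.5); set
# sigma_n_s: 0 for the noise-free variant.
m_s: 4.0
delta_s: 0.5
sigma_n_s: 0.5
m_b: 2.4
delta_b: 0.0
sigma_n_b: 0.0
n_e: 450
n_i: 150
rho: 1.0
g_ee: 0.002                  # 1.2 / (n_e + n_i)
g_ei: 0.002                  # 1.2 / (n_e + n_i)
g_ie: 0.011666666666666667   # 7 / (n_e + n_i)
g_ii: 0.011666666666666667   # 7 / (n_e + n_i)
tau_m_e: 50.0
tau_m_i: 10.0
r_e: 1.0
r_i: 1.0
v_leak: -65.0
v_thresh: -63.0              # calibrated threshold, see docs/methods.md
v_reset: -65.0
tau_d_e: 6.0
tau_r_e: 0.1
e_syn_e: 0.0
tau_d_i: 6.0
tau_r_i: 0.1
e_syn_i: -85.0
delay: 0.2
dt: 0.05
duration: 300.0
init_policy: at-reset
noise_scaling: none
bin_width: 0.01
log_base: 2.0
seed: 0
n_repeats: 20
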