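# Anterior spinal-cord-like synthetic run, all defaults made explicit
preset: anterior-like
seed: 1
t_half: 3.0            # assumed reporter mRNA half-life, hours
sat_max_frac: 0.05     # drop records with >5% saturated pixels
smooth_window: 6       # moving-average window, time points (36 min)
smooth_iterations: 1
window_start: 10.0     # analysis window, hpf
window_end: 15.0
onset_threshold: 0.025 # normalized-activity onset threshold
onset_persistence: 3   # time points (18 min)
on_threshold: 0.05     # AU/hr^2, "promoter on" level for response time
k_min: 5
k_max: 25
n_perm: 200
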