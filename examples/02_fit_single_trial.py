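"""Fit a kernel to one synthetic trial and check what was recovered.

A trial is generated with a known ground-truth kernel: a 5 s odor-like
stimulus drives a calcium trace (difference-of-exponentials kinetics),
which is convolved with the kernel to produce the vascular trace, plus a
little observation noise.  The multi-run simulated-annealing protocol then
fits a kernel from the data alone, and we compare peak times.
"""

from nvctf import FitConfig, SimConfig, cut_trial, fit_tf, make_trial, tf_peak_time

config = SimConfig(noise_sd_to=0.05, seed=8)  # 5% noise on the vascular trace
trial = cut_trial(make_trial(config))  # restrict to the 5-27 s fit window

print(f"ground-truth kernel : {config.true_tf}")
print(f"true peak time      : {tf_peak_time(config.true_tf):.3f} s")

# 12 annealing runs x up to 2 iterations keeps this example quick; the
# full protocol uses 50 runs x up to 3 iterations (see FitConfig defaults).
result = fit_tf(
    trial.from_sig,
    trial.to_sig,
    FitConfig(runs_per_iteration=12, max_iterations=2, seed=3),
)

print(f"fitted kernel       : {result.params}")
print(f"fitted peak time    : {tf_peak_time(result.params):.3f} s")
print(f"prediction Pearson r: {result.pearson_r:.4f}")
print(f"annealing runs used : {len(result.history)}")
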