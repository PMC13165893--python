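"""Decompose one contaminated epoch with all four families and compute the
oracle reconstruction for each.

The oracle solves min_w ||X - C^T w||^2 with 0 <= w_k <= 1: the best-case
recombination of components given the clean reference X.  Its RRMSE is an
upper bound on what any component-selection denoiser could recover from the
same decomposition — lower is better, and all-ones weights reproduce the
noisy input for the additively exact families.
"""

import numpy as np

import eegoracle as eo

rng = np.random.default_rng(1)
pools = {
    "eeg": eo.synth_eeg(rng, 10),
    "eog": eo.synth_eog(rng, 10),
    "emg": eo.synth_emg(rng, 10),
}
epoch = eo.build_benchmark(pools, eo.BenchmarkConfig(n_eog=0, n_emg=0, n_mixed=1), rng)[0]
print(f"mixed epoch at Z_tot = {epoch.Z_tot:+.2f} dB "
      f"(EOG share r = {epoch.share_r:.2f}); "
      f"unprocessed RRMSE = {eo.noisy_baseline_rrmse(epoch):.3f}\n")

configs = [
    eo.MethodConfig.make("ssa", L=128),
    eo.MethodConfig.make("dwt", wName="coif3", J=8),
    eo.MethodConfig.make("vmd", K=12),
    eo.MethodConfig.make("ceemdan", Nstd=0.2, NR=30, MaxIMF=12),
]
print(f"{'config':34s} {'K_eff':>5s} {'rrmse':>7s} {'pcc':>7s} {'t_dec':>8s}")
for cfg in configs:
    cs = eo.timed_decompose(epoch.Y, cfg, rng=np.random.default_rng(7))
    res = eo.evaluate_epoch(epoch, cs)
    print(f"{cfg.label:34s} {cs.K_eff:5d} {res.rrmse:7.3f} {res.pcc:7.3f} "
          f"{cs.t_dec:7.4f}s")

print("\nevery family beats the unprocessed baseline: the oracle keeps the"
      "\ncomponents that overlap the clean EEG and attenuates the rest.")
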