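"""Rank the four decomposition families per epoch and test pairwise gaps.

Within each epoch the families are ranked by oracle RRMSE (1 = best); the
stratum summary is the rank distribution P1|P2|P3|P4 with the mean rank,
plus paired Wilcoxon signed-rank tests (Holm-corrected within stratum),
median paired differences and win rates.
"""

import numpy as np
import pandas as pd

import eegoracle as eo

rng = np.random.default_rng(5)
pools = {
    "eeg": eo.synth_eeg(rng, 40),
    "eog": eo.synth_eog(rng, 30),
    "emg": eo.synth_emg(rng, 30),
}
epochs = eo.build_benchmark(pools, eo.BenchmarkConfig(n_eog=40, n_emg=0, n_mixed=0), rng)

configs = {
    "ssa": eo.MethodConfig.make("ssa", L=128),
    "dwt": eo.MethodConfig.make("dwt", wName="coif3", J=8),
    "vmd": eo.MethodConfig.make("vmd", K=12),
    "ceemdan": eo.MethodConfig.make("ceemdan", Nstd=0.2, NR=30, MaxIMF=12),
}
rows = []
for i, epoch in enumerate(epochs):
    for fam, cfg in configs.items():
        cs = eo.decompose(epoch.Y, cfg, rng=np.random.default_rng(100 + i))
        rows.append({
            "epoch_id": epoch.epoch_id, "kind": epoch.kind, "bin": eo.assign_bin(epoch),
            "family": fam, "rrmse": eo.evaluate_epoch(epoch, cs).rrmse,
        })

rank_tables, paired = eo.run_comparison(pd.DataFrame(rows))
all_bin = next(rt for rt in rank_tables if rt.bin == "ALL")
print(f"rank distribution over {all_bin.n} ocular epochs (P1|P2|P3|P4, mean rank):")
for fam in all_bin.methods:
    print(f"  {fam:8s} {all_bin.row(fam)}")

print("\npairwise tests in the pooled bin (median diff of RRMSE, win rate, Holm p):")
for s in paired:
    if s.bin == "ALL":
        print(f"  {s.a:8s} vs {s.b:8s}  d_med={s.median_diff:+.4f}  "
              f"win={s.win_rate:.2f}  p_holm={s.p_holm:.2e}")

print("\na P1 column near 100 means that family recovered the cleanest EEG "
      "on nearly\nevery epoch; Holm-adjusted p-values guard the six pairwise "
      "comparisons per stratum.")
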