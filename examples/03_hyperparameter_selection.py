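"""Best / Opt1 / Opt2 hyperparameter selection for one family.

A small ocular benchmark is evaluated over a thinned SSA window grid; per
(kind, NSR-bin) stratum three configurations are selected:

* Best — lowest mean oracle RRMSE, runtime ignored;
* Opt1 — fastest configuration whose per-epoch RRMSE distribution is within
  |Cohen's d| <= 0.05 of Best (effectively tied, but cheaper);
* Opt2 — Pareto front over (mean RRMSE, mean latency), utopia-nearest point.
"""

import numpy as np

import eegoracle as eo
from eegoracle.pipeline import RunConfig, evaluate_grid, synthesize
from eegoracle.selection import selection_table

config = RunConfig(
    seed=3,
    benchmark=eo.BenchmarkConfig(n_eog=60, n_emg=0, n_mixed=0),
    pool_sizes={"eeg": 40, "eog": 30, "emg": 30},
    families=("ssa",),
    grid_indices={"ssa": [0, 4, 9, 15, 21, 27]},  # L = 8, 40, 80, 128, 176, 224
)
epochs = synthesize(config)
results = evaluate_grid(epochs, config.grids(), seed=config.seed)
triples = eo.run_selection(results, d0=0.05)

table = selection_table(triples)
cols = ["kind", "bin", "n", "best", "best_rrmse", "opt1", "opt1_tdec", "d_opt1", "opt2"]
print(table[cols].to_string(index=False))

print("\nBest ignores cost; Opt1 trades at most a 0.05-standard-deviation "
      "RRMSE\nincrease for speed; Opt2 balances the two objectives on the "
      "Pareto front.")
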