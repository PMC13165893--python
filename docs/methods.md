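# Methods

## The oracle-recoverability model

Every benchmark epoch is a linear, instantaneous mixture of a clean 2 s
single-channel EEG segment `X` (125 Hz, T = 250 samples) with scaled
ocular and/or myogenic artifact exemplars:

```
Y = X + λ_EOG · N_EOG + λ_EMG · N_EMG
```

The gains are set from target noise-to-signal ratios (NSR, dB)

```
Z = 10 · log10( λ² · mean(N²) / mean(X²) ),
```

inverted as `λ = sqrt(10^(Z/10) · mean(X²)/mean(N²))`. Targets are drawn
uniformly from [−10, 10] dB; a floor of −10 dB labels an absent modality
(stored as an exact zero vector by default; a config flag instead mixes the
inactive modality at the floor). Mixed epochs draw a total NSR `Z_tot`,
convert to linear power `q_tot = 10^(Z_tot/10)` and split it by an ocular
share `r ∈ [0,1]`: `q_EOG = r·q_tot`, `q_EMG = (1−r)·q_tot`. The share is
drawn under three patterns: uniform, and Beta(1+4z̃, 1+4(1−z̃)) with
z̃ = (Z_tot+10)/20 (increasing with Z_tot) or its mirror (decreasing) —
the named patterns fix only monotonicity, so the Beta family is this
package's concrete choice, config-exposed. The default design is 1250
EOG-only + 1250 EMG-only + 2000 mixed epochs (mixed allocated 667/667/666
to the three patterns), stratified into NSR bins [−10,−5), [−5,0), [0,5),
[5,10] (top bin closed) plus the pooled range; binning uses Z_EOG, Z_EMG or
Z_tot according to the epoch kind.

Two consequences used throughout as exact oracles on the construction:
`Y − X` equals the stored artifact sum to machine precision, and for
single-artifact epochs the unprocessed error obeys
`‖X−Y‖/‖X‖ = 10^(Z/20)` identically.

A decomposition of `Y` into components `c_1..c_K` is scored by the
box-constrained least-squares recombination

```
min_w ‖X − Cᵀw‖²   s.t. 0 ≤ w_k ≤ 1,
```

a convex problem solved with bounded-variable least squares
(`scipy.optimize.lsq_linear`, BVLS, trust-region fallback), with a
projected-gradient optimality check at the solution (tolerance 1e-6 scaled
by ‖CᵀC‖₂). All-zero component rows are dropped and reported with weight 0.
Because all-ones weights reproduce `Y` for additively exact families, the
oracle RRMSE can never exceed the unprocessed baseline there; for VMD the
bound is baseline + reconstruction gap (below). PCC over an epoch is
undefined when either vector is constant; such epochs carry a NaN flag and
are excluded from PCC aggregation only.

## Decomposition families

All families share one contract: components are rows of a `K_eff × T`
matrix that (approximately) sum to `Y`; latency is wall-clock seconds of
the decomposition call only.

**SSA.** The epoch is embedded into the `L × (T−L+1)` Hankel trajectory
matrix and factored by SVD; every singular triple with σ > 1e-12·σ₁ is
diagonal-averaged back to a length-T series (implemented as a convolution
of the singular vectors divided by anti-diagonal counts). No grouping is
applied — the oracle's weights subsume grouping. Components are ordered by
decreasing singular value; the sum over all components reconstructs `Y`
exactly. Window grid: L = 8, 16, …, 248. A caution for interpretation:
when two oscillations have nearly equal amplitude their singular values are
nearly degenerate and the SVD may rotate within the joint subspace, so
individual pairs mix the oscillations even though the total is exact.

**DWT sub-bands.** `pywt.wavedec` with periodization boundary handling;
each sub-band (approximation + J details) is inverted alone with all other
coefficients zeroed, giving K_eff = J_eff + 1 components that sum to `Y`
to reconstruction round-off. Grid: {sym4, db4, coif3} × J ∈ {4,…,16}.
Depths are clamped to J_eff = min(J, floor(log2 T)) = 7 at T = 250: with
periodization every level up to that depth is well defined and perfectly
reconstructing regardless of filter length, and the clamp reproduces the
observed saturation of deep-level settings (J = 16 behaves like J = 8).
The conventional filter-length-based maximum level would forbid the
depth-6 shrinkage baseline for coif3, so it is deliberately not used.

**VMD.** In-package implementation of the variational formulation:
frequency-domain ADMM on the mirror-extended signal's half-spectrum, with
Wiener-style mode updates and power-weighted center-frequency updates.
Frozen defaults: penalty α = 2000, no dual ascent (τ = 0), tolerance 1e-7
on the spectral update energy relative to the signal's spectral energy,
500 iterations maximum, center frequencies initialized uniformly over
[0, 0.5) — all fixed in `_vmd.py` so runs are exactly reproducible; only
the mode count K ∈ {4,…,24} is swept. Uniform initialization was chosen
over all-zero because coincident starts can collapse modes onto the lowest
band. With τ = 0 the additivity constraint is soft: broadband energy far
from every mode center is attenuated by the narrow Wiener filters, so the
mode sum reconstructs `Y` only up to a residual (`recon_gap`,
‖Y−Σc_k‖/‖Y‖). On broadband synthetic epochs this gap routinely exceeds
the nominal 0.05 tolerance (means around 0.2); enforcing exactness by dual
ascent needs orders of magnitude more iterations and destabilizes the
center frequencies at large step sizes, so the gap is recorded per epoch,
logged when above tolerance, and folded into the dominance bound instead.
Non-convergence returns the best iterate with a warning.

**CEEMDAN.** In-package EMD with cubic-spline envelopes through local
extrema (two extrema mirrored across each boundary, natural end
conditions), Cauchy-type sift stop (relative change < 0.2, at most 12
sifts). The complete-ensemble scheme with adaptive noise perturbs the
current residual with a scaled IMF of each white-noise realization
(stage-0: the raw noise at amplitude Nstd; later stages:
ε_k = Nstd·std(r_k) times the k-th noise IMF), extracts the first IMF of
each perturbed residual and averages over the NR realizations. Residuals
are defined by exact subtraction, so IMFs + final residual sum to `Y` to
machine precision for any ensemble size. Noise is seeded per (epoch,
config), making ensembles reproducible. Grid: Nstd ∈ {0.1,0.2,0.3},
NR ∈ {30,50,100}, MaxIMF ∈ {8,12,16}; the final residual always joins the
component stack (K_eff ≤ MaxIMF + 1).

## Hyperparameter selection

Per (family, kind, bin) stratum, every grid configuration is summarized by
its mean/sd oracle RRMSE, mean PCC and mean decomposition latency over the
identical epoch set (a violated paired design is an error; strata with
fewer than two epochs never enter selection). Three selectors:

- **Best**: argmin mean RRMSE (ties: smaller latency, then grid order).
- **Opt1**: Cohen's d of each config against Best —
  `d = (μ_h − μ_Best)/s_pooled` with n−1 pooled variances (zero spread with
  unequal means maps to signed infinity) — then the fastest config with
  |d| ≤ d₀ = 0.05, a deliberately stringent "visually negligible"
  threshold (ties: smaller RRMSE, then grid order). Best itself always
  qualifies, so the tolerance set is never empty.
- **Opt2**: Pareto front over (mean RRMSE, mean latency), min–max rescaled
  over the front (a zero-range objective maps to 0, leaving distance to
  depend on the informative objective alone), utopia-nearest point (ties:
  smaller RRMSE, then grid order). The selection is invariant to positive
  affine transformations of either raw objective. For VMD, mode counts
  K < 7 are excluded from the Opt2 analysis only (they are uniformly poor
  and would distort the front's scaling); a config flag disables the floor.

All tie-breaking rules are this package's own determinism choices.

## Baseline and comparison protocol

The practical wavelet-shrinkage baseline decomposes `Y` to depth 6
(periodization), soft-thresholds all detail levels with the single
universal threshold `t = σ̂·sqrt(2·ln T)`, σ̂ = median(|d₁|)/0.6745
estimated from the finest-scale details only (per-level estimation is a
config option), leaves the approximation band untouched and inverts. It is
evaluated with the same RRMSE/PCC metrics and per-epoch pairing as the
oracle, so the oracle of the same depth-6 sub-bands bounds it from below.

Inter-method comparison operates on the per-epoch results at each family's
bin-wise Opt1 configuration. Per (kind, bin) stratum: within-epoch ranks by
RRMSE (1 = lowest; exact float ties — probability ~0 — resolve by fixed
alphabetical family order, so ranks are always a permutation), rank
percentages P1..P4 and mean ranks; all C(4,2) = 6 pairwise Wilcoxon
signed-rank tests (zero differences dropped; exact null for ≤ 25 untied
pairs, tie-corrected normal approximation otherwise; all-zero differences
give p = 1), Holm-adjusted within the stratum; median paired differences
and win rates (ties win for neither side). The pooled ALL row aggregates
epochs evaluated at their own bin's Opt1 configuration, consistent with
"bin-wise Opt1 tuning". PCC-based ranks are available as a secondary view.

## Synthetic exemplars: what they emulate, what they do not

The default generators produce surrogates with the spectral signatures the
benchmark needs, not physiological recordings: clean EEG as 1/f-shaped
Gaussian background plus 1–3 narrowband oscillations at 4–30 Hz; EOG as
1–2 raised-cosine blink transients (200–400 ms, random polarity/position)
over slow drift, putting ≥ 80 % of power below 8 Hz; EMG as 15–60 Hz
band-passed Gaussian noise with amplitude-modulated bursts (ensemble
spectral centroid > 20 Hz). All exemplars are normalized to unit mean
power — the mixture gains fully determine relative power, so exemplar
scale is free. Generators are pure functions of (seed, parameters).

Consequently, passing tests demonstrate the *mechanics* — mixture algebra,
oracle optimality and dominance, selection/comparison rules, and the
qualitative increase of oracle error with contamination — but not the
numeric performance levels attainable on recorded physiology: real blinks
have stereotyped asymmetric shapes, real EMG has heavier tails and
broader-band structure, and real EEG has subject-specific rhythms. With the
EEGdenoiseNet arrays downloaded (EEG/EOG/EMG epochs at 256 Hz; the loader
resamples 512 → 250 samples with polyphase FIR anti-aliasing), the same
pipeline runs on recorded exemplars; at full scale one expects the
rank-comparison tables to favour SSA most often in EMG-contaminated and
mixed strata. This is an extended, data-dependent check, not part of the
test suite.

## Numerical choices and degenerate inputs

- Oracle solver tolerance: projected-gradient condition at 1e-6·‖CᵀC‖₂;
  brute-force grid search (step 0.01) agrees with the solver to < 1e-4 in
  objective on K ≤ 3 instances.
- Exemplars with zero mean power, zero-norm clean references, zero-power
  artifact exemplars, out-of-range NSR labels, empty pools, and unpaired
  result tables are all rejected with explicit errors.
- Epoch counts and proportions are exact; mixed-pattern allocation is
  deterministic (remainders to earlier patterns).
- One integer seed drives everything: exemplar pools, benchmark draws, and
  per-(epoch, config) CEEMDAN noise streams (derived via `SeedSequence`
  spawning), so complete runs are bit-reproducible apart from wall-clock
  latency fields. Because Opt1 selects on measured latency, selections can
  differ across machines even under a fixed seed; all non-timing
  quantities are reproducible.
- Scaled-down problem sizes used by the shipped checks (the package's own
  choice of smoke scale): 200-epoch benchmarks for dominance and the
  shrinkage bound, 600 epochs for the error-versus-contamination pattern,
  one mid-grid configuration per family (vmd K=8, ssa L=40, dwt sym4 J=6,
  ceemdan 0.1/30/8).

## Known limitations

- VMD's reconstruction gap (see above) makes its oracle bound conditional
  on the gap; the other three families are additively exact.
- The run manifest records per-file checksums for corruption detection,
  but `run_all` does not resume partially completed runs; individual
  stages can be re-run via the CLI subcommands on a saved epoch store.
- Statistical tests treat epochs as independent; epochs sharing exemplars
  are correlated, so p-values are exploratory summaries, not confirmatory
  inference.
- No modeling of ECG, line noise, electrode pops, motion artifacts, or
  multichannel structure; gains are constant within an epoch.
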