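# Methods

## Dynamical model

All energies derive from the linear time-invariant system
`dx/dt = A x + B u` on an `n`-parcel structural network with symmetric,
non-negative weights `W` (diffusion-derived connection strengths; zero
diagonal). `A = W / (lambda_max(W) + c) - I` with `c = 1` by default, so the
spectrum of `A` lies in `[-1 - |lambda_min|/(lambda_max + c),
-c/(lambda_max + c)]`: all modes decay, and the slowest decay rate is
`c/(lambda_max + c)`. The constant `c` is exposed in the configuration; the
analysis properties validated here (oracle agreement, scaling laws, recovery
power) do not depend on its exact value. The default actuator set is
`B = I`: every parcel receives independent input with unit weight. Time is
in model units; the default horizon is `T = 1`, likewise configuration-
exposed, and all validated properties hold for any `T > 0`.

This is a deliberately coarse model of neural dynamics: linear, noise-free,
time-invariant, with no state-cost term in the control objective (pure
minimum input energy). Its value is comparative — the same functional is
evaluated across states, sessions, groups and null models — not mechanistic.

## Energies and trajectories

The finite-horizon controllability Gramian is computed by the Van Loan
block-exponential identity: exponentiating `[[A, BBᵀ], [0, -Aᵀ]] T` yields
`Wc(T) = F12 · e^{AᵀT}` from the upper-right block. A composite-Simpson
quadrature route (2001 grid points) is retained as an independent method;
the two agree to ~1e-13 relative Frobenius norm on random stable systems and
are cross-checked in the test suite.

Minimum transition energy is `E = vᵀ Wc⁻¹ v` with `v = xf - e^{AT} x0`.
`Wc` is inverted through a Cholesky factorization guarded by an explicit
condition-number limit of 1e12 (estimated from the symmetric eigenvalues);
beyond it the computation fails loudly, carrying the condition number.
Persistence energy is the self-transition `x0 = xf = x`; it scales exactly
quadratically with state amplitude, which the suite asserts to 1e-10.

The optimal input is sampled on a uniform grid (1001 points by default).
The state trajectory is advanced *exactly* on that grid via
`x_{k+1} = e^{A dt} x_k + Wc(dt) e^{Aᵀ(T - t_{k+1})} Wc(T)⁻¹ v`, a
consequence of the variation-of-constants integral; the endpoint error is
therefore at machine precision rather than an integrator artifact, and the
generic `simulate_trajectory` verifier (exponential step plus trapezoidal
input term) provides an independent O(dt²) check. Per-node input
`e_i = ∫ u_i(t)² dt` uses composite trapezoid, so `sum_i e_i` reproduces `E`
to ~1e-7 relative at the default grid when `B = I`.

Control impact of node `i` removes row/column `i` from the *raw* weights,
re-normalizes the reduced system (the reduced network's own
`lambda_max` — the alternative of reusing the original normalization is a
coherent but different convention), truncates state and actuators, and
reports `(Pe_reduced - Pe_full) / Pe_full`. An actuator-only mode removes
only column `i` of `B`; since that shrinks the feasible input set, its
impact is provably non-negative, which the suite asserts on random systems.

## Null models

*Structural*: degree-preserving double-edge swaps on the binary topology
(default 10 swaps per edge), then the original weight multiset is
reassigned to the surviving edges at random; a variant assigns large
weights to high-degree endpoints to approximately preserve the strength
sequence. Disconnected rewired networks are allowed with a warning (the
Gramian stays invertible for `B = I`).

*Spatial*: uniformly random permutation of each state's in-slab values,
out-of-slab entries untouched. A geometry-respecting (spin-type)
permutation is not implemented because the synthetic parcels carry no
coordinates; with real parcellations the uniform permutation is the more
destructive null, which is the role it plays here.

## Statistical inference

Energy models: one linear mixed model per task × condition cell,
`energy ~ group * drug` with a random intercept per subject (no random
slopes), fit by REML. The outcome is z-scored within the cell by default so
coefficients are in SD units and comparable across cells. Fixed-effect
p-values use a t reference on `df = n_obs - n_fixed` rather than the
asymptotic normal; at crossover sample sizes (40 subjects, 80 observations)
the normal reference was measurably liberal (empirical type-I 0.085 vs
0.075 over the same 200 null cohorts). Efficiency models add
`+ drug + group + age + sex` covariates with the z-scored persistence
energy as the predictor of interest, FDR-corrected across the six cells.
Benjamini–Hochberg is implemented directly (step-up with a running minimum)
and cross-checked against `statsmodels.multipletests` in a test.

Receptor alignment: the statistic is the mean over subjects of the Spearman
correlation between each subject's per-parcel |drug − placebo| control-input
difference and a receptor density map, on in-slab parcels. The null permutes
the receptor map's parcel labels — one shared permutation per iteration
across subjects, preserving the between-subject dependence of the
statistic — with the add-one two-sided p-value
`(1 + #{|null| ≥ |obs|}) / (n_perm + 1)`, 500 permutations by default, and
FDR across receptor maps. Internally ranks are computed once and the
permuted correlations are evaluated as matrix products;
`scipy.stats.spearmanr` serves as the oracle for the observed statistic in
the unit tests.

Demographics: Fisher's exact test with the cross-product odds ratio
oriented as event odds in the first group over the second (event level
explicit in the output; a zero cell yields an undefined OR, no continuity
correction), pooled-variance t-tests (`df = n1 + n2 - 2`) or Wilcoxon
rank-sum z for variables flagged non-normal, and Cohen's d with pooled SD,
signed as group 2 minus group 1.

## Synthetic cohort

The generator emulates the study design: `n_controls + n_relatives`
subjects, each with placebo and drug sessions (complete crossover), two
tasks × three emotion conditions, 233 parcels by default with 60% inside
the imaging slab (out-of-slab parcels zeroed). Each task × condition has a
spatially autocorrelated template (white noise diffused 3 steps along the
network, unit SD); a state is
`template × drug_gain × (1 + delta) + subject_offset + noise`, where
`(1 + delta)` applies only to relatives' drug-session threat-memory states.
Because persistence energy is quadratic in amplitude, the injected
interaction propagates through the genuine control computation as a
`(1 + delta)²` energy ratio (asserted exactly in the noise-free case).

Key defaults and their rationale:

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `delta_interaction` | 0.009 | fraction of amplitude | calibrated by simulation (200 reps) for ~98% power to recover the interaction at 20+20 subjects, 100 nodes, so the ≥80/100 recovery property holds robustly across seeds |
| `subject_sd` | 0.015 | template-SD units | see noise-regime note below |
| `session_noise_sd` | 0.04 | template-SD units | see noise-regime note below |
| `drug_amplitude_effect` | 1.0 | multiplicative | no drug main effect on energy by default, matching the motivating design's null main effects |
| `drug_efficiency_drop` | 0.1 | efficiency (1/s) | sedation lowers performance efficiency in all drug sessions |
| `efficiency_slope` | 0.05 | efficiency per SD of Pe | positive energy–performance coupling in threat identification |
| `base_accuracy` | 0.9 | proportion | accuracy held near ceiling on a clipped logistic; median RT absorbs the efficiency variation |
| `T`, `c` | 1.0, 1.0 | model units | canonical normalization/horizon, exposed in config |

*Noise regime.* The spatial-null contrast is only informative if the
permutation-induced variability of persistence energy exceeds the cohort's
intrinsic noise: a purely amplitude-multiplicative interaction survives
value permutation in expectation, so its z-scaled estimate attenuates by
the factor `CV_noise / sqrt(CV_noise² + CV_perm²)`. The measured
permutation CV of Pe at 100 nodes and 60% slab coverage is ≈ 0.05, so the
generator's noise SDs are set low (combined Pe CV ≈ 0.02) for the
attenuation of the recovered interaction under spatially permuted states to
be decisive (measured ratio ≈ 0.3–0.45 over 20-cohort batches) while the
same cohorts still support near-complete recovery power. This is a
deliberately clean regime: empirical fMRI betas carry far more
between-subject and between-session variance.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: hemodynamics and trial-level structure,
realistic noise magnitudes and heavy-tailed activation distributions,
parcel geometry (no spatial coordinates, hence no distance-dependent
autocorrelation beyond graph diffusion), individual structural matrices
(one group connectome), and receptor maps with realistic cross-map
correlation structure. Recovery of the injected effect shows the chain is
statistically sound at desk scale, not that effects of this size are
detectable in empirical cohorts.

## Validation problem sizes

The simulation studies run at 20+20 subjects and 100 nodes: 100 cohorts for
recovery power, 200 for interaction type-I error, 200 independent-map
simulations (20 subjects × 140 parcels, 500 permutations) for permutation
calibration, and 20 cohorts for the structural/spatial null contrast. The
brute-force control oracle uses exact zero-order-hold discretization over
2000 steps with the minimum-norm input from the pseudoinverse of the
stacked reachability map, on systems of up to 10 nodes and horizons 0.5–3.

## Known limitations

- Mixed-model degrees of freedom use the simple residual convention
  (`n_obs - n_fixed`); Satterthwaite/Kenward–Roger approximations are not
  implemented, and reported df should be read accordingly.
- The Gramian condition guard rejects, rather than regularizes, severely
  under-actuated problems (e.g., a single actuator on a weakly coupled
  network).
- `control_impact` on an `n`-node network re-solves `n` reduced problems
  (one matrix exponential each); for 233 nodes the pipeline stage computes
  impact on group-mean states rather than per record.
- Accuracy/RT decomposition of efficiency is under-determined; the
  generator holds accuracy near its base and lets RT carry the signal, so
  simulated accuracies carry almost no condition information.
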