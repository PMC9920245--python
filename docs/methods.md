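# Methods

## Signal model and simulator

A trunk AE record is modelled as a sum of narrowband AM–FM modes excited
periodically and ringing down exponentially:

    y(t) = Σᵢ Aᵢ(t) cos(2π fᵢ t + φᵢ) + ε(t),   ε ~ N(0, σ²) i.i.d.

The simulator (`signal_sim`) generates records on a uniform grid (phase
integrals by cumulative trapezoid) with three modes at base frequencies
200/500/900 Hz and relative amplitudes 1 / 0.6 / 0.35, each gated by a
summed one-sided exponential envelope restarting at every excitation
(default every 0.15 s). The defaults mirror a 10 kHz / 9 s field record;
desk-scale tests use 2 kHz / 0.4 s.

The latent moisture content enters through a fixed, strictly monotone law
(`mc_to_physics`): ring-down rate `d0·(1 + mc/100)` (wetter wood damps
faster), frequency shift `−0.5·mc` Hz (modes move down), and coupling gain
`g0·exp(−mc/150)`. The constants d0 = 6 s⁻¹, k = 0.5 Hz/%, g0 = 1 were
chosen once so that, over MC ∈ [20, 160] %, the three observables vary by
factors a field practitioner would recognise as a strong but not
caricatured moisture effect (damping ×2.2, shifts up to 80 Hz, gain ×0.4)
while every mode stays inside the Nyquist band at the desk rate. Dataset
noise is specified as a fraction of the principal-mode burst amplitude
(default 5%), emulating a fixed front-end SNR across trees.

What the simulator does **not** emulate: wood anisotropy and dispersion,
sensor/coupling transfer functions, interfering environmental AE sources,
and any nonmonotone or species-dependent MC response. Passing tests
therefore demonstrate that the chain recovers a recoverable latent
variable through this signal family — not field accuracy on real trees.

## ACMD

Each mode is extracted by alternating two steps at a trial frequency
track f̃(t):

* **Demodulation solve.** Minimize `‖Ωm‖² + ‖Ωn‖² + λ‖y − GB‖²` where
  Ω is the (N−2)×N second-difference matrix, G the cos/sin kernel at the
  cumulative phase of f̃ and B = [m; n]. The normal equations
  `(ΛᵀΛ + λGᵀG)B = λGᵀy` are solved with the unknowns interleaved
  (m₀,n₀,m₁,n₁,…), which makes the system 9-banded and the solve O(N)
  (`scipy.linalg.solve_banded`); N up to 10⁵ is routine.
* **Frequency refinement.** The residual phase `δ(t) = arctan2(−n, m)`
  drifts at rate 2π(f − f̃); the corrected track f̃ + δ′/2π is smoothed by
  a constant-preserving ridge smoother `(I + μ ΩᵀΩ)⁻¹` and clipped to
  [0, rate/2]. Where the envelope is numerically zero the previous track
  is held (the phase is undefined there).

Numerical choices. λ defaults to 1e-3 per sample: the smoother
`λ/(λ + 16 sin⁴(ω/2))` then passes ring-down envelopes but attenuates a
300 Hz cross-mode beat at 5 kHz by ~20×, which is what separates closely
spaced tones; an N-scaled λ would let the operators absorb neighbouring
modes. μ (`smooth_bandwidth`) defaults to 1e4 (~80 Hz IF cutoff at 5 kHz).
The inner loop stops when the relative change of the track falls below
1e-4 (typically 1–3 iterations for near-stationary modes); non-convergence
returns the best iterate with a warning flag. Recursion initializes f̃ at
the dominant FFT peak of the residual and stops at a residual energy
fraction of 1% or the mode budget; an extraction that fails to reduce the
residual energy is discarded and stops the recursion, which guarantees the
residual energy decreases strictly across accepted modes and that
components + residual sum to the input exactly (pure bookkeeping).
Estimates within ~5% of the record edges are biased by the
second-difference penalty; tests and features that need unbiased values
exclude those bands.

## Improved grey wolf optimizer

Canonical GWO with distance-control parameter a = 2(1 − t/tmax), step
coefficient A = 2a·r₁ − a and weighting C = 2·r₂ drawn fresh per wolf and
leader; each wolf moves to the mean of the three leader-relative
candidates, clamped to the box. Three additional strategies:

* **Hénon initialization.** The classic Hénon recurrence
  y₁ ← 1 − a·y₁² + y₂, y₂ ← b·y₁(prev) with a = 0.6, b = 0.7 is *not*
  chaotic — it settles on a period-2 orbit — but its transient from random
  starts spans ≈[−2, 2.25] with good coverage. The initializer therefore
  samples short orbits (16 steps, first 2 discarded, seeded restarts;
  divergent orbits restarted), normalizes affinely from [−2, 2.25] to
  [0, 1], clamps, and maps into the box. A 10-bin histogram of 10⁴ samples
  stays within 3× the uniform expectation.
* **Reverse (elite opposition) learning**, once per iteration on the
  incumbent best: `X_op = ub + r∘(lb − X_best)` with r ~ U(0,1) per
  dimension, blended back by `c₁ = ((tmax−t)/tmax)ᵗ` (1 at t = 0, rapidly
  decaying, so late iterations probe near-pure opposition points); the
  incumbent is replaced only on strict improvement.
* **Firefly perturbation** of every wolf relative to the alpha:
  `Y = X + σ(X − X_p) + θ_t·(ub−lb)∘(rand − ½)` with
  `σ = β₀ exp(−γ r²)`, r the Euclidean distance to the alpha normalized
  by the box diagonal, and `θ_t = θ(1 − t/tmax)`. The normalization makes
  the strategy invariant to the scale of the search box (an absolute-units
  γ deactivates the attraction entirely on wide boxes), and the decaying
  jitter turns it from global exploration into local refinement over the
  run. Acceptance is greedy, so the step never worsens a wolf. Defaults
  β₀ = 2, γ = 1, θ = 0.6 were calibrated on a held-out seed set of
  30-dimensional benchmark runs.

A best-so-far archive provides elitism: the recorded history is
non-increasing for every variant and seed, and `converged_at` is the first
iteration whose best-so-far value is within 1e-6 (absolute) of the run's
final best. Objective values that are not finite are treated as +∞. Ties
in leader selection break toward the lower index; one seeded generator
drives a whole run.

Ablation variants follow the usual naming: IGWO₁ (no firefly), IGWO₂ (no
reverse learning), IGWO₃ (no Hénon), IGWO (all three), GWO (none).
Benchmarks use the standard forms and boxes: sphere and Rastrigin on
[−5.12, 5.12]³⁰, Rosenbrock on [−30, 30]³⁰, Schwefel
`418.9829·d − Σ x sin√|x|` on [−500, 500]³⁰.

## Gradient-boosted trees

Squared-error loss: g = ŷ − y, h = 1. For a fixed partition the optimal
leaf weight is `ξ* = −G/(H+η)` and the structure score
`J = −½ Σⱼ Gⱼ²/(Hⱼ+η) + γT`; a split is accepted only if its gain
(score decrease minus γ) is strictly positive. Split search is exact
greedy over all features and midpoints between consecutive distinct sorted
values, vectorized over (position, feature); ties break toward the lower
feature index, then the lower threshold. Stopping: max depth, non-positive
gain, or a child Hessian below `min_child_hessian`. The ensemble adds each
tree with shrinkage ν (default 0.3) from a base score equal to the target
mean; row subsampling uses the seeded generator. η here is the L2 penalty
on leaf weights (the role usually called lambda elsewhere); the symbol is
kept for consistency with the rest of the package.

## Diagnosis pipeline

Features per record: for each of the top-`max_modes` ACMD components
(energy order) the energy share, envelope-weighted mean instantaneous
frequency, envelope peak and envelope decay rate (median negative
log-envelope slope over samples above 10% of peak — robust to the rising
edges of a burst train); plus the means of hit amplitude, ring count and
energy from threshold/HDT hit detection. The decomposition-free baseline
("raw" arm) uses exactly the five standard AE hit parameters (amplitude,
rise time, duration, ring count, energy), record-averaged.

Records are ordered canonically by id, split 8:2 with a seeded shuffle
(so the partition is invariant to presentation order), and the boosting
hyperparameters are tuned by IGWO over a box (integer knobs rounded on
decode) with mean k-fold validation RMSE as fitness (default 3 folds; the
fold partition and fit seeds derive from the run seed only, making the
objective deterministic and memoizable). The tuned model is refitted on
the full training split and scored on the held-out 20%.

Metrics: RMSE, MAE, MAPE, R² by their standard formulas; **accuracy is
defined as 100 − MAPE**, a choice that is natural here because the target
is itself a percentage — the paper-style "accuracy %" for a continuous
target is otherwise undefined. ROC-AUC is only computed when a wet/dry
binarization threshold is configured (default suggestion 30% MC, the
fiber-saturation convention) and both classes occur.

## Desk-scale problem sizes

The package's own evaluation runs at desk scale: records of 0.4 s at
2 kHz (800 samples, 3 modes, bursts every 0.15 s), collections of 100
records with MC uniform on [20, 160] % and noise at 5% of the
principal-mode amplitude, tuner budget 6 wolves × 8 iterations over
{trees 30–200, depth 3–6, ν 0.05–0.5, η 0–5, γ 0–2, subsample 0.6–1}
with 3-fold CV. Under these conditions the ACMD-feature arm attains
median held-out R² ≈ 0.998 and beats the hit-parameter baseline on RMSE
in 9 of 10 seeded collections; optimizer benchmarks use the full n = 30,
tmax = 500 setting.

## Known limitations

* The ACMD frequency-update rule (smoothed derivative of the residual
  phase) is the standard refinement but is one of several possibilities;
  very closely spaced modes (< the demodulation smoother's bandwidth
  apart) will merge.
* Mode counting is energy-threshold driven; heavy noise inflates the
  residual and can exhaust the mode budget before the threshold.
* The firefly perturbation moves wolves *away* from the alpha (the sign
  follows the update formula as printed in the literature this package
  follows); with greedy acceptance this acts as a safe outward probe, but
  it is not the attraction move of the original firefly algorithm.
* The regressor is piecewise constant: with ~80 training records its
  interpolation floor (≈1–2 %MC here) dominates the error long before
  feature information runs out.
* "Accuracy = 100 − MAPE" is a reporting convention, not a probability.
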