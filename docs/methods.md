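# Methods

This note records the model, the numerical choices, the synthetic-data
assumptions, and the open design decisions of `dcepnms`, in the spirit of a
statistical-software methods appendix.

## Kinetic models and units

Time is in minutes and rates in min⁻¹ throughout; AIF text files may
declare seconds (`time_unit: s`) and are converted on load. Concentration
is raw ΔR₁ in arbitrary relaxivity-proportional units: longitudinal
relaxivity is assumed constant across tissues, so v_p and K^trans are
scale-consistent once the AIF is normalized to a reference tissue.
No hematocrit correction is applied anywhere — plasma volume is estimated
directly against the plasma concentration trace.

The three nested models are linear in (v_p, K^trans) given k_ep. The
Patlak integral uses the cumulative trapezoid on the acquisition grid. The
model-3 convolution uses an exact-exponential recursion that integrates a
piecewise-linear interpolant of the AIF analytically over each frame: with
`E = exp(−k_ep Δt)` the update is `I_i = E·I_{i−1} + α c_{i−1} + β c_i`,
where α and β are the exact segment weights. This is unconditionally
stable for large `k_ep·Δt` and reduces to the trapezoid as `k_ep → 0`
(series-switch below `k_ep·Δt < 1e−8`). Against a 100×-finer-grid numerical
oracle the acquisition-grid curves agree to < 0.1% relative L2 over a
3×3×3 grid spanning the physiological parameter ranges (the acceptance
script recomputes this bound).

Estimates are never clamped to physical ranges during fitting — clamping
would distort the F-test null — but out-of-range values are flagged
(`PKParams.flags`) and thresholding is left to map export.

## Baseline handling and the AIF

The first 20 frames (~30 s) are excluded from all residuals to let the
spin system reach equilibrium; the forward-model integrals still run from
t = 0, and the bolus is injected at frame 15 (~23 s), i.e. during the
excluded window, matching the acquisition design the pipeline targets.
Degrees of freedom use the post-exclusion sample count (n − 2 for the
1-vs-2 test, n − 3 for 2-vs-3); whether baseline exclusion should also
shrink the df is not standardized, and the post-exclusion count is the
conventional nested-regression choice.

Measured AIFs are normalized to a non-leaky reference tissue
(conventionally caudate putamen) by `normalize_aif`: the AIF is scaled so
the model-1 fit of the reference returns v_p = 1% exactly.

For simulation the AIF is a gamma-variate first pass
(`(τ/t_p)^α e^{α(1−τ/t_p)}`, peak delay 0.25 min, shape 3) plus a
recirculation term `0.35·(1−e^{−8τ})e^{−0.12τ}`, zero before injection.
This is a smooth Parker-like stand-in chosen for qualitative realism
(sharp first pass, slow washout); it is simulation-only and makes no claim
to reproduce any measured radiological trace.

## Model-3 solver

Separable least squares: for each candidate k_ep the (v_p, K^trans) solve
is linear, so the outer problem is one-dimensional. The search uses

1. a coarse grid: k_ep = 0 (which makes SSR₃ ≤ SSR₂ structural) plus 64
   log-spaced points on [1e−3, 20] min⁻¹ — bounds that cover physiological
   back-flux with margin;
2. a 17-point zoom ladder spanning ± one coarse step around each best
   candidate (grouped across voxels sharing a candidate, so the design
   columns are built once per group);
3. a vectorized golden-section polish in log-k_ep (24 iterations within
   ± one ladder step), accepted per voxel only where it lowers the SSR.

On noiseless phantoms the selected-model parameters are recovered to
< 1e−4 relative; fits are unweighted (no noise model is assumed).

## Sequential F-tests and the perfect-fit guard

Selection is sequential (1→2, then 2→3 only if model 2 was accepted) with
ties resolved toward the simpler model. Two degenerate conventions:
`SSR_full = 0` with a strictly worse reduced model returns an infinite-F
sentinel (p = 0); and a *reduced* model whose SSR is at numerical roundoff
(≤ 1e−12 × signal energy over the fit window) never promotes — on exact
synthetic curves the F ratio of two roundoff-level SSRs is meaningless, and
without the guard noiseless labels would be arbitrary. Real noisy data
never reach the floor. Under model-1 truth with iid Gaussian noise the
empirical promotion rate at α = 0.05 is ~5% and the empirical F quantiles
match F(1, n−2); the residuals of real acquisitions are unlikely to be
exactly iid, so the nominal confidence level should be read as the
operational convention of the conventional pipeline, not a guaranteed
type-I rate.

## Kohonen map

8×8 hexagonal lattice (nearest-neighbor distance 1; odd rows offset by ½,
rows √3/2 apart), batch training for up to 250 epochs. The neighborhood
radius decays linearly from 3 to 1 over the first 100 epochs (ordering
phase) and stays at 1 thereafter (tuning phase) — a two-phase schedule in
the style of classical batch-SOM toolboxes; the kernel is a Gaussian in
lattice distance with σ = r/2, truncated at r. Prototypes initialize from
a seeded random sample of the training vectors and the input order is a
seeded permutation, so training is bitwise reproducible given
`random_state`. Training stops early once the maximum weight change falls
below `tol` (1e−9) after the ordering phase. The mean BMU distance is
recorded per epoch; with a smoothing neighborhood the batch update
minimizes the *smoothed* distortion, so the raw quantization error can
settle into a narrow bounded oscillation rather than decrease strictly —
the tests assert the no-net-increase form of the property.

Features are peak-normalized profiles: baseline mean subtracted, the
post-baseline segment divided by its own maximum absolute value (all-zero
profiles map to the zero vector), making the map scale-invariant and
shape-sensitive.

BMU ties break to the smallest row-major index; exact ties only arise for
bitwise-identical prototypes (e.g. training on exactly duplicated
vectors), in which case floating-point association is arbitrary among the
duplicates.

## Neuron probabilities and the constant prefactor

The canonical stored probability is the normalized ratio
`P_j = K_j / (K₁+K₂+K₃)`, which sums to 1 at every non-empty neuron. The
literal formulation carries an additional constant factor
`1/((Σ₁⁸n)(Σ₁⁸m)) = 1/1296` under which per-neuron values no longer sum
to 1; because the model-averaging equations renormalize by ΣP_j, any
common rescaling cancels exactly (verified to < 1e−12), so the constant is
representational only. `scaling="literal"` emits it for parity. Neurons
with zero training hits are filled from the nearest non-empty neuron on
the lattice (ties averaged; `empty_fill="uniform"` substitutes 1/3) and
flagged; voxels whose BMU was filled carry an `empty_bmu` quality flag in
all derived maps.

## Model averaging and map conventions

Averaged v_p uses all three per-voxel fits, averaged K^trans the two leaky
fits, and v_e divides the averaged K^trans by the model-3 k_ep. Edge
conventions: P₂+P₃ = 0 yields K^trans = 0 with a `nonleaky` flag;
k_ep ≤ 0 leaves v_e undefined (flagged). The v_e equation applies even
where model 2 dominates; such voxels are flagged (`low_p3_ve`) since the
conventional pipeline defines v_e only on model-3 regions — comparisons
between the two techniques restrict v_e to those regions. With one-hot
probabilities every averaged map reduces exactly to its conventional
counterpart (tested to max |Δ| = 0 on v_p/K^trans everywhere and v_e on
model-3 voxels).

Deterministic regions threshold the probability maps at 50%; following the
conventional protocol, the model-1 region is removed from the brain before
the model-2/3 masks are formed and compared (Dice) against the NMS labels.
The fused RGB map codes (R, G, B) = (P₃, P₂, P₁).

## Synthetic phantom and cohort

The phantom is a brain ellipse (model 1) containing an off-center tumor
with a leaky rim (model 2) around a core with back-flux (model 3);
background voxels are zero and excluded by the mask. Acquisition defaults:
400 frames at 1.533 s (≈10.2 min), injection at frame 15, 20 baseline
frames. Per-voxel parameters are drawn uniformly from physiological
ranges — v_p ∈ [0.005, 0.04], K^trans ∈ [0.01, 0.3] min⁻¹,
k_ep ∈ [0.1, 3] min⁻¹ — and noise is additive iid Gaussian with σ given as
a fraction of the AIF peak (an optional AR(1) knob exists for robustness
experiments, off by default). Flat profile collections default to a
65/26/9% class imbalance, mirroring the composition of a realistic labeled
brain corpus dominated by normal tissue. The cohort generator gives each
subject a lognormal random effect (SD 0.15) on its v_p/K^trans range
centers.

What the phantom does *not* emulate: measured-AIF shape and dispersion,
temporally correlated or signal-dependent noise, partial-volume mixtures
within a voxel, water-exchange effects, and continuous (rather than
block-uniform) spatial parameter variation. Passing tests therefore
establish the correctness and calibration of the algorithms under the
stated assumptions, not performance on real acquisitions.

## Validation design

Nested cross-validation splits at the subject level: subjects are randomly
permuted (seeded) into k = 10 disjoint test folds, so every subject is
tested exactly once; the probability model for each fold is trained only
on a random 66% subset of the remaining subjects. (A literal 0.66/0.34
train/test split at every iteration cannot coexist with 10 disjoint test
folds; this design honors both the leakage guarantee and the training
fraction.) Per fold the pipeline reports Dice for models 2 and 3 and the
parameter means of both techniques over the NMS-region fusions (v_p over
regions 1+2+3, K^trans over 2+3, v_e over 3 — the same regions for both
techniques so the estimates are directly comparable). Across folds it
reports means, percentile-bootstrap CIs (2000 resamples), and mean percent
differences computed both as the mean of per-fold MPDs and as the MPD of
fold-averaged parameters (the two differ when folds are heterogeneous,
and the literature is not explicit about which is meant).

Two empirical observations on the default synthetic cohort are worth
recording. First, the fold-to-fold CI widths of the two techniques are
nearly equal (differences of a few percent): fold spread is dominated by
genuine inter-subject parameter variation, which affects both estimators
identically, so the "probabilistic estimates vary less across folds"
effect is reproduced only weakly and can flip for individual parameters at
individual seeds. Second, the mean percent differences between PNMS and
NMS are near zero with indeterminate sign: at the default 2% noise the
classes are well separated, the SOM neurons are nearly pure, and one-hot
probabilities make averaging a near-identity. Strong directional shifts
require substantial class overlap (probability mass spread across models
within voxels), which is a property of real heterogeneous tissue that the
block-design phantom does not produce.

## Known limitations

* The noisy-recovery floor of v_p is high: at σ = 2% of the AIF peak the
  median relative error of model-3 v_p (~29%) and K^trans (~15%) sits at
  the Cramér–Rao bound of the unweighted least-squares problem for this
  AIF and parameter range (numerically verified); v_e, which depends on
  the well-determined curve shape, recovers to ~6%. Plasma volume is
  simply weakly identified for small v_p when the bolus is blunt relative
  to the noise — a property of the experiment, not the solver.
* The F-test's iid-Gaussian residual assumption is an idealization of real
  DCE noise.
* SOM variants (growing grids, neural gas, hierarchical maps) and
  information-criterion model averaging (AIC/BIC) are out of scope.
* Estimation of ΔR₁ from raw echo signals, T₁ mapping, AIF measurement,
  and dispersion/delay correction are upstream of this package: it
  consumes ΔR₁ volumes and an AIF directly.
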