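# Methods

## Model and optimization

One data round delivers a feature chunk X ∈ ℝ^{d×n_t} with per-sample
individual labels. The loss minimized at round *t* over W, G, R, V is

    α(‖Ṽ − X̃ᵀW‖² + ‖V − XᵀW‖²) + β(‖X̃ − GṼᵀ‖² + ‖X − GVᵀ‖²)
    + γ‖A − HRᵀ‖² + θ‖R − V‖² + η‖S − V_m Vᵀ‖² + δ(‖W‖² + ‖G‖²)

where tilde matrices are all past rounds' data and latents. The four
closed-form updates per iteration are

    W = (C1 + (δ/α) I)⁻¹ C2                       C1 = C1_prev + XXᵀ
    G = C2 (C3 + (δ/β) I)⁻¹                       C2 = C2_prev + XV
    R = (θV + γAᵀH)(θI + γHᵀH)⁻¹                  C3 = C3_prev + VᵀV
    V = (αXᵀW + βXᵀG + θR + ηSᵀV_m)
        ((α+θ) I + βGᵀG + η V_mᵀV_m)⁻¹

Notes on the algebra, as implemented:

* **Ridge bracket.** The regularized normal equations give δ/α and δ/β inside
  the W/G brackets. At the default α = β = 1 this coincides with the δα/δβ
  variant; we implement the derivation-consistent form.
* **V bracket.** The exact minimizer of the V sub-problem has (α+θ)I plus
  ηV_mᵀV_m; an alternative published form adds a further ηI to the diagonal.
  The default is the exact minimizer — it is what makes the monotone-descent
  guarantee a testable property — and `Hyperparams(published_v_update=True)`
  switches to the (α+θ+η)I variant for comparison. With an empty memory the η
  term is skipped entirely and the two modes coincide.
* **Past data through statistics only.** X̃ and Ṽ are never stored. Their
  α/β residuals are exactly reconstructible from the frozen statistics:
  ‖Ṽ − X̃ᵀW‖² = tr(C3) − 2tr(WᵀC2) + tr(WᵀC1W) and
  ‖X̃ − GṼᵀ‖² = tr(C1) − 2tr(GᵀC2) + tr(GᵀG C3), so
  `objective(..., include_past=True)` evaluates the full streaming loss at any
  iterate. Storage is O(d² + dr + r²) for any stream length.
* **Within-round statistics.** The current chunk's contribution to C2/C3 is
  refreshed from the latest V at every update, while C1's chunk part is fixed;
  prior rounds' parts are immutable. This keeps each update the exact
  minimizer of its sub-problem, which in turn makes the loss non-increasing
  after every one of the 4T steps (relative tolerance 1e-8 in the tests).
* **Final refresh.** After the T iterations the statistics are frozen with the
  converged V and W/G are recomputed from them once. The returned projection
  is therefore exactly the cumulative ridge solution on all frozen data — an
  invariant the tests check per round — and the refresh is itself a descent
  step, so monotonicity is unaffected.
* **Initialization.** V and R start from seeded Normal(0, 0.01-variance)
  noise; the round index is folded into the seed. W and G are initialized the
  same way for completeness but are overwritten by their first update before
  being read.
* **Linear solves.** All brackets are solved by Cholesky factorization (never
  explicit inversion) with a 1e-10·I jitter fallback; the prototype bracket at
  θ = 0 deliberately skips the jitter so a rank-deficient HᵀH surfaces as an
  error rather than an arbitrary solution.
* **Module toggles (ablations).** `bidirectional_regressions=False` sets
  α = β = 0: W/G drop out of the objective and V is driven by prototypes and
  memory alone. Matching still needs a projection, so after each round W is
  fit post hoc as the cumulative ridge map from features to the frozen
  representations (W = (C1 + δI)⁻¹C2), used only at matching time.
  `prototype_learning=False` removes the R/H/A terms;
  `memory_enhancement=False` removes the memory store and the η term.

## Hadamard codes and memory

Individuals are assigned rows of a Sylvester Hadamard matrix (2⁷×2⁷ by
default, r = 128 tied to the order) in first-appearance order, which makes
assignment deterministic without randomness and replayable from the stream.
Row 0 (all ones) is used like any other row. If r is set below the Hadamard
order, codes are truncated to the leading r columns (documented, off by
default). Capacity overflow raises an error telling the user to raise k.

The memory bank stores one count-weighted running mean per individual — the
unique update rule for which each stored row equals the arithmetic mean of
every representation that individual has ever produced (tested against a
brute-force recomputation at 1e-10). Representations from different rounds
are produced under different W's; the means average across them regardless,
and stored means are not re-encoded under newer projections. Memory is
updated once per round, after the chunk converges, consistent with treating
V_m as a constant within the round.

## Matching and metrics

Queries and registered samples are projected as XᵀW. **Identification**
assigns each query the label of the nearest registered row (Euclidean; ties
broken toward the lowest gallery index and counted). The default gallery is
per-sample, with a per-individual class-mean mode available.
**Verification** scores each query against per-individual enrolled templates
(the mean registered representation per individual), the standard biometric
verification protocol; pairwise per-sample scoring is available through the
same API and is what `verification_scores` produces for any gallery. On the
default synthetic conditions, template verification yields EER ≈ 0.5–2%,
while per-sample pairwise scoring yields ≈ 4–6% — per-sample genuine
distances inherit the full within-class feature noise, so a single global
threshold separates less cleanly.

EER is computed by sweeping the pooled sorted distances as thresholds with
FAR(t) = fraction of impostor distances below t and FRR(t) = fraction of
genuine distances above t, locating the crossing of the two step functions,
and interpolating both linearly between the bracketing thresholds (genuine
{1,3} vs impostor {2,4} → 25% at threshold 2.5; perfectly separated scores →
exactly 0). Stepwise alternatives differ by O(1/n) near ties, which the tests
cross-check against an independent ROC construction.

## Synthetic data

`simulate_feature_stream` emulates pre-extracted heartbeat feature streams:
Gaussian class clusters whose means are random directions rescaled so the
minimum pairwise distance equals class_separation × within_sd, delivered on a
configurable chunk schedule (defaults 70/70/70/70/49; a 108×5+27 schedule
constant is provided), with five held-out test samples per individual and an
optional class-incremental protocol (a fraction of individuals withheld until
`introduce_round`, all debuting there).

Default calibration, chosen to emulate the statistics of normalized
local-binary-pattern histogram features on which this family of methods
operates: `within_sd = 0.1` so feature columns have roughly unit norm —
normalized histograms are O(1) objects, and the all-ones trade-off weights
balance the regression terms against the {0,1}-valued prototype/memory terms
only at that scale — and `class_separation = 8`, at which a raw-feature
nearest-neighbor baseline sits at ≈ 99–100% accuracy, the separability regime
real heartbeat features exhibit on standard on-the-person recordings. At
these defaults the full pipeline reaches ≈ 100% identification accuracy and
≈ 0.5% template EER, the magnitudes reported for such methods on real data.

What the generator does *not* emulate: histogram non-negativity and bounded
support, heavy-tailed or structured within-class variation (electrode drift,
heart-rate dependence), session effects, and class-dependent covariance.
Passing tests therefore demonstrate correctness of the optimization,
streaming and memory machinery and qualitative behavior (separation
monotonicity, per-round improvement, ablation direction) — not performance on
real recordings.

`simulate_ecg_record` builds pseudo-ECG beats from three Gaussian bumps (P,
QRS, T; defaults 0.15/1.0/0.3 in amplitude, widths 25/12/50 ms, P at −160 ms
and T at +300 ms relative to R) with jittered RR intervals (0.8 ± 0.04 s),
grid-aligned R peaks, optional per-individual morphology jitter, and additive
Gaussian noise settable directly or via a target SNR. It exercises R-peak
detection and segmentation; it is not a physiological simulator.

## Preprocessing and features

R peaks: Pan–Tompkins stages — 5–15 Hz band-pass (2nd-order Butterworth,
zero-phase forward–backward so no group-delay correction is needed),
five-point derivative, squaring, 150 ms moving-window integration, adaptive
dual thresholds with an eight-beat RR history, search-back at 1.66× the mean
RR, and a 200 ms refractory period; detections are refined to the strongest
band-passed deflection nearby. All constants are keyword-overridable.
Records shorter than the 2 s threshold-learning phase raise a "too short"
error; an all-flat record returns no peaks.

Segmentation cuts [peak − ⌊offset_fraction·L⌋, +L) windows (offset_fraction
0.5 by default — the window split around the R peak is a convention, and the
learner is agnostic to it); boundary-crossing beats are dropped and counted
rather than padded, keeping every column homogeneous.

Features: at each radius (defaults {1, 2, 4}), every interior sample is
compared with neighbors_per_side = 2 neighbors per side at multiples of the
radius; neighbor ≥ center contributes a 1 bit (ties are 1), bits are packed
left-to-right (most significant first). Code series are histogrammed over
64-sample windows at stride 32 (window clipped to the series length), one
2^(2·neighbors_per_side)-bin normalized histogram per window, all
concatenated per beat. The defaults keep d in the low hundreds, comparable to
r = 128. The extractor is a convention choice documented here — bit order,
tie handling, truncated boundaries — and any FeatureChunk-shaped matrix can
be fed to the learner instead.

## Known limitations

* The six-iteration default (T = 6) leaves a slowly-decaying mode in the
  objective on cold-start rounds: G can grow while V shrinks leaving GVᵀ
  unchanged, a near-gauge direction curbed only by δ = 0.01 and θ. Accuracy
  plateaus by roughly iteration 3 regardless; the objective's tail drift is
  ~1e-2 relative per iteration in round 1 and fades as statistics accumulate.
* Memory means mix representations produced under different rounds' W.
* Verification assumes a single global distance threshold; no score
  normalization is applied.
* The matching gallery stores raw registered features for projection at
  evaluation time; the online contract (never re-reading past chunks) applies
  to training.
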