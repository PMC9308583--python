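# Methods

This note documents the models the package implements, the synthetic study
conditions it is validated under, and the numerical and design choices that
were genuinely open.

## Kinetic models

Tracer exchange between arterial plasma and tissue is described by linear
compartment models.  With plasma input C_p(t) and whole-blood activity
C_wb(t) (both kBq/mL, decay-corrected to injection), the tissue response is

* **1T2k** (reversible one-tissue): C_t = K₁ e^{−k₂t} ⊗ C_p
* **2T4k** (reversible two-tissue):
  C_t = K₁/(θ₁−θ₂) · [(θ₁−k₃−k₄) e^{−θ₁t} + (k₃+k₄−θ₂) e^{−θ₂t}] ⊗ C_p,
  with θ₁,₂ the roots of s² − (k₂+k₃+k₄)s + k₂k₄
* **2T3k** (irreversible, k₄=0): the slow root collapses to zero and the
  second exponential becomes the running plasma integral, giving
  C_t = [K₁k₃/(k₂+k₃)]∫C_p + [K₁k₂/(k₂+k₃)] e^{−(k₂+k₃)t} ⊗ C_p.

The measured region signal includes a fractional blood volume,
C_pet = (1−V_B)·C_t + V_B·C_wb.  Macroparameters are the net influx rate
K_i = K₁k₃/(k₂+k₃) (the myelin-density index), the volume of distribution
V_T = K₁/k₂ (1T2k) or (K₁/k₂)(1+k₃/k₄) (2T4k), and BP_ND = k₃/k₄.

Rate constants are in min⁻¹ (K₁ in mL·cm⁻³·min⁻¹); all times are minutes
internally, converted from the seconds carried in frame-schedule files.

### Exact frame-averaged evaluation

The input curves are piecewise linear on their sample grid.  On the union of
that grid and the frame boundaries, each convolution E_θ(t) = e^{−θt} ⊗ C_p
is propagated exactly per segment, and frame integrals follow from the ODE
identity ∫E_θ = (∫C_p − ΔE_θ)/θ (for θ→0, an exact cumulative double
integral of the piecewise-linear input).  Predicted frame values are
therefore exact time averages of C_pet over each frame, not midpoint
samples — with 5–10 s frames around the blood peak, midpoint sampling is
materially biased.  Against an independent stiff-ODE oracle the forward
model agrees to ~2×10⁻⁹ relative (the acceptance script recomputes this).

Repeated eigenvalues (θ₁=θ₂, a measure-zero configuration such as k₃=0 with
k₂=k₄) are handled by a symmetric split θ±δ with δ = 10⁻⁶·θ.  The split is a
central approximation of the confluent t·e^{−θt} limit; the formula error is
O(δ²) and the cancellation error ~10⁻¹¹ relative, far below the forward
model's stated 10⁻⁶ tolerance.

### Weighted fitting

Fits are bounded trust-region least squares (rates in [10⁻⁶, 2] min⁻¹,
V_B in [0, 0.2]; defaults K₁=0.1, k₂=0.1, k₃=0.05, k₄=0.01, V_B=0.05), with
multi-start over log-normally jittered initials (deterministic jitter seed;
5 starts by default, fewer where callers know the data are clean).  Frame
weights are w_i ∝ Δt_i·e^{−λt_i} (λ = ln2/20.34 min, carbon-11), normalized
to mean one — the standard count-statistics weighting for decay-corrected
frames; uniform weighting is available.  All models compared by AIC for one
TAC use identical weights by construction.

Standard errors come from the scaled inverse Gauss–Newton Hessian,
cov = (JᵀWJ)⁻¹·WRSS/(n−m), with macroparameter SEs by the first-order delta
method (numerical gradients, clipped at the bounds).  A singular information
matrix yields infinite %SE rather than an error.  R² is reported on
unweighted residuals.  AIC is the classical n·ln(WRSS/n) + 2m without the
small-sample correction; which variant commercial packages use is not
verifiable, so model-preference results are validated as directional
properties rather than exact counts.

The "K₁/k₂ fixed" mode reparameterizes with K₁ free and k₂ = K₁/ratio, the
ratio coming from a first-pass unconstrained fit of the whole-brain white
matter TAC; it is the workflow's default for lesion quantification.

## Input function

The continuous detector curve is cross-calibrated against the manual
arterial samples by a single multiplicative factor (closed-form least
squares); detector cross-calibration is multiplicative, so no offset is
fitted.  The parent fraction is the three-parameter Hill-type sigmoid
PF(t) = 1 − a·tᵇ/(tᵇ+c) with the structural anchor PF(0)=1 — `a` is the
asymptotic metabolized fraction (plateau 1−a), `c^{1/b}` the half-conversion
time.  The plasma-to-whole-blood ratio is interpolated linearly through the
five manual samples with constant extrapolation, since five points support
no parametric model.  The metabolite-corrected input is
C_p = C_wb·R(t)·PF(t) on the detector grid; interpolation is piecewise
linear, zero before the first sample and constant after the last.  No
delay or dispersion correction is applied.

## Simplified estimators

Patlak (slope = K_i over frames with midpoint ≥ t*) and Logan (slope = V_T)
use t* = 20 min by default; a sweep utility quantifies the t*-sensitivity.
The MLAIR operational equations are derived by integrating the irreversible
two-tissue ODEs twice and substituting C_t = (C_pet − V_B·C_wb)/(1−V_B):

    MLAIR1: C_pet(T) = P₁C_wb + P₂∫C_wb + P₃∫C_p + P₄∬C_p + P₅∫C_pet
    MLAIR2: ∫C_pet  = b₁C_wb + b₂∫C_wb + b₃∫C_p + b₄∬C_p + b₅C_pet(T)

with P₁ = V_B, P₅ = −(k₂+k₃), P₄ = (1−V_B)K_i(k₂+k₃), so K_i = −P₄/P₅, and
b₄ = (1−V_B)K_i read directly.  The reported K_i is the apparent coefficient
(it absorbs 1−V_B, matching common practice); an option divides by a known
V_B.  A four-term variant omitting ∫C_wb is available as a config switch.

Regression points are frame midpoints.  Input-side integrals come from the
input's own fine grid; tissue-side cumulative integrals use a frame-aware
rule — the integral to the end of frame i is exactly Σ avg_j·Δt_j because
TAC values are frame averages, plus avg_i·Δt_i/2 for the half frame to the
midpoint.  The generic midpoint trapezoid (kept as `cumulative_integral`
for arbitrary grids) leaves ~2% error on Logan through the early 5-s
frames; the frame-aware rule reduces it to ~0.03%.

SUV over a window is the duration-weighted mean concentration divided by
net injected dose per body weight (g/cm³); partially covered frames
contribute their overlap, with a warning.  Parametric maps apply MLAIR2 or
SUV voxelwise, propagating NaN for masked or degenerate voxels; maps are
unsmoothed (any presentation smoothing is out of analysis scope).

### Noise behaviour of the linearizations (known limitation)

Under the frame-noise model below, the short peak frames carry roughly 3×
the relative noise of the late 600-s frames.  Because C_pet appears as a
*regressor* in MLAIR2 (and its integral in MLAIR1), errors-in-variables
attenuation biases the MLAIR2 K_i low — about −9% when late-frame noise is
5%, and −16% or more at voxel-level noise — whereas Patlak, confined to the
quiet late frames, keeps a small negative equilibration bias (−1…−7%).
MLAIR2's *variance* is nonetheless orders of magnitude below MLAIR1's, and
its correlation with the compartmental K_i degrades more slowly than
Patlak's as noise grows; both properties are asserted in the tests.  Users
comparing absolute MLAIR2 values across noise regimes should expect the
attenuation; at matched noise it cancels in group contrasts.

## Synthetic study conditions

The generator emulates a 26-frame, 60-min acquisition
(1×10, 10×5, 1×10, 2×30, 3×60, 2×150, 4×300, 3×600 s — kept verbatim even
though the durations sum to 3610 s; which frame absorbs the discrepancy is
unknowable, so nothing is truncated) of a fast-metabolizing C-11 tracer:

* **Arterial model**: tri-exponential whole-blood curve
  C(t) = (A₁(t−τ) − A₂ − A₃)e^{−λ₁(t−τ)} + A₂e^{−λ₂(t−τ)} + A₃e^{−λ₃(t−τ)},
  defaults A = (600, 12, 16) kBq/mL(/min), λ = (4, 0.25, 0.012) min⁻¹,
  τ ∈ [0.3, 0.7] min, peaking inside the first minute.  Amplitudes scale
  with injected dose per body size and carry 15% subject jitter; washout
  rates λ₂, λ₃ carry 15% jitter.  The exact amplitude constants are fixture
  choices (no tabulated curves exist to match); only the scalar anchors
  below are calibrated.
* **Sampling**: 1-s grid over 0–5 min, 5-s grid thereafter (the two
  withdrawal speeds of an online detector); manual samples at
  10/20/30/45/60 min; a detector miscalibration factor in [0.8, 1.2] that
  the calibration step must recover.
* **Metabolism**: Hill defaults (a, b, c) = (0.95, 2, 17.86), i.e. parent
  fraction 0.194 at 10 min and 0.055 at 60 min; the half-conversion scale c
  varies log-normally (50%) across subjects so the 10-min parent fraction
  spreads ≈ 0.19 ± 0.07.  Plasma-to-whole-blood ratio defaults to a
  constant 1.1 (no reported value).
* **Kinetic truths**: per-class log-normal distributions.  Grey matter:
  K_i 0.064 ± 0.018 with high influx and fast washout (K₁ ≈ 0.40,
  k₂ ≈ 0.50); white matter: K_i 0.113 ± 0.031 with lower influx and slow
  washout (K₁ ≈ 0.25, k₂ ≈ 0.18); V_B 0.05 (GM) / 0.02 (WM).  Lesion
  classes use WM-like exchange with K_i anchors 0.072 (black holes),
  0.079 (demyelinated), 0.085 (partially myelinated), 0.102 (remyelinated),
  NAWM 0.105 ± 0.045; default class sizes 105/111/69/7.  k₃ is derived from
  the drawn K_i via k₃ = K_i·k₂/(K₁−K_i), with K_i clipped at 0.7·K₁ (a
  <2σ tail) to keep k₃ finite.  The truth model defaults to the
  irreversible 2T3k; 1T2k/2T4k generation is selectable for
  model-selection experiments.
* **Frame noise**: independent Gaussian with
  sd_i = α·√(max(C_i,0)·e^{λt_i}/Δt_i) — variance grows for short frames
  and late (decay-weighted) times.  Noise levels are specified as the
  duration-weighted mean relative sd over post-1-min frames
  (`alpha_for_cv`): ~2% for litre-scale whole-brain masks, ~5% for ordinary
  VOIs, ~35% for small (0.1–0.3 mL) lesions.

What the generator does **not** emulate: spatial structure and partial
volume effects, motion, scatter/randoms residuals, input-function
measurement error in the manual samples, and between-scanner calibration.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the estimators under the assumed noise model, not robustness
to those real-data effects.

## Study-level procedures

Estimates with %SE > 25 are flagged unreliable and removed before
comparisons (the threshold is configurable).  AIC preference tallies one
vote per region for the lowest-AIC model, splitting ties equally so the
table always sums to the number of scored regions.  Method comparison is
Pearson r plus OLS of the candidate on the compartmental K_i, stratified by
cohort.  GM-vs-WM uses a two-sample t-test gated by Kolmogorov–Smirnov
normality (against a normal with the sample moments) and Levene's variance
test (Welch correction when unequal); lesion-vs-NAWM uses the two-sided
Mann–Whitney U, exact for min(n₁,n₂) ≤ 8 without ties.

Lesion classification priority: diameter ≤ 3 mm → excluded;
gadolinium-enhancing → active; T1 iso-intense to CSF → black hole; T1
hypointense with T1 volume < (1−0.2)·FLAIR volume → partially myelinated,
otherwise demyelinated; T1 iso-intense to NAWM in a FLAIR-hyperintense
lesion → remyelinated.  The 20% volume-equality tolerance is a package
choice (none is reported); it is configurable.  Contralateral NAWM partners
are data-provided labels; peri-lesion regions exist only as a tissue-class
label, their image-space construction being out of scope.

## Observed behaviour of AIC model selection

With the amplitude-dependent noise model and amplitude-blind decay-duration
weights, the weighted per-frame residual variances vary ~20× across frames.
The effective degrees of freedom of the weighted residual sum are then much
smaller than the frame count, and the likelihood-ratio improvements
available to an over-parameterized model are ~2–3× larger than nominal
chi-square.  Consequently AIC picks the generating model in only ~73–85% of
regions rather than >90%, independent of the noise scale.  This mirrors the
empirical observation that AIC tends to prefer the reversible two-tissue
model on real cortical data even when the irreversible model is adopted for
its far better parameter identifiability (the 2T4k V_T/BP_ND %SE run
several orders of magnitude above the 2T3k K_i %SE in the same fits).

## Problem sizes

The test suite and the acceptance script size their simulations for a
single CPU: 50 parameter sets per topology for the ODE cross-check, 150–200
TACs for recovery and reliability experiments, 60–100 regions per truth
model for AIC preference, ~90-region mixed cohorts for method comparison,
40–60 seeds for the power experiments, and single full-size lesion cohorts
(292 lesions) for the Mann–Whitney pattern.
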