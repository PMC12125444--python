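# Methods

## Model

The package quantifies reversible tracer kinetics with a two-tissue
compartment model. Parent tracer in plasma, C_p(t), exchanges with a
free/nonspecific tissue compartment C1 and a bound compartment C2:

    dC1/dt = K1 C_p(t-δ) − (k2+k3) C1 + k4 C2
    dC2/dt = k3 C1 − k4 C2

The PET measurement mixes tissue and blood signal,

    C_T(t) = (1 − v_b)(C1+C2)(t) + v_b C_wb(t−δ),

with v_b the fractional blood volume and C_wb the whole-blood activity. The
`(1 − v_b)` mixing convention is the default; the additive variant
`C_T = (C1+C2) + v_b C_wb` is available through
`FitOptions(vb_convention="additive")` since both conventions are in active
use and differ only at the percent level for cortical v_b ≈ 0.03–0.04.

Assumptions: decay-corrected data (no decay term), a well-mixed blood pool
common to all regions, passive first-order exchange, and a single arrival
delay δ per region applied to both C_p and C_wb (what is delayed is the
arrival of blood, so both curves shift together).

Macro-parameters: total distribution volume V_T = (K1/k2)(1 + k3/k4)
(undefined and flagged when k2 or k4 is 0), DVR = V_T/V_T(reference), and
duration-weighted SUVR over late windows (60–90 min default, 45–75 min
exploratory) using the inferior cerebellum as reference.

## Numerical solution

The tissue response is the analytic bi-exponential impulse response

    h(t) = φ1 e^{−θ1 t} + φ2 e^{−θ2 t},
    θ1,2 = ½[(k2+k3+k4) ± sqrt((k2+k3+k4)² − 4 k2 k4)],
    φ1 = K1(θ1−k3−k4)/(θ1−θ2),  φ2 = K1(k3+k4−θ2)/(θ1−θ2),

convolved with the delayed C_p by trapezoidal quadrature on a uniform 1-s
grid (configurable; the repeated-root limit
h = K1(1+(k3+k4−θ)t)e^{−θt} is used when θ1 ≈ θ2, and the discriminant is
non-negative for non-negative rates). The fine-grid model is then averaged
over each frame, matching how PET frames integrate the signal; with 2-s
early frames this sub-frame resolution is what makes the bolus phase
fittable. Against an independent 0.1-s-step ODE integration the forward
curve agrees to ≈0.15% of the curve maximum; halving the grid step moves
frame values by <0.3% (both are regression-tested).

Curves are represented by their frame mid-point samples, interpolated
piecewise-linearly with a virtual anchor at (t=0, 0) — activity is zero at
injection — and held constant beyond the last mid-point. Integrals
(`integrate_curve`, the Logan transforms) are exact integrals of that
interpolant. Scan truncation keeps whole frames only (`end ≤ T`); the
protocol's frame boundaries align with every 10-min cut point, so no frame
is ever split.

## Fitting

Bounded weighted least squares (`scipy.optimize.least_squares`, trust-region
reflective) over (v_b, K1, k2, k3, k4, δ) with box bounds 0–1 on the five
kinetic parameters, 0–20 s on δ, and initial value 0.01 for all kinetic
parameters. δ is continuous and optimized jointly, not grid-searched; its
initial value is 5 s (mid-range; the fit is insensitive to this choice on
clean data). Default weights are proportional to frame duration
(w_i ∝ Δt_i, normalized), which down-weights the noisy 2-s frames in
proportion to their acquired counts; uniform weighting is a switch, and the
recovery tests pass under both. On optimizer non-convergence up to 5
restarts from jittered initials are drawn from a fixed seed, so identical
inputs always produce identical results. Noiseless generate-and-fit
recovery is exact to well below 0.1% for all parameters.

Logan analysis regresses y = ∫₀ᵗC_T/C_T(t) on x = ∫₀ᵗC_p/C_T(t) by
unweighted OLS over frames whose **mid-time** is ≥ t*
(default 20 min; ≥3 usable points required, non-positive C_T frames are
excluded with a warning). The input is the fully corrected parent plasma
curve without delay shift — the few-second arrival delay is irrelevant to
integrals evaluated tens of minutes post-injection — though a fitted delay
can be supplied. On noiseless cohort-mean subjects the slope lands within
1–2% of the compartmental V_T; subjects near the slow-equilibration edge of
the cohort's V_T band show the expected pre-equilibrium underestimation of
up to ~6–10% at t* = 20 min. The slope converges monotonically toward the
late-time asymptote of the composite signal, which sits slightly above the
tissue V_T because C_T includes the v_b C_wb term.

## Synthetic study conditions

The generator emulates the study's acquisition: the 90-min framing protocol
30×2 s, 12×10 s, 7×60 s, 16×300 s (65 frames), a descending-aorta-like
input, and cortical grey-matter kinetics.

**Input function.** Parent plasma follows a linear-rise × tri-exponential
bolus family, C(u) = (A1·u − A2 − A3)e^{−λ1 u} + A2 e^{−λ2 u} + A3 e^{−λ3 u}
for u = t − onset, with defaults A1 = 500 kBq/mL/min, λ1 = 6 min⁻¹,
A2 = 2.0 kBq/mL, λ2 = 0.5 min⁻¹, A3 = 1.2 kBq/mL, λ3 = 0.010 min⁻¹,
onset = 20 s: a ≈33 kBq/mL peak ~10 s after onset, resolved by the 2-s
frames and ~30–40× the late tail, qualitatively matching published aorta
IDIFs for this tracer class. Total plasma is parent/(p/100) and whole blood
is plasma/ratio, i.e. the correction layers are built **inversely**, so
applying the package's plasma and metabolite corrections to the generated
whole-blood curve recovers the parent curve to machine precision — a
round-trip that is regression-tested.

**Correction defaults.** The parent-fraction parameters (α = 55%, τ1 = 6
min, τ2 = 120 min, t0 = 1 min; ≈36% parent at 30 min, ≈21% at 90 min) and
the plasma/whole-blood ratio (1.0 constant; a time-varying fixture is also
shipped) are documented synthetic-test defaults, not population science:
for real data both models are required configuration inputs, because the
published population values live outside the main text of any single study.

**Ground truth.** Per-ROI truths are drawn from truncated normal marginals
whose means/SDs default to the study cohort's printed per-ROI values for
the lateral parietal, medial temporal and posterior cingulate ROIs; the
reference region's means are chosen so its V_T is 2.04 mL/cm³, the level
implied by the cohort's V_T/DVR ratios. Because independent marginal draws
can combine into near-irreversible subjects (k4 → 0, V_T in the hundreds)
that the cohort's printed V_T spread rules out, a draw is accepted only if
its implied V_T lies within mean ± 3 SD of the ROI's V_T; this keeps the
cohort jointly consistent with the reported distribution while preserving
the marginals to within sampling error (rejection nudges the k4 mean up
slightly; the sample-mean test uses a 3-SE band across its 24 comparisons).

**Noise.** Per-frame independent Gaussian noise with
SD = scale·sqrt(max(v, ε)/Δt_min), the simplest frame-statistics model for
decay-corrected OSEM data (variance ∝ value, ∝ 1/duration). The default
scale 0.05 gives ≈1–2% noise on late 300-s frames and ≈20–30% on the 2-s
bolus frames of a cortical ROI. All randomness flows from one seed through
split substreams per subject and ROI; regeneration is bit-identical.

**What the generator does not emulate:** voxel-level (image-domain) noise
and its spatial correlation, partial-volume effects and scanner PSF, motion,
real metabolite-measurement error, tau-positive binding patterns, or
between-subject variation in the input-function shape (all subjects share
one parametric input). Passing tests therefore demonstrate correctness of
the estimation machinery under a faithful but idealized forward model, not
performance on real images.

## Stability and sensitivity experiments

The scan-duration analysis refits every subject and region on truncated
data (10–90 min, 10-min steps; inputs truncated identically), then
correlates each parameter at each duration with its full-scan estimate
across subjects (Pearson, two-sided t test), with Benjamini–Hochberg
correction over the whole parameter × duration × ROI family of one run.
Failed fits are recorded as missing and excluded pairwise with explicit
counts. At the default conditions (15 subjects, noise 0.05) K1 correlates
at ≥0.99 from 30 min onward; the slow parameters reach high stability
around 60 min. The tracer-arrival delay is the marginal case: its
between-subject spread (≈0.5 s SD in the parietal ROI) is comparable to its
estimation noise, so its 60–80-min correlations fluctuate around 0.8–0.99
across seeds. Per-duration summary curves report mean ± SD (labelled as SD).

The IDIF sensitivity analysis perturbs the whole-blood peak, re-derives the
corrected input, refits, and reports percent changes (delay as absolute
seconds). Two peak conventions are implemented, and the choice dominates
the outcome:

* `window="fwhm"` (default): every sample in the contiguous ≥50%-of-max run
  is scaled. On the default input this window spans 22–48 s and carries
  ≈13% of the input area, so a ±10% scaling is a ±1.3% change of total
  input exposure concentrated in the bolus phase; the refit re-allocates
  the early-time parameters at the several-percent level (K1 ≈ 7–8%, v_b up
  to ≈20%) while V_T stays within ≈0.5%.
* `window="max-frame"`: only the single maximum sample (≈1% of the input
  area) is scaled. All parameters then move well under 1% for K1 and V_T
  (≤2.5–3% for v_b) at ±10%.

The contrast is structural: K1 and v_b are identified by the bolus-phase
data, so any perturbation that moves a nontrivial share of the bolus area
must move them proportionally, whereas V_T responds only to the total-area
change. Reported robustness of K1 at the sub-percent level under "peak"
manipulation is therefore only achievable when the manipulation touches a
~1%-area slice of the curve, as in the max-frame convention.

## Problem sizes and determinism

The shipped tests run cohorts of 15 subjects × 4 regions on the full 65-frame
protocol (≈800 bounded fits overall, including the 9-duration stability
scan); all seeds are fixed in the test code, hypothesis runs derandomized,
and every file output uses sorted keys and fixed float formatting so reruns
are byte-identical.

## Known limitations

* No irreversible (k4 = 0) or one-tissue model selection, no reference-tissue
  Logan, no multilinear (MA1/MA2) or noise-bias-corrected variants.
* No image-domain preprocessing: motion correction, registration and ROI
  definition are upstream; NIfTI support is limited to mean-over-mask TAC
  extraction with strict orientation matching and external frame timing.
* The delay is bounded to [0, 20] s; negative delays (tissue leading the
  blood-pool curve, possible for some ROI/blood-pool pairs) are out of range.
* Logan V_T at t* = 20 min carries a small negative bias that grows for
  slowly equilibrating kinetics; t* is configurable but not auto-selected.
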