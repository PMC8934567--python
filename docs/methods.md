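# Methods

## Stimulus model

Stimuli are gratings in log-polar retinal coordinates,
`f(r, θ) = cos(ω_r ln r + ω_a θ + φ)`, with integer radial frequency `ω_r`
(radians per unit of ln eccentricity) and integer angular frequency `ω_a`
(cycles per revolution). The phase gradient of this function gives the
local spatial frequency `ω_l = √(ω_r² + ω_a²) / r` radians/degree and
local orientation `θ_l = θ + atan2(ω_a, ω_r)`; all public interfaces
report frequency in cycles/degree (dividing by 2π) and reduce `θ_l` mod π.
`θ_l = 0` denotes a locally *vertical* grating (horizontal phase
gradient); `atan2` keeps pinwheels (`ω_r = 0`) well defined. The canonical
set has 48 vectors — 10 pinwheels, 10 annuli, 10 forward and 10 reverse
spirals, 8 fixed-magnitude mixtures with `√(ω_r²+ω_a²) ≈ 32` — spanning an
exact 91/4 = 22.75-fold frequency range at any eccentricity (the smallest
magnitude is the 4-cycle spirals at 4√2, the largest the 91-cycle spirals
at 91√2). At the 1–2° band center the set runs from 0.600 to 13.65 cpd; at
the 11–12° band center from 0.078 to 1.781 cpd.

Rendering uses a 1536×1536 grid at 64 px/degree by default (12° radius),
with the region inside 0.96° and outside 12° set to mid-gray. Since only
the existence of a central anti-aliasing mask is prescribed, the mask
edges get a raised-cosine amplitude ramp of 0.5°, applied at both borders
for symmetry. Display compensation fits a degree-1 smoothing spline to
measured (period, Michelson contrast) pairs as a function of frequency in
cycles/pixel (smoothing budget 1e-3, appropriate to contrasts on [0, 1])
and multiplies the stimulus by the envelope
`mtf(ω_l) / max(mtf over the image's frequency range)`, so displayed
contrast is equalized without amplitudes ever exceeding the input.
Frequencies outside the measured range clamp to the nearest sample with a
logged warning.

A note on DC content: any stimulus with `ω_a ≠ 0` completes an integer
number of cycles per revolution, so its mean over the annulus cancels to
numerical precision; annuli (`ω_a = 0`) retain a phase-dependent DC
residual that decays with `ω_r` (up to ~0.2 at `ω_r = 6`). Tests assert
exactly this rather than a blanket zero-mean claim.

## Synthetic voxel responses

The generator emulates the data product of retinotopy + GLM response
estimation. pRF centers are log-uniform in eccentricity on [0.5°, 13°]
(deliberately extending past the stimulated 1–12° so the border-exclusion
rules are exercised), uniform in polar angle, with size
`0.1·r + 0.15°` under 20% lognormal jitter. Noiseless responses are the
2-D model's forward prediction at the pRF center. Noise is additive
Gaussian at the run level (12 runs), homoscedastic within voxel; per-voxel
noise standard deviations are lognormal with σ = ln(10)/2, giving a 10×
16th–84th percentile spread so precision weighting matters. Response
amplitudes are run means; 100 bootstraps are means of runs resampled with
replacement; `σ_vi` is half the 68-percentile range of the bootstraps, and
`σ_v² = mean_i(σ_vi²)`.

Defaults: `noise_scale = 0.3` (median run-level SD, i.e. run-mean SE
≈ 0.087 against a unit-gain peak response — a mid-range single-voxel fMRI
SNR), `n_voxels = 3000` per subject (plausible post-exclusion V1 count,
sized for stable fits), between-subject heterogeneity ±20% multiplicative
jitter on all nonzero template parameters. The ground-truth template puts
the preferred period at `0.12·r + 0.35°` with σ = 2.2 octaves,
`p1 = p3 = 0.07` (equal absolute-vertical and relative-annular period
advantages, sized so the annulus–pinwheel gap at 5° on the horizontal
meridian is ≈ 1.06° vs 0.80° and cancels at the vertical meridian),
`p2 = 0.02`, `p4 = 0.01`, `A1 = 0.04` (≈ 8% weaker horizontal than
vertical gain), `A2 = 0.02`, `A3 = A4 = 0`.

What the generator does *not* emulate: hemodynamics and GLM fitting
itself, temporally or spatially correlated noise, pRF-size-dependent
frequency integration (responses depend on the pRF center only), and
non-V1 signals. Passing recovery tests therefore demonstrate estimator
correctness under the stated noise model, not robustness to every
real-data pathology.

## One-dimensional tuning curves

Eligible voxels are binned into eleven 1° half-open bins [1,2) … [11,12);
responses are averaged per bin and stimulus class without precision
weighting (intra-bin weighting is an open choice; unweighted means keep
the estimator simple), paired with `ω_l` evaluated at the arithmetic bin
center, and fit with `A·exp(−log2(ω_l p)²/(2σ²))` by bounded least squares
(`curve_fit`; start at the empirical peak, p = 1/argmax frequency, σ = 2
octaves; bounds p ∈ [0.01, 100]°, σ ∈ [0.1, 10] octaves; at least 4 points
spanning > 1 octave). Note the log argument is `log2(ω_l·p)`, so `p` is
the period at the curve's mode and FWHM = 2√(2 ln 2)·σ octaves.
Uncertainty comes from refitting under run resampling; subjects combine
via the precision-weighted bootstrap mean with weights `1/σ_s²`,
`σ_s` the subject's 16–84 percentile spread. Zero spreads are capped at
the largest finite weight rather than dominating. Each bootstrap draw
resamples as many subjects as are available (12 in a full-size cohort).

## Two-dimensional model and fitting

The model and loss are as in the README. Fitting details:

- Parameters are optimized unconstrained with `σ = exp(s)`; positivity of
  the preferred period and gain is enforced by quadratic hinge penalties
  (floor 1e-3 on `p_v`, 0.05 on `A_v`, weight 10) that are inactive at any
  reasonable solution.
- The optimizer is AMSGrad (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with analytic
  gradients, learning rate 0.02, at most 25 000 iterations, stopping when
  the relative objective change over a 100-iteration window falls below
  1e-6. The objective normalizes the precision weights to sum to one per
  subject (same minimizer as the raw mean, better conditioned); reported
  cross-validation losses use the raw per-voxel mean.
- Voxels with all-zero uncertainty (noiseless simulations) receive uniform
  weights; fits require ≥ 50 eligible voxels.
- Initialization: σ = 2 octaves, a = 0.1, b = 0.3, modulations 0.
- Several subjects are fit simultaneously by stacking padded arrays;
  per-subject objectives are independent, so this is exactly equivalent to
  sequential fitting, just vectorized.
- Eligibility: pRF center at least one pRF standard deviation inside both
  stimulus borders and non-negative mean response.
- Gradient correctness is verified against central differences (agreement
  to ~1e-9 relative), and noiseless self-consistency recovers generating
  parameters to < 1e-3 relative error.

## Model selection

The registry encodes the 14 submodels in one place: 1 {σ,b}, 2 {σ,a},
3 {σ,a,b}, 4 = 3+{p1,p2}, 5 = 3+{p3,p4}, 6 = 3+{p1–p4}, 7 = 3+{A1,A2},
8 = 4+{A1,A2}, 9 = 6+{A1,A2}, and 10–14 add {A3,A4} to 3, 5, 6, 7, 9.
Submodels 4 and 5 (absolute-only vs relative-only period effects) are the
one point of reconstruction from the described comparisons; they are
defined only in `build_registry` so the reading can be revised in one
place. Cross-validation holds out 4 of the 48 classes per fold (12 folds,
seeded permutation, identical across submodels and subjects), assembles
held-out predictions into one complete 48-vector per voxel, and scores
with the normalized precision-weighted loss. Fold fits warm-start from the
submodel's full-data fit (same optimizer, capped at 3000 iterations with a
1e-5 window tolerance — the warm start makes this ample). Losses are
demeaned per subject with the grand mean restored; the winner minimizes
the mean normalized loss, ties to the simpler model.

## Group aggregation and report

Group parameters are a precision-weighted bootstrap across subjects
(weights = mean response precision over fit voxels, normalized by the
summed weights so parameter units are preserved). Surfaces evaluate the
period and gain equations per bootstrap draw on an eccentricity × angle
grid (defaults 1–12° in 0.25° steps, 0–2π in 1° steps); relative
categories set `θ_l = θ_v + offset` (annulus 0, pinwheel π/2, spirals
∓π/4), absolute ones fix `θ_l` (vertical 0, horizontal π/2, diagonals
π/4). Gain curves are normalized to mean 1 over angle. The meridian split
assigns voxels with `θ_v ∈ [0, π/4] ∪ (3π/4, 5π/4] ∪ (7π/4, 2π]` (half-open
exactly as printed; π/4 goes to the horizontal set) to the horizontal
quadrants, fits {σ,a,b} per quadrant per subject on unweighted response
estimates, and bootstraps the horizontal-minus-vertical period difference
across subjects.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (NumPy `default_rng`);
identical configs give bit-identical tables. The recovery experiments in
the test suite and acceptance script use 4 subjects × 2000 voxels
(slope/intercept recovery, 3–10 replicates) and 4 subjects × 1000 voxels
(model recovery with the full 14 × 12-fold CV); the pipeline smoke preset
is 2 subjects × 250 voxels. These sizes give stable estimates — recovery
is well within the asserted 5% — while keeping a full run in minutes on
one CPU.

## Known limitations

- The instantaneous-frequency approximation: responses are evaluated at
  the pRF center only; pooling over a pRF's spatial extent would blur the
  effective tuning for large, peripheral pRFs.
- The noise model is white within voxel and across runs; real GLM
  estimates have correlated errors across stimuli and space.
- The precision weights (1/σ_v²) are not re-estimated during fitting;
  voxels with extremely small bootstrap spreads can dominate, which the
  lognormal spread in the generator is designed to exercise.
- The MTF spline is monotone in practice but not by construction; strongly
  non-monotone measurement tables would be fit faithfully rather than
  regularized.
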