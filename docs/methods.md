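# Methods

This note documents the models, the synthetic data generator, the numerical
choices, and the limitations of `wmhfreq`.

## The analysis

Three measurements connect white matter microstructure to macrostructural
damage:

**Segmentation.** A FLAIR-like volume is z-scored over brain voxels (mean 0,
SD 1 over the brain mask, never the full grid — background zeros would bias
the threshold) and WMH are all brain voxels with z ≥ k, inclusive, with
k = 1.2 by default. NAWM is the exact set difference `white_matter \ WMH`.
The threshold is applied within the whole brain rather than within white
matter only, so hyperintense gray matter voxels can be flagged; NAWM is
derived afterwards. A `wm_restrict` pipeline option intersects the WMH masks
with the white-matter mask before frequency mapping, which removes
gray-matter contamination of the low-frequency bin (see *Binning* below). No
morphological cleanup is applied by default.

**Frequency mapping.** With per-subject binary WMH masks on a common grid,
the frequency at voxel v is `count(v)/n`. Binning uses half-open percentage
intervals (low, high] evaluated on the exact rational `100·count/n` — never
on rounded percentages — so 0% belongs to no bin, boundary values land
deterministically in the lower-labeled bin, and a value like 5.04% cannot be
rounded into the wrong bin. Frequencies above the top edge (the default bins
stop at 20%) are left unbinned; an optional overflow bin collects them.

**Statistics.**

- *Paired t-test* on per-subject (mean FA in WMH, mean FA in NAWM); subjects
  whose WMH mask is empty have an undefined WMH mean (NaN, never a silent 0)
  and are excluded with their count recorded.
- *Simple linear regression* of WMH volume (cm³) on mean FA within WMH. This
  direction makes the slope's magnitude dimensionally interpretable as cm³
  per unit FA; the reverse direction is available
  (`regression_direction="fa_on_volume"`).
- *Repeated-measures ANOVA with a Satterthwaite-type correction.* Young
  subjects each contribute a mean FA per frequency bin (equal cell sizes);
  bins have very different voxel counts, hence very different noise levels.
  The one-way within-subject decomposition gives
  `F = MS_bins / MS_error`, and the Box (Greenhouse–Geisser-type) epsilon,
  computed from the double-centered sample covariance of the bin columns,
  multiplies both numerator and denominator df:
  `df1 = ε(k−1)`, `df2 = ε(k−1)(n−1)`, with `ε ∈ [1/(k−1), 1]` and ε = 1
  under compound symmetry. For k = 2 the F statistic equals the squared
  paired t exactly. A Welch one-way ANOVA treating bins as independent
  groups is provided as a sensitivity variant
  (`ws_variant="independent"`). The effect size reported is the partial
  sum-of-squares ratio `SS_bins / (SS_bins + SS_error)`.

All tests are two-sided with 95% CIs and no covariate adjustment.

## Diffusion tensor fitting

The mono-exponential model `S_i = S0 exp(−b_i gᵢᵀ D gᵢ)` is linear in
`(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, log S0)` after taking logs; one ordinary
least-squares solve per voxel (a single pseudo-inverse, since the design is
shared) estimates the tensor. Choices:

- *Estimator:* plain OLS on log-signals. It is exact on noiseless data,
  which is what the round-trip self-consistency checks exercise; weighted or
  nonlinear variants would differ slightly on noisy data.
- *Signal floor:* signals are clamped to `1e-6 × mean b0` before the log
  (Rician noise can produce near-zero magnitudes); the number of floored
  signals is reported in the pipeline log.
- *Negative eigenvalues* (noise artifacts) are clamped to 0 before FA, so
  FA ∈ [0, 1] always; FA is 0 by convention for an all-zero tensor.
- *Outside the brain* FA is NaN, never 0, so masked means cannot be diluted.
- A rank-deficient gradient scheme (fewer than 6 independent directions)
  raises an explicit error.

## The synthetic cohort generator

The generator emulates the *statistical structure* the analysis consumes,
not brain anatomy. All outputs are pure functions of (config, seed); every
per-subject quantity draws from its own seeded stream.

**Anatomy.** Nested ellipsoids on a shared grid (default 48³ voxels of
2 mm): central CSF ventricle, white-matter compartment, gray-matter shell,
background. The ventricle is generously sized (≈13% of brain volume, an
aged/atrophic geometry): the dark CSF tail spreads the brain intensity
histogram so that the global mean+1.2 SD threshold lands usefully above the
white-matter mean, as it does on real FLAIR, whose histogram is spread by
CSF, partial volume and bias fields that the phantom otherwise lacks. The
seed jitters compartment semi-axes by ±3%.

**Lesion probability field.** `p(v) ∝ exp(−d(v)/decay) · (1 + (aw−1)·y/Y)`
with d the Euclidean distance to the ventricle surface (periventricular
predominance, decay 24 mm), an anterior gain aw = 1.6 (frontal
predominance), normalized so max p = 0.22, and support restricted to white
matter by default (setting `restrict_lesions_to_wm=False` lets lesions enter
gray matter).

**Per-subject lesion masks.** A standard-normal latent field is smoothed
with a periodic Gaussian kernel (σ = 3 mm) and thresholded voxelwise at the
exact quantile of its known marginal distribution: lesions are spatially
contiguous blobs *and* the cross-subject positive rate at every voxel equals
p(v) exactly (the periodic boundary keeps the marginal stationary; the
kernel's l2 norm gives the marginal SD in closed form).

**Severity coupling.** Each older subject carries a severity scalar
γ ~ Gamma(mean 1, SD 0.4) that (a) scales the subject's lesion rate to
`min(1, γ·p)` — leaving the cross-subject marginal at p since E[γ] = 1 —
and (b) deepens a within-lesion FA reduction of `lesion_depth·γ` (default
0.06 at γ = 1). This encodes damage progression: heavier lesion burden
co-occurs with lower FA inside lesions. Without it, a pure
threshold-sampling model produces the *opposite* association (subjects with
larger masks extend into lower-probability, higher-FA territory), which is
not how lesion progression behaves.

**Microstructure.** In white matter the normative (young) truth is the
affine ramp `fa_true = fa0 − beta·p` (fa0 = 0.45, beta = 0.30): regions that
frequently lesion have normatively lower FA — the hypothesis under study,
and the signal the bin-wise ANOVA is designed to detect. Gray matter and CSF
get fixed low FA (0.15, 0.03) and realistic mean diffusivities
(0.75/0.85/3.0 ×10⁻³ mm²/s). Setting beta = 0 and lesion_depth = 0 yields a
null generator in which lesion placement is independent of microstructure.

**Images.** FLAIR = tissue mean + lesion contrast + iid Gaussian noise
(means 0/10/100/92 for background/CSF/WM/GM; contrast 45; noise SD 15 —
i.e. the default operating point has lesion contrast equal to 3× the noise
SD). GM is set slightly *darker* than WM; on real FLAIR GM is mildly
brighter, but with a global-threshold rule at this noise level a brighter GM
would flood the segmentation with false positives — a documented phantom
simplification. DWI signals follow the tensor model with an axially
symmetric tensor realizing (fa_true, md_true) about a per-voxel random
principal axis shared by all subjects and both cohorts (so maps are
voxelwise comparable); noise is Rician (magnitude of a complex Gaussian
perturbation) at SNR 20 on S0 = 1000, b = 800 s/mm², 16 directions for the
older protocol and 56 for the young protocol (deterministic spherical-
Fibonacci direction sets; no protocol harmonization — the analysis never
compares FA between cohorts directly).

The closed-form inverse used to build tensors: for λ1 = md(1+2a),
λ2 = λ3 = md(1−a), FA = 3a/√(3+6a²), inverted by a = FA√3/√(9−6FA²),
valid for FA < 1.

## Problem sizes and calibration

Default cohort sizes are desk-scale: 60 older and 20 young subjects on a
48³ grid; the null-calibration simulations use 400 replicates of a 16³ grid
with 20/8 subjects and ground-truth masks. Phantom geometry and the lesion
field's decay/smoothing were calibrated once against the segmentation
operating point the package targets (Dice = 1 noiseless; Dice > 0.8 at
lesion contrast = 3× noise SD) and then frozen; with iid Gaussian noise and
a pure global threshold, that operating point constrains the feasible design
tightly — the threshold must sit roughly 2–2.5 noise-SD above the WM mean
while lesions sit 3 above it, which requires both the spread ventricle
geometry above and a substantial lesion burden (mean p ≈ 0.15 in WM, i.e. a
heavily lesioned cohort).

Null-generator type-I checks use ground-truth lesion masks rather than
segmentations: with segmentation in the loop, gray-matter false positives
concentrate low-FA voxels in the low-frequency bin — a real composition
effect (the same contamination the analysis observes at its low-frequency
bin when gray matter is included), not a calibration failure of the tests.

## What passing tests do and do not show

The generator matches the analysis's assumptions by construction:
mono-exponential diffusion, Rician magnitude noise, additive Gaussian FLAIR
noise, piecewise-constant tissue intensities, perfect spatial
correspondence across subjects, and lesions that are exactly hyperintense
by a fixed contrast. Passing tests therefore certify the *computational
chain* — segmentation arithmetic, tensor algebra, counting, binning,
degrees-of-freedom corrections, calibration of the simulated frequencies —
not robustness to eddy currents, susceptibility distortion, bias fields,
partial-volume mixing, registration error, or biological FA/lesion
heterogeneity, none of which the phantom models. Registration, skull
stripping, atlas labeling and tissue segmentation are out of scope
(masks and the common grid come from the generator).

## Known limitations

- The regression's slope magnitude on synthetic data (≈ −185 cm³ per unit
  FA at defaults) depends directly on the severity-coupling parameters; only
  its sign and significance are meaningful claims.
- The Box epsilon estimator is biased slightly below 1 under exact
  sphericity in finite samples; the ANOVA is correspondingly a little
  conservative.
- The OLS t-test in the volume-on-FA regression is mildly anti-conservative
  under the null generator (measured rejection ≈ 0.05–0.075 at α = 0.05)
  because the predictor's measurement noise shrinks with lesion volume
  (more voxels averaged), a heteroscedasticity the classical test ignores.
- Empty frequency bins raise an explicit error rather than being dropped;
  tiny cohorts should use coarser bin edges.
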