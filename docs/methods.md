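# Methods

## Signal model and tensor estimation

Each voxel's diffusion-weighted magnitude signal is modelled as
monoexponential, `S_i = S0 · exp(−b_i · g_iᵀ D g_i)`, with D the 3×3
symmetric diffusion tensor (mm²/s), b_i the b-value (s/mm²) and g_i the
unit gradient direction of frame i.  Taking logs turns estimation into a
7-parameter linear problem in (D_xx, D_yy, D_zz, D_xy, D_xz, D_yz,
ln S0) with design row `[−b gx², −b gy², −b gz², −2b gx gy, −2b gx gz,
−2b gy gz, 1]`.  The default estimator is weighted least squares with a
single reweighting pass from the OLS solution, weights equal to the
squared predicted signals — the standard correction for the
heteroscedasticity the log transform induces.  Plain OLS is available by
flag.  Fitting requires at least one b = 0 frame and six non-collinear
diffusion directions (checked by the rank of the quadratic design).

Numerical guards:

- **Signal floor before the log**: `max(S, 1e-3 · S0_estimate)`, with
  S0 estimated as the per-voxel mean b0 signal.  Prevents −∞ at low SNR;
  inert on clean data.
- **Eigenvalue floor** 1e-6 mm²/s: eigenvalues below the floor are
  clamped and the tensor rebuilt in its own eigenbasis.  Voxels needing
  no clamp are passed through bit-exactly, so noiseless fits stay exact.
  The floor keeps diffusivities physical and FA defined.
- Voxels whose fit produces non-finite parameters are removed from the
  output mask (with a logged count) rather than crashing the volume.

Brain masking follows the background-noise rule: the threshold is
`mean + k·SD` (k = 2 by default) of magnitudes in a background region —
either a supplied mask or cubic patches at the eight grid corners — and
a voxel is in-brain when its mean b0 signal exceeds the threshold.

FA is computed from the eigenvalues as
`sqrt(3/2)·sqrt(Σ(λᵢ−λ̄)²)/sqrt(Σλᵢ²)` (defined as 0 for an all-zero
tensor) and colour-FA as `|principal eigenvector| · FA` per RGB channel.

## The ALPS index

With component means taken over a projection-fiber ROI and an
association-fiber ROI (left hemisphere by default),

```
ALPS = ((Dxx_proj + Dxx_assoc)/2) / ((Dyy_proj + Dzz_assoc)/2)
     = D_xmean / D_yzmean .
```

The index is scale-invariant in the four inputs, strictly increasing in
the two x-components and strictly decreasing in the two perpendicular
ones; these are property-tested.  All twelve component means (six per
ROI) are extracted and reported in 10⁻³ mm²/s — the analysis of the
off-diagonal components uses the same machinery — while everything
internal stays in mm²/s; the unit conversion happens exactly once, at
the ROI-mean reporting layer.

ROI placement accepts either a label volume (masks used verbatim) or a
config of sphere centers with a default 5 mm radius, clipped to the
brain mask.  A deliberate methodological substitution: template (MNI)
normalisation of the diffusivity maps is replaced by native/phantom-space
ROI placement, since registration is a generic tool step rather than part
of the computation this package defines; external ROI volumes drawn in
any space the user registered to are accepted through the label pathway.
The left hemisphere is the half-grid with the lower x indices under the
declared RAS-like axis convention (+x toward the subject's right).

## The phantom

The digital phantom encodes the geometry the index assumes, medial to
lateral along x: a ventricle slab (isotropic CSF-like diffusivity,
3.0×10⁻³ mm²/s), a projection-fiber shell (principal axis z), an
association-fiber shell (principal axis y), a subcortical shell
(principal axis x), and a zero-signal background rim.  Default
fiber-shell diffusivities are the published OSA group means; the grid is
32×32×20 voxels of 1.8×1.8×1.7 mm (the in-plane/slice resolution class
of the target acquisition), sizes chosen so region means are stable yet
a simulate–fit cycle runs in well under a second.  A single *glymphatic
factor* g multiplies the x-diffusivity of both fiber shells, so the
ground-truth index is known in closed form and is linear in g.

Forward simulation produces `S0·exp(−b gᵀDg)` per frame inside the
object and zero outside, then applies **Rician** noise `|S + n₁ + i·n₂|`
with σ = S0/SNR.  Magnitude reconstruction is what the scanner outputs,
and its floor-like bias at low SNR is exactly what the noise-threshold
and eigenvalue-clamp logic must face; Gaussian noise would hide it.  The
default gradient scheme is one b0 plus 30 directions at b = 800 s/mm²
placed on a Fibonacci spiral — a deterministic quasi-uniform spread
(electrostatic-repulsion layouts differ negligibly for tensor fitting).
The number of b0 frames is configurable; one is the default.

## The cohort generator

The generator emulates the *statistical* structure of the study
population, not its anatomy.  Per group (59 OSA / 62 control by
default), each subject receives:

- twelve ROI component means drawn from per-group truncated normal
  distributions (truncation at 0) whose defaults are the published group
  means and SDs;
- clinical covariates (age, sex ratio, BMI, heart rate, blood pressures,
  PSQI, ESS; for OSA also AHI, baseline SaO₂ and the desaturation depth
  ΔSaO₂) from per-group truncated normals matching the published
  demographics.  AHI is truncated at 15 events/hour, the study's
  eligibility criterion (at-least-moderate OSA), which raises the
  realised mean a few events/hour above the printed marginal mean.
  SaO₂ nadir is derived as baseline − ΔSaO₂ so the desaturation is
  non-negative by construction.

The ALPS index is computed from each subject's four drawn components
(default), or drawn directly from the per-group published ALPS
distribution (`alps_mode="direct"`) when a comparison at exactly those
parameters is wanted.  Components are drawn **independently** within
subject: no between-component covariance is published, so independence
is the assumption of record.  Consequence: the derived ALPS SD (≈0.12)
emerges from the component SDs and happens to match the published ≈0.11,
but cross-component correlation structure in real data is not emulated —
multivariate analyses across components should not lean on the
generator.

Rank correlations between a clinical variable and a component can be
planted via a Gaussian copula: latent normals are coupled with Pearson
ρ_p = 2·sin(π·ρ_s/6) and mapped through the strictly monotone
truncated-normal quantile transform, which preserves the Spearman
correlation exactly.

A slow path (`voxel_phantoms=True`) materialises one phantom per subject
with the subject's diagonal components embedded in the fiber shells; the
off-diagonal means cannot be represented in the axis-aligned phantom and
exist only in the drawn table.

## Statistics layer

- **Demographics**: independent-samples t-tests (pooled variance by
  default, Welch by flag) for continuous variables, 2×2 Pearson
  chi-square (no continuity correction by default) for sex; missing
  values excluded per variable with the per-group n reported.  A
  summary-statistics t-test is provided for printed-table inputs.
- **Group comparison**: ANCOVA as the linear model
  `value ~ intercept + group + age + sex` (sex coded male = 0,
  female = 1; group control = 0, OSA = 1), group effect tested by the t
  statistic on its coefficient (the partial F is its square); adjusted
  means are predictions at grand-mean covariates.  Constant covariate
  columns are dropped, which reduces the model *exactly* to the pooled
  t-test — a tested identity.  BMI is deliberately not a default
  covariate (the adjustment set of record is age and sex, despite the
  group BMI difference); it can be added by the caller.  Bonferroni
  family size defaults to the number of outcomes in the table being
  tested (3 for the index family) and is configurable; both raw and
  adjusted p-values are always emitted, since published tables are often
  ambiguous about which is printed.
- **Correlations**: Spearman's r as Pearson correlation of mid-ranks
  (tie-corrected), two-sided p from the t approximation, exact
  permutation p by flag for n ≤ 9; pairwise deletion of missing pairs;
  a constant vector yields "not estimable", not a crash.  The default
  severity panel is the four reported pairs (projection: ESS–D_xy,
  SaO₂-nadir–D_xx, ΔSaO₂–D_xx; association: AHI–D_zz), with a full
  clinical-by-component grid available.

## What the tests do and do not show

Closure tests (phantom → noiseless simulation → fit → ROI means →
index) verify the pipeline is *internally* exact; noisy-recovery and
SNR-monotonicity tests verify robustness to Rician noise at realistic
SNR.  Calibration tests verify the statistics layer against closed-form
oracles (two-sample power, p-value uniformity, family-wise error,
planted-correlation recovery) on the fast generator path, using 500–1000
replicate cohorts at the study's sample sizes.  None of this validates
ROI placement on real anatomy, registration quality, motion/eddy
artefacts, or crossing-fiber effects — all outside the phantom's world.

## Known limitations

- Axis-aligned single-tensor regions: no crossing fibers, no partial
  volume between shells, no CSF pulsation.
- No eddy-current/motion correction and no template registration;
  real-data use assumes preprocessed, aligned input.
- Between-component independence in the generator (see above).
- The exact ROI sizes/coordinates of published studies are unreported;
  sphere radius is exposed as a parameter (default 5 mm) rather than
  guessed more precisely, and sensitivity to it can be explored directly.
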