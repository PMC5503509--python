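# Methods

This note documents the models, parameter choices and numerical
decisions behind `follimech`, and what the synthetic-data tests do and
do not demonstrate about real measurements.

## Contact mechanics and the forward model

The elastic response of a pyramidal tip indenting a flat soft sample is
modelled by the Sneddon/Bilodeau contact law

    F = C · E/(1 − ν²) · tan θ · δ²

with geometry constant `C = 1/√2` for a four-sided pyramid and `2/π`
for a cone, half-opening angle `θ` (default 35°, typical for
silicon-nitride probes), and Poisson ratio `ν = 0.5` (incompressible
hydrated tissue). None of these constants is measured by the pipeline;
all are configurable on `TipGeometry`, because published "modified
Hertz" variants differ mainly in `C`.

The synthetic generator inverts this law exactly. During an approach at
constant piezo velocity the deflection `w = d − d₀` at piezo travel
`s = z − z₀` past contact satisfies the implicit force balance
`k·w = C·E/(1−ν²)·tanθ·(s − w)²`, which is quadratic in `w`; the
physically admissible branch is evaluated in the cancellation-free form
`w = 2As² / (2As + k + √(4Ask + k²))` (with `A` the stiffness
prefactor), exact to machine precision for all moduli. A per-sample
bracketed root finder serves as the independent oracle in the tests.
Each curve provides ≥ 50 nm of pre-contact travel and reaches 100 nm of
indentation in 2048 samples. Optional noise is additive Gaussian
(`noise_sd_deflection`, in metres) and/or multiplicative Gaussian
(`noise_fraction_deflection`; 5% is the working level used in the noisy
cohorts). A rate-dependent preset scales the apparent modulus as
`E·(v/v_ref)^(−γ)` above the reference approach speed of 0.4 µm/s,
reproducing the viscoelastic softening signature that the speed-sweep
diagnostic is designed to flag; no viscoelastic correction is applied
anywhere.

## Calibration

The spring constant follows from equipartition of the cantilever's
fundamental mode: `k = k_B T / var_p(d)`, with the population variance
of a thermal deflection trace (≥ 100 samples required; 2¹⁷ samples give
≈ 0.4% relative standard error, consistent with the χ²-variance scaling
`√(2/n)` verified by Monte Carlo in the tests). The simulated
cantilever is a soft probe with true `k = 10 pN/nm` at 295 K.

## Contact detection and fitting

The baseline `d₀` is the median deflection over the leading 20% of the
approach; its robust scatter (1.4826·MAD, floored at 0.1 pm so exact
noiseless records remain detectable) sets a 3σ crossing threshold whose
first sustained crossing initializes `z₀`. The final Hertz fit then
frees both `E ≥ 0` and a contact offset `dz` (bounded by the window
width), so the threshold estimate only needs to be close. Fits use
`scipy.optimize.least_squares` with residuals weighted by `1/max(F,
5%·F_max)`: deflection noise on soft cantilevers is predominantly
multiplicative, so relative residuals are near-homoscedastic, and this
weighting keeps the joint (E, dz) fit unbiased under noise (unweighted
fitting inflates the recovered modulus by ~3% at 200 kPa; weighted it
stays within ~1.5% across 5–200 kPa with 5% noise). Only samples with
`0 < δ ≤ 50 nm` enter the fit; the shallow window isolates the thin
stiff shell from the soft interior. The window is measured in
indentation depth by default; a configuration switch (`window_on`)
measures it in deflection instead, since both conventions appear in
practice. Fewer than 10 in-window samples flags `window_short`; a
relative rms residual above 20% flags `poor_fit`; curves that never
cross the contact threshold are flagged `no_contact` and excluded, and
any such curve flags its whole position. Each XY position is probed
four times and the per-curve fits averaged (fit-then-average; the
alternative average-then-fit is deliberately not the default because it
is sensitive to contact-point jitter between repeats).

## Stage and genotype presets

Regional Young's moduli (Pa) for the wild type:

| stage | pole | terminal | central |
|-------|------|----------|---------|
| 3 | 15 k | 30 k | 30 k |
| 5 | 20 k | 40 k | 40 k |
| 7 | 26.9 k | 53.8 k | 70 k |
| 8 | 20 k | 61.5 k | 80 k |

These encode the measured progression (30/40/70 kPa central at stages
3/5/7), poles ~50% softer than the terminal/central level, the central
region becoming ~30% stiffer than terminal by stage 7, and a ~300%
pole-to-center rise by stage 8 (central = 4 × pole; the absolute
stage-8 level, not separately constrained, is set to 80 kPa to continue
the stage trend). Collagenase digestion multiplies all moduli by 0.03
(a 97% loss). Mutant presets encode the observed qualitative orderings:
*fat2* and *msn* knockdowns stay at the 30 kPa stage-3 level,
isotropic, with a four-fold circumferential coefficient of variation
(20% vs the wild-type 5%); SPARC depletion scales the whole profile to
80%; uniform Collagen IV depletion flattens at 30% of central; EHBP1
overexpression raises the center 15%; Perlecan overexpression flattens
at half the terminal level; regional drivers (`mirr>ColIV-KD`,
`fru>EHBP1`) flatten the gradient from the center or the termini; and
JAK/STAT inhibition (`Dome-DN`) flattens at the terminal level. These
single numbers stand in for biological distributions; only their
orderings and the printed ratios are meaningful.

A–P region boundaries on the normalized meridian arc coordinate
`u ∈ [0, 1]`: pole for `u < 0.15` or `u > 0.85`, terminal for
0.15–0.35 / 0.65–0.85, central for 0.35–0.65. The source figures give
no numeric boundaries; these splits are a package convention applied
uniformly to stiffness mapping and burst positioning. The anisotropy
index divides central stiffness by the mean over the five A–P sample
positions (pole, terminal, central, terminal, pole) — the averaging set
is likewise a convention, chosen to match the five measured positions.
Group comparisons use Welch's unequal-variance two-tailed t-test (the
safer default when only "t-test" is specified), with stars at strict
thresholds p < 0.05 / 0.01 / 0.001.

## Phantoms and surface unrolling

Phantoms are Gaussian ridges (default half-width 1 µm, floored at one
voxel) around an ellipsoid surface; the exact surface distance is
approximated by `(r² − 1)/(2|∇r|)` of the normalized implicit form.
Shell brightness is `level · (1 + A–P profile) · (1 + circumferential
modulation) · (1 + fibril stripes)`: a Gaussian central elevation
(amplitude 0.5, width 0.15 in u, for Collagen-IV-like patterns),
a smooth 4-harmonic azimuthal modulation scaled to the preset's
circumferential sd, and sinusoidal ridge families with physical spatial
frequency whose orientation encodes planar polarity (one
circumferential family for ordered presets; five families at random
orientations for the disordered *fat2*/*msn* texture, with the
azimuthal wavenumber rounded to an integer to keep the texture
periodic). The default voxel size is 0.17 µm lateral × 0.50 µm axial,
matching the confocal acquisition being emulated; tests and examples
render coarser (1–2 µm) voxels and smaller semi-axes to keep stacks
small, which the chain tolerates because every quantification is
expressed in physical units.

Surface extraction thresholds with Otsu's method, fits an algebraic
quadric for initialization, and refines geometrically by least squares
on the normalized radius (center, log-semi-axes, rotation vector). The
algebraic fit alone is biased by several percent on shells of finite
thickness, which is why the geometric refinement exists. The chart
parameterizes the ellipsoid by normalized meridian arc length `u` (not
polar angle — profiles are "standardized to follicle length") and
azimuth `φ`, with ≤ 1 µm grid spacing, and assigns each node the
maximum intensity within ±3 µm along the analytic surface normal
(13 samples, trilinear interpolation); nodes whose band leaves the
stack are masked. This analytic ellipsoid chart deliberately replaces
general surface-fitting toolboxes: it is exact for the phantoms the
package generates and keeps the pullback transparent. For meridian arc
length on triaxial ellipsoids the transverse radius is approximated by
(b + c)/2; phantoms are spheroidal, where this is exact.

Line profiles average five one-node-wide lines evenly placed in a 10 µm
stripe (fewer, with a warning, if the grid is too coarse); per-follicle
variability is the population variance of the profile. Fibril
orientation uses the structure tensor (σ = 2 nodes, nearest-edge
padding); the alignment score is the energy-weighted doubled-angle
order parameter `|⟨e^{2iθ}⟩| ∈ [0, 1]` over the stronger half of the
tensor energy, with angles measured from the circumferential chart
axis. No published definition exists for this polarity statistic; the
order parameter is a package choice validated only against synthetic
ground truth (≈ 1 for parallel stripes, ≈ 0 for isotropic noise).

## Junction polarity and recoil

Junctions are classified by their angle to the A–P axis: 60–90° = A–P,
0–30° = circumferential, the 30–60° gap excluded (mirroring the assay's
bins), with a 1 nano-degree tolerance so exact bin edges stay on their
nominal side. Intensities are 8-px-wide line-profile means on a
rolling-ball background-subtracted image (radius configurable, default
50 px), and the statistic is the ratio of class means — not the mean of
per-junction ratios, matching "the mean ratio" wording; fewer than 30
junctions per class warns. Recoil velocity is the first-frame secant
`(L(t₁) − L₀)/t₁` with `t₁ ≤ 300 ms`; the generator's relaxation model
`L(t) = L₀ + v₀τ(1 − e^{−t/τ})` shows the estimator's bias directly:
for τ = 5 s and t₁ = 0.3 s the secant recovers v₀ to within 3%, and the
bias grows as τ approaches the frame interval.

## Swelling assays

Swelling series are midplane outlines; per-frame ellipses are fitted by
least squares (`skimage` EllipseModel) and the aspect ratio is
major/minor. A burst is the first frame whose polygon area drops by
more than 20% relative to the previous frame — the threshold is a
package operationalization of what is judged visually from movies — and
an explicit breach-marker channel, when present, takes precedence.
"Instant" bursting means failure at the first post-immersion frame.
Breach positions are projected onto the pre-burst ellipse and
classified with the same arc-coordinate boundaries as stiffness
mapping. Cohort tables report burst percentage with a 95% Wilson
binomial CI, median burst time, the position distribution and mean
pre-burst aspect ratio. Burst hazards per genotype (e.g. wild type
0.04/frame at stage 7, pole-weighted 70/20/10 over pole/terminal/
central bands; collagenase instant and uniform; EHBP1 overexpression
zero) are qualitative encodings — no quantitative hazard model is
published — so only orderings (frequencies, orderings of median times,
modal position classes) should be compared, not absolute rates.

## Problem sizes and determinism

All randomness flows through `GeneratorConfig.seed` via
`numpy.random.default_rng`; identical configurations give bit-identical
outputs, and the CLI `demo` writes byte-identical CSVs under a fixed
seed. Cohort computations use 20 replicate follicles with 4 repeats per
position and 5% multiplicative noise, and 100-curve cohorts for
single-position recovery — sizes chosen so Monte-Carlo error is well
inside the tolerances being checked while the whole chain stays
desk-scale. The reproduction script (`scripts/acceptance.py`) derives
per-quantity sub-seeds deterministically from its single `--seed`.

## Limitations

The generator emulates geometry, contact mechanics and noise, not
optics: there is no PSF, no photobleaching, no segmentation ambiguity,
and phantoms contain exactly one follicle. The contact model assumes a
flat, homogeneous, purely elastic half-space within the 50 nm window —
substrate effects, adhesion and viscoelasticity beyond the diagnostic
preset are out of scope, as are vendor binary formats and
tilt/virtual-deflection corrections. Passing tests therefore
demonstrate the correctness and statistical behaviour of the analysis
chain under the stated forward models, not the biological accuracy of
any preset; on real data the presets play no role and only the analysis
path is exercised.
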