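# Methods

This note records the models, parameter choices, numerical conventions,
and known limitations of each analysis stage, and what the synthetic
phantoms do and do not establish about performance on real micrographs.

## Stain deconvolution

Transmitted-light staining is modeled by the Beer–Lambert law with
base-10 logarithms: `OD_c = −log10((I_c + ε)/(I0_c + ε))` with `ε = 1`
intensity count, so zero intensity maps to the finite cap
`log10(I0 + 1)` instead of diverging. `I0` defaults to the dtype channel
maximum (255 for 8-bit) and is configurable; no background calibration
beyond that is attempted. The phantom generator applies the exact
inverse transform (including the ε offset), which is why the round trip
closes to machine precision.

With three dyes and three channels the mixture `OD = Cᵀd` is square, so
unmixing is an exact per-pixel linear solve rather than non-negative
least squares. Physically meaningless negative densities are clipped to
zero afterwards, and the fraction of affected pixels (`clip_fraction`)
is always reported — clipping silently would hide model misfit. The
built-in stain matrix is fixed (rows: trichrome red, trichrome blue,
counterstain; unit-norm within 10⁻³); estimating matrices from images
(Macenko/NMF style) is deliberately out of scope.

Collagen positivity requires the blue density to exceed a threshold
(default 0.15, configurable) *and* to be the arg-max stain at the pixel.
The second condition prevents red/blue bleed-through from being counted
twice. The tissue mask defaults to summed OD > 0.05, which excludes
blank background. Area fraction is the headline collagen metric; mean
blue density is also emitted since the underlying measurement convention
(area vs density) is a free choice.

## IF quantification

Channel intensities are normalized to [0, 1] by the dtype maximum before
any thresholding, so fixed thresholds are scale-meaningful. The DAPI
threshold is Otsu's between-class-variance maximizer on a 256-bin
histogram over [0, 1]; it is implemented directly (vectorized cumulative
moments) so that it provably equals an exhaustive scan over all 255 bin
cuts, which the tests verify against an independent brute-force oracle.
A constant channel has no meaningful threshold and is an error.

Conventions chosen where a written protocol is ambiguous, all exposed in
config:

* marker threshold exactly 0.30 with a strict `>` (a pixel at 0.30 is
  background);
* nucleus size filter inclusive (area ≥ 15 px counts);
* connectivity 8 for all component labeling;
* the GFP⁺ object count uses the same size filter as DAPI (symmetric
  debris rejection);
* touching nuclei are *not* watershed-split — raw thresholded components
  are counted, favoring procedural fidelity over segmentation accuracy;
* area-per-cell with zero nuclei is an error, never a silent 0.

## Clonal analysis

Each reporter color channel is thresholded (fixed 0.30) and labeled
independently, then pooled: in a stochastic multicolor reporter the
color *is* the clone identity, so cross-channel merging would conflate
distinct clones. The clone/single-cell boundary is area ≥ 2000 px,
inclusive, mirroring the inclusive nucleus rule. Border-touching
components are not excluded (no exclusion flag is asserted by default).

Group comparisons: one-way fixed-effects ANOVA computed from the
standard sums of squares. Zero within-group variance with non-zero
between-group variance yields F = ∞ and p reported at a documented floor
(10⁻³⁰⁰) rather than an exact 0. Post hoc options are Tukey HSD
(studentized range, via `scipy.stats.tukey_hsd`) and pairwise t tests
with Benjamini–Hochberg adjustment; both are provided because either is
defensible, with Tukey the default. Dispersion is reported as SEM and
the nominal significance level is 0.05.

## Fiber architecture

**Orientation field.** Per-pixel structure tensor (Gaussian scale σ = 2
px, `nearest` boundary mode so image borders do not fabricate edges).
The local fiber axis is the minor eigenvector of the smoothed gradient
outer product, computed in closed form as
`θ = ½·atan2(2J_rc, J_rr − J_cc)` and mapped to the mathematical
convention (counter-clockwise from +x, y up), wrapped to [0, π).
Coherence `(λ₁−λ₂)/(λ₁+λ₂)` (0/0 → 0) gates which pixels contribute.
This is a per-pixel substitute for per-fiber curvelet extraction: it
feeds the same downstream alignment statistics but does not measure
fiber length, width, or curvature, and per-fiber metrics are therefore
not emitted.

**Coherence cutoff 0.65 (default).** Calibration on fiber phantoms
showed that a permissive cutoff (0.2) admits pixels where
differently-oriented fibers cross or blur; their intermediate angles
bias the alignment coefficient downward by up to ~0.07 at high
concentration. At 0.65 the recovered R̄ tracks the von Mises population
value within ~0.03 across κ ∈ {0, 1, 4} under the validation conditions
below while still retaining tens of thousands of angle samples per
image. The cutoff is configurable.

**Circular statistics.** Fibers are axial (defined modulo π), so angles
are doubled onto the circle before any statistic; this is stated
prominently because it changes R̄. The Rayleigh test uses `z = nR̄²`
with the standard finite-n series approximation for p, clipped to
(0, 1], and requires n ≥ 4. Under uniformity the sample R̄ has a
positive finite-sample bias ≈ 0.89/√n; validation therefore pools angle
samples across replicate phantoms before computing R̄ when comparing to
the population (Bessel-ratio) expectation.

**PCA.** Features are centered and scaled to unit sample variance
(correlation-matrix PCA, the `prcomp(scale.=TRUE)` convention).
Components are ordered by decreasing eigenvalue with a deterministic
sign convention (largest-magnitude loading positive). Zero-variance
features are rejected by name rather than silently dropped.

**Box counting.** Grid origin fixed at (0, 0), box sizes powers of two
by default, image padded with background to a multiple of each size;
N(s) counts boxes containing any foreground. D is the least-squares
slope of log N vs log(1/s) and the fit R² is reported; at least 4 sizes
are required. The Sierpinski validation pattern uses the binomial
(bit-AND) construction on a 2^depth grid, for which N(s) = 3^(depth−k)
at s = 2^k exactly, so the fit recovers log 3/log 2 to floating point.

## Phantoms: what they establish

The generators emulate the *quantification-relevant* structure of real
data — known density planes under the exact forward optics, exact
object counts/areas with guaranteed component separation (placement
enforces ≥ 2 px Euclidean margins so 8-connected labeling cannot merge
objects), controlled von Mises axial orientation, analytic fractal sets
— plus optional additive Gaussian noise. They deliberately do not model
confocal point-spread functions, uneven illumination, chromatic
aberration, stain variability between batches, overlapping nuclei, or
tissue autofluorescence. Passing phantom recovery therefore shows the
*computations* are correct and calibrated, not that the fixed
thresholds are optimal for any particular microscope or stain lot.

Placement is rejection sampling with a hard cap of 10,000 attempts;
hitting the cap raises an error reporting the achieved count, never a
silent shortfall. Identical `(kind, size, seed, params)` produce
bit-identical phantoms.

Validation problem sizes were chosen once as a realistic resolvable-
fiber regime and are used unchanged everywhere: fiber calibration uses
1024² px phantoms with 800 fibers of length 70 px (sparse enough that
crossings are rare at the tensor scale, dense enough that the κ = 0
finite-sample bias stays small); IF and clone recovery use 50 phantoms
of 256²/512² px; the deconvolution round trip uses 1000 random density
vectors.

## Pipeline

The demo batch is 3 groups × 4 assays = 12 phantoms with group-graded
effect sizes (collagen fraction 0.15/0.30/0.45; fiber κ 0.5/2/8), so
group orderings are visible in the summary output. With one image per
assay per group the per-assay ANOVA is skipped (the skip rule for
under-filled cells); `group_timecourse` performs per-timepoint ANOVA +
post hoc on real batches and is tested separately. Timepoints are tested
independently without cross-timepoint correction, matching common
practice; a Benjamini–Hochberg flag across the timepoint family is
available. All stages are deterministic given config + inputs; the demo
reproduces byte-identical CSVs under a fixed seed.

## Known limitations

* Orientation estimates are per-pixel, so R̄ is an area-weighted (not
  fiber-count-weighted) statistic; long fibers contribute more samples.
* The structure-tensor front end degrades when fiber spacing approaches
  the tensor scale σ; dense mats of crossing fibers bias R̄ downward.
* Otsu thresholding assumes a bimodal histogram; on nearly-empty
  channels it will split noise.
* Clone identity assumes one color per clone; same-color clones that
  touch are merged by connectivity.
* Phantom geometry is in abstract pixel units; no physical pixel pitch
  or magnification is modeled.
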