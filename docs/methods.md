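# Methods

## Secretome track

### Model of the data

An experiment is a proteins × samples abundance matrix with samples
labelled by condition (`CTR`, `FSH`, `hCG`, `FSH_hCG`) × analytical
replicate (1–3). Missingness is explicit (NaN, never zero): a protein
undetected in a whole condition is informative — it lands in the
exclusive class of the Venn partition — and must not enter the
quantitative comparison as a zero.

### Identification filter and Venn partition

Proteins identified by at least two unique peptides are retained (k is
configurable). A protein counts as "identified in a condition" when it
has at least one observed value in at least one replicate of that
condition — the most permissive reading, matching the qualitative intent
of an identification list. Two identification lists are partitioned into
common, treatment-only and control-only sets; the three sets are
disjoint by construction and their union is the union of the inputs.

### Top-3 quantification

Protein abundance per sample is the mean of the three largest
non-missing peptide precursor areas. With k < 3 observed peptides the
mean of those k is used (the common top-N convention); zero observed
peptides propagate as missing.

### Quantile normalization with missing values

The reference distribution is the mean of the per-sample sorted value
vectors. Each sample's observed values are ranked and replaced by the
reference quantile at their rank, with ties receiving the mean of the
tied reference quantiles. A sample with n observed values uses the
reference linearly interpolated onto n equally spaced probability
points; with complete data this reduces exactly to the classical
equal-length algorithm, and the transform is idempotent.

**Limitation** (verified by simulation): quantile normalization assumes
near-identical sample distributions. A differential protein sitting at
an extreme of the abundance distribution has its fold change compressed,
because the reference tail averages spiked and unspiked column extremes
— a mid-abundance 3× spike-in is recovered to within ±0.1 of log2(3) at
5% replicate CV, whereas a top-rank spike can be biased low by several
tenths. Interpretation of fold changes for the very most abundant
proteins should account for this.

### Fold change and calls

log2 FC = log2(mean over observed treatment replicates / mean over
observed control replicates), computed after normalization. Proteins
entirely missing in either condition are excluded (they belong to the
Venn track); nonpositive means are excluded with a warning. Calls use
strict inequalities: UP iff log2 FC > 1.5, DOWN iff log2 FC < −1.5,
else NS. The 1.5 threshold applies on the log2 scale — the bundled
tables' magnitudes (up to 5.5) only make sense under that reading.

### Clustergram

Rows restricted to proteins quantified in all samples are
log-transformed and autoscaled, z = (log x − row mean)/row SD; the log
base is immaterial after scaling (natural log used), zero-variance rows
are dropped with a warning, and nonpositive values are an error naming
the protein. Rows and columns are clustered agglomeratively
(scipy.cluster.hierarchy; euclidean distance with average linkage by
default, ward/complete and correlation available). Trees export to
Newick.

### Over-representation analysis

One-sided upper-tail hypergeometric test per pathway — the standard
over-representation model; p = P(X ≥ found) with X ~
Hypergeom(|background|, |pathway|, |query|) — with Benjamini–Hochberg
FDR across pathways (Bonferroni available). The background defaults to
the union of GMT members, but supplying the experiment's identified
universe is recommended: published "entities total" columns depend on
the annotation release and are not reproducible from a local GMT.

## Fiber track

### What the generator emulates

Synthetic filament images are sums of straight segments with a Gaussian
cross-section (default FWHM-like width 3 px, intensity 100 over
background 10, Gaussian read noise SD 5), centered uniformly over the
image. Orientations are axial (π-periodic) von Mises: an angle is drawn
on the doubled circle with concentration κ and halved, so κ=0 is exactly
uniform and large κ concentrates around the mean axis. Segment length
defaults to half the smaller image dimension. Not emulated: fiber
curvature, branching, point-spread optics, depth structure, or
intensity variation between fibers — so passing tests demonstrate the
estimators respond correctly to orientation order, not that they are
calibrated for any particular microscope.

### Spectral metrics

Each ROI (100×100 px, top-left-anchored, half-open) is mean-subtracted,
Hann-windowed by default (edge-leakage suppression; Parseval checks run
unwindowed, where total power = N²·variance holds to 1e-8 relative),
and 2D-FFT transformed; power = |F|²/N, DC-centered.

- *Amplitude*: power in the 0.02–0.30 cycles/pixel annulus is binned
  into 36 angular bins over [0, π) (5° resolution) and normalized;
  amplitude is the magnitude of the second circular harmonic
  |Σ p(θ)e^{2iθ}| — exactly 0 for a uniform profile, 1 for a delta.
  The radial band excludes DC/illumination gradients below 0.02 and the
  noise-dominated region above 0.30. Orientation is half the harmonic's
  argument, rotated by π/2 to map the spectral ridge back to the fiber
  axis.
- *Eccentricity*: the DC bin is zeroed, power below its 0.75 quantile is
  zeroed (stabilizes the moments against the noise floor), and the
  second central moments of the remaining power define an inertia
  ellipse with semi-axes a ≥ b; eccentricity = √(1 − b²/a²).
- *Intensity*: mean ROI pixel value. A constant ROI yields
  intensity only; amplitude, orientation and eccentricity are NaN.

### Estimator floors near isotropy

Both anisotropy metrics are magnitudes and therefore positively biased
at the isotropic point. With 200 fibers on a 256² image, the 20-seed
mean per-ROI amplitude at κ=0 is ≈ 0.17 (the |mean| of a few dozen
random 2θ-phasors), rising to ≈ 0.65 at κ=2 and ≈ 0.84 at κ=8; the mean
eccentricity of pure-noise ROIs is ≈ 0.27, versus ≈ 0.96 for aligned
fibers, because √(1 − b²/a²) amplifies small speckle anisotropy. The
metrics are ordinal measures of orientation order, not absolute zeros;
group comparisons (the intended use) are unaffected, and the κ=0 vs κ=8
discrimination test detects the difference at Bonferroni p < 0.05 in
effectively every repetition.

Amplitude and eccentricity are invariant under affine intensity
rescaling of the ROI (mean subtraction plus profile normalization);
rotating an aligned image rotates the recovered axis equivariantly
within one angular bin while leaving amplitude within ±0.05.

## Group statistics

One-way ANOVA is computed from the between/within sums of squares
directly (cross-checked against scipy.stats.f_oneway), which lets
degenerate inputs have defined answers: equal group means give F = 0,
p = 1; zero within-group variance with unequal means is reported as the
limiting F = ∞, p = 0 with a flag. Post hoc comparisons are pooled-
variance two-sample t-tests on all unordered pairs (Welch optional)
with p multiplied by the number of comparisons performed, capped at 1;
pairs involving a singleton group are skipped with a flag. Medians come
with either a seeded percentile-bootstrap interval (B = 2000 default) or
the distribution-free order-statistic interval (coverage ≥ level by the
binomial argument); n < 3 returns the data range, flagged. The unit of
analysis pools ROI values within a condition; aggregating to image
level first is available and more conservative. Both median-based and
mean ± SD summaries are emitted.

## Problem sizes and determinism

Simulation-based tests use 100–500 proteins, 256²–512×256-pixel images,
20 seeds for monotonicity means, 100 repetitions for the discrimination
rate, 500–2000 replicates for coverage/type-I calibration — sizes at
which the binomial/coverage tolerances in the tests are meaningful.
Every stochastic routine takes an explicit seed and owns its RNG stream;
reruns with the same configuration are byte-identical (the CLI embeds a
config hash in its outputs).

## Known limitations

- Printed pathway-enrichment p/FDR values from annotation-service
  releases are not reproducible from a local GMT; the package reproduces
  the statistic, not the release.
- Quantile normalization compresses extreme-tail fold changes (above).
- Anisotropy metrics have positive floors near isotropy (above).
- No mixed-effects handling of ROI-within-image nesting; image-level
  averaging is the offered alternative.
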