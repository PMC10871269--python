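# Methods

This note documents the models, estimators and numerical choices behind
metkit, the assumptions they make, and what the synthetic-data tests do
and do not demonstrate about real data.

## Synthetic image model

A nucleus is a disk of radius *r* (default 24 px, ~1.2 µm at the 0.05
µm/px default pixel size) in a square field. Its expected photon count
is split between a uniform diffuse pool and `puncta_count` isotropic
2-D Gaussian puncta of width `psf_sigma` (default 2 px), the standard
PSF-limited approximation for sub-diffraction condensates; real puncta
shapes and sizes vary, and real condensates are 3-D objects sampled by
a finite PSF, neither of which is modelled. Puncta centres are uniform
in a disk of radius r − 2·psf_sigma so essentially all punctum mass
stays inside the mask (candidates outside that disk are rejected and
resampled). Noise is Poisson shot noise on the expected image plus
additive Gaussian read noise, then a detector-style clamp at zero so
that rendered images satisfy the segmenter's nonnegativity contract.
Not modelled: depth-dependent aberration, Airyscan deconvolution
artefacts, autofluorescence structure, or cell-to-cell expression
variability beyond what the caller scripts inject.

Two-channel images share one nucleus geometry; `shared_puncta` reuses
one set of punctum positions in both channels while shot/read noise
stay independent, `independent` redraws positions per channel. This is
the minimal structure needed to give pixelwise Pearson correlation a
known sign and approximate magnitude; it does not emulate chromatic
shift or differing PSFs between channels.

Dot stacks place a single dominant 3-D Gaussian dot in the marker
channel (in-plane width `psf_sigma`, axial width 1 plane) and a GFP
punctum displaced by a known in-plane offset in the dot's z-plane,
with the diffuse nuclear pool spread evenly across planes. The default
stack is 14 planes at 0.4 µm (axial span 5.2 µm); the plane count is a
free parameter.

Default intensity scale (2×10⁵ expected photons per nucleus over
~1800 px, background 2 photons/px, read noise SD 1) gives a diffuse
per-pixel SNR ≳ 10, representative of a well-exposed confocal image;
all statistics in the package are intensity-scale covariant or
invariant, so the absolute scale matters only for noise levels.

## Segmentation

Gaussian smoothing (default σ = 2 px) → Otsu threshold → hole filling
→ 8-connected labelling → border-region removal → area filter
(min 100 px; max defaults to 10× the median candidate area), with an
optional distance-transform watershed for touching nuclei. One
departure from plain Otsu: the smoothed image is first clipped at its
95th percentile. Bright puncta otherwise dominate the histogram and
the threshold isolates puncta instead of nuclei; the clip removes
their leverage while leaving the background/nucleus separation intact
(puncta occupy far less than 5% of the field). Quantile and Otsu are
both scale-equivariant, so segmentation is invariant under a positive
global rescaling of the image. Border-touching nuclei are discarded
because their pixel samples are censored. Background is the mean pixel
intensity of unlabelled-cell images; corrected intensities are raw
minus background, and negative values are kept — clipping them would
bias the variance and hence CV/Fano.

## Dispersion statistics

Per nucleus: mean, SD and variance of corrected intensities (unbiased
n−1 variance), CV = SD/mean, Fano = variance/mean. The mean must be
positive; a non-positive corrected mean indicates a background estimate
larger than the signal and is an error rather than a silent NaN.
Whether variance should be computed on raw or background-subtracted
pixels is ambiguous in general practice; corrected-everywhere is used
for internal consistency (background subtraction shifts the mean but
not the variance, so Fano values are reported in corrected-intensity
units). Statistics are computed per nucleus and then aggregated across
nuclei — pixel pooling across nuclei would conflate within- and
between-cell variability. Fano normalization divides every condition,
the reference included, by the mean Fano of the reference
(free-fluorophore) condition, making the reference mean exactly 1 by
construction.

Passing the synthetic monotonicity tests (CV and Fano strictly
increasing in the planted punctate fraction) shows the estimator chain
orders punctateness correctly under this generative model; it does not
calibrate absolute Fano values against any particular microscope.

## Colocalization

Pearson product-moment correlation of paired corrected intensities
inside one nucleus mask (identical pixel order, n ≥ 3, both channels
with nonzero variance). Pearson r is invariant under positive-slope
affine transforms of either channel, so background subtraction and
detector gain do not affect it. Alternatives such as Manders
coefficients are out of scope.

## Dot-centered averaging

The dot detector takes the global maximum of the per-plane
Gaussian-smoothed stack (σ = 1 px); ties resolve to the lowest z, then
smallest (row, col). "Highest dot intensity" is interpreted as the
peak of the smoothed stack rather than an integrated spot intensity.
A detection requires the peak to exceed (1 + min_prominence) × median
of the smoothed stack (default prominence 0.5); otherwise a NoDotFound
error is raised rather than returning a spurious maximum. Alignment is
integer-pixel — consistent with averaging hundreds of cells where
sub-pixel jitter averages out; cells whose window would leave the
field are dropped and counted, not padded, since padding would dilute
the average with artificial values. The default window halfwidth
(20 px) spans ~2 µm at the default pixel size. Line profiles use
nearest-pixel sampling at signed offsets through the window center.

## FRAP

Acquisition model: frames every 3 s for 270 s, bleaching after three
pre-bleach frames (the bleach pulse itself is instrument detail and is
not modelled). Traces are normalized to percent of the pre-bleach mean
and averaged pointwise. The post-bleach recovery is fitted by
least squares to the single-exponential
I(t) = B + (A − B)(1 − e^(−kt)) with t re-zeroed at the first
post-bleach frame. t½ = ln 2/k equals the time to reach halfway
between floor B and plateau A, which makes the definition testable in
closed form. Initialization: B₀ = first post-bleach value, A₀ = last
value, k₀ from the linearly interpolated half-crossing time; k is
bounded to (10⁻⁵, 10) s⁻¹. A fitted amplitude A − B below
`min_recovery` (default 2 percentage points) raises NoRecovery instead
of returning an unstable half-time. Single-exponential recovery is an
empirical summary, not a mechanistic reaction–diffusion model; an
immobile fraction is captured by A < 100 but binding kinetics and
bleach-spot geometry are not.

## MTAC proximity calling

Counts per NDR and replicate are modelled as negative binomial with
variance μ + αμ². Counts are normalized by library size to a common
scale (input-DNA normalization is represented abstractly by these
per-replicate sizes). The log₂ fold change is log₂ of the ratio of
condition means, with a 0.5 pseudocount added to both means when
either is zero. The Wald statistic divides log₂FC by a delta-method SE
propagated from the NB variance through the log of each condition
mean; p-values are two-sided normal.

Dispersion: the per-NDR method-of-moments estimate from biological
duplicates has a single degree of freedom and routinely collapses to
zero, which would inflate the Wald statistic. The test therefore
floors the per-NDR estimate at a pooled trend — the mean of
method-of-moments estimates across the full NDR set (negative values
included so the average stays unbiased) — and at α_min = 0.01. This
moderation keeps the null rejection rate at the nominal 5% level in
simulation at 2+2 replicates while retaining per-NDR sensitivity to
genuinely overdispersed regions. With fewer than two replicates per
condition, only the pooled value is used. This estimator is
deliberately simpler than DESeq2 (no shrinkage of fold changes, no
dispersion trend fitting) and will not match it numerically;
correctness is established by planted-truth recovery and calibration
simulations instead.

Multiple testing uses Benjamini–Hochberg across the full NDR set.
Classification is purely geometric and count-independent: trans for a
different chromosome; local for |NDR midpoint − VP| ≤ 30 kb (boundary
inclusive); far-cis beyond. Coordinates are BED-style 0-based
half-open; the VP is a single insertion coordinate. A proximity call
("significant") requires q < 0.05 and log₂FC > 0 — depletion is never
evidence of proximity.

## Reproducibility and problem sizes

Every generator takes an explicit integer seed; there is no hidden
global random state, and identical spec + seed gives bit-identical
output. The pipeline manifest records a config hash and per-file
content hashes, so end-to-end determinism is checkable byte-for-byte.

Simulation sizes used by the test suite were chosen to make the
statistical assertions sharp at desk scale: 10⁴ NDRs for the null
calibration of the NB test (binomial SE ≈ 0.002 on the rejection
rate), 10⁴–10⁵ pixels for Poisson-Fano and null-correlation checks,
50 nuclei per punctate level for the monotonicity suite, 100 repeats
for FRAP parameter recovery, and 25–40 cells per population for the
dot-averaging contrasts. The planted MTAC scenarios (two far-cis
promoter NDRs at +150/+310 kb from a chr7 viewpoint; three trans NDRs
on other chromosomes) use log₂FC 2.5 at baseline mean 200 with
dispersion 0.05 and duplicate libraries, a regime where the caller
should — and does — recover exactly the planted set.

## Known limitations

- Segmentation is 2-D and single-channel; nuclei are assumed roughly
  convex and non-overlapping (the watershed split is a convenience,
  not a tracking solution).
- Fano values depend on the intensity scale of the corrected pixels;
  only normalized Fano values are comparable across detectors.
- The dot detector assumes one dominant dot per stack; fields with
  multiple comparable dots return the first by the tie-break rule.
- The NB Wald test relies on a normal approximation of the log fold
  change; at very low counts (means ≲ 5) it is conservative rather
  than exact.
- Synthetic inputs validate estimator logic, not optics: passing these
  suites does not certify performance on images with aberrations,
  uneven illumination, or segmentation-resistant morphology.
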