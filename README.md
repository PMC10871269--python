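# metkit

Quantification of nuclear transcription-factor (TF) condensates and
their relation to chromatin, built for imaging studies of stress-response
TFs in budding yeast (e.g. the methionine-starvation regulators Met4 and
Met32). The package turns raw fluorescence images, FRAP time series, and
methylation count tables into the per-cell statistics such studies
report, and ships a synthetic-data module that generates every input
with known ground truth so each stage can be validated end to end.

## What it computes

**Puncta statistics.** Nuclei are segmented from a fluorescence image
(Gaussian smoothing → quantile-clipped Otsu threshold → hole filling →
connected components → area/border filters). For each nucleus with
background-corrected pixel intensities *x₁…xₙ* (background = mean
intensity of unlabelled cells):

- CV = s / x̄   (coefficient of variation; s uses the n−1 denominator)
- Fano = s² / x̄  (variance over mean; overdispersion ⇒ punctate signal)
- normalized Fano = Fano / mean Fano of a free-fluorophore reference,
  so the reference condition averages exactly 1.

A diffuse fluorophore pool under shot noise gives Fano ≈ 1 per photon
unit; condensate-forming TFs concentrate signal into puncta and push CV
and Fano up. Group contrasts use the two-tailed equal-variance Student
t-test.

**Colocalization.** For two co-expressed channels, the Pearson
correlation *r* of paired in-nucleus pixel intensities, per nucleus.

**Dot-centered averaging.** In two-channel z-stacks where a marker dot
(tetO/tetR-mCherry) tags a genomic locus, the dot is detected as the
global maximum of the smoothed stack, the GFP channel is reduced to 2-D
(same-z plane or maximum-intensity projection), windows are aligned on
the dot and averaged across cells, and a line profile is drawn through
the center. A central peak in the averaged image indicates that TF
puncta colocalize with the tagged locus.

**FRAP kinetics.** Traces are normalized to percent of the pre-bleach
mean, averaged, and the post-bleach recovery is fitted to
I(t) = B + (A − B)(1 − e^(−kt)). The half-recovery time is
t½ = ln 2 / k; the mobile fraction is (A − B)/(100 − B).

**MTAC proximity calling.** MTAC infers physical proximity between a
genomic viewpoint (VP) and nucleosome-depleted regions (NDRs) from
elevated methylation in a methyltransferase-targeted strain versus an
untargeted control. Per NDR, a negative-binomial Wald test (library-size
offsets, moment-based dispersion with a pooled floor) yields log₂ fold
change and p; Benjamini–Hochberg adjustment yields q; NDRs are classed
as local (same chromosome, ≤ 30 kb), far-cis (same chromosome, > 30 kb)
or trans (different chromosome). Proximity calls require q < 0.05 *and*
positive fold change.

## Worked example

```python
import numpy as np
from metkit.synthetic import NucleusImageSpec, gen_nucleus_image, FRAPSimSpec, gen_frap_traces
from metkit.segment import segment_nuclei, extract_pixels
from metkit.puncta import compute_stats, normalize_fano
from metkit.frap import normalize_trace, average_traces, fit_recovery

# per-nucleus Fano factors: free fluorophore vs a condensate-forming TF
fanos = {}
for name, pc, pf in [("free_gfp", 0, 0.0), ("condensate_tf", 4, 0.6)]:
    vals = []
    for seed in range(30):
        spec = NucleusImageSpec(puncta_count=pc, puncta_fraction=pf, seed=seed)
        img, mask, _ = gen_nucleus_image(spec)
        nucleus = segment_nuclei(img)[0]
        vals.append(compute_stats(extract_pixels(img, nucleus, spec.background_rate)).fano)
    fanos[name] = np.array(vals)
norm, ref = normalize_fano(fanos["condensate_tf"], fanos["free_gfp"])
print(f"free GFP mean normalized Fano: {np.mean(ref):.3f}")
print(f"condensate TF mean normalized Fano: {np.mean(norm):.2f}")

# FRAP: recover the half-time of a simulated condensate
spec = FRAPSimSpec(t_half_true=64.0, seed=7)
mean, sd = average_traces([normalize_trace(t) for t in gen_frap_traces(spec)])
fit = fit_recovery(mean)
print(f"t_half = {fit.t_half:.1f} s, mobile fraction = {fit.mobile_fraction:.2f}, floor = {fit.floor:.1f}%")
```

prints

```
free GFP mean normalized Fano: 1.000
condensate TF mean normalized Fano: 282.35
t_half = 63.8 s, mobile fraction = 0.90, floor = 39.9%
```

The free-fluorophore reference averages exactly 1 by construction; the
punctate condition is far more overdispersed. The FRAP fit recovers the
simulated 64 s half-time and 0.9 mobile fraction from ten noisy traces
sampled every 3 s for 270 s after three pre-bleach frames.

A command-line interface mirrors the library: `metkit simulate`,
`metkit segment`, `metkit puncta`, `metkit coloc`, `metkit dotalign`,
`metkit frap`, `metkit mtac-call`, and `metkit run` (several stages as
one reproducible bundle with a content-hash manifest). See
`metkit --help`.

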