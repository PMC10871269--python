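"""Per-nucleus dispersion statistics and two-channel colocalization.

Punctate (condensate-like) fluorophore distributions are quantified
without segmenting individual puncta: an uneven pixel-intensity
distribution inside a nucleus raises the coefficient of variation
(CV = SD / mean) and the Fano factor (variance / mean).  Because the
Fano factor carries intensity units, it is normalised against a free
fluorophore reference whose mean Fano is set to exactly 1.

Colocalization of two co-expressed channels is the Pearson correlation
of the paired in-nucleus pixel intensities, reported per nucleus.
Group differences use the classical two-sample equal-variance Student
t-test (two-tailed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .segment import PixelSample

__all__ = [
    "PunctaStats",
    "ColocResult",
    "compute_stats",
    "normalize_fano",
    "coloc_pearson",
    "compare_groups",
]


@dataclass
class PunctaStats:
    """Summary of one nucleus' corrected pixel intensities.

    ``fano_norm`` stays unset until :func:`normalize_fano` divides by a
    reference condition's mean Fano.
    """

    mean: float
    sd: float
    variance: float
    cv: float
    fano: float
    fano_norm: float | None = field(default=None)


@dataclass(frozen=True)
class ColocResult:
    r: float
    n_pixels: int


def compute_stats(sample: PixelSample) -> PunctaStats:
    """Mean, SD, variance (n-1 denominator), CV and Fano of one nucleus."""
    if sample.n < 2:
        raise ValueError(f"need at least 2 pixels, got {sample.n}")
    x = np.asarray(sample.corrected_intensities, dtype=float)
    mean = float(x.mean())
    if mean <= 0:
        raise ValueError(
            f"non-positive corrected mean ({mean:g}); check background estimate"
        )
    variance = float(x.var(ddof=1))
    sd = float(np.sqrt(variance))
    return PunctaStats(mean=mean, sd=sd, variance=variance, cv=sd / mean, fano=variance / mean)


def normalize_fano(
    condition_fanos: "Mapping[str, Sequence[float]] | Sequence[float]",
    reference_fanos: Sequence[float],
):
    """Divide all Fano values by the reference condition's mean Fano.

    The reference (free fluorophore) is normalised too, so its mean
    becomes exactly 1.  Returns ``(normalized_conditions,
    normalized_reference)`` preserving the input structure (mapping of
    arrays, or a single array).
    """
    ref = np.asarray(reference_fanos, dtype=float)
    if ref.size == 0:
        raise ValueError("reference_fanos must be nonempty")
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        raise ValueError(f"reference mean Fano must be positive, got {ref_mean:g}")
    if isinstance(condition_fanos, Mapping):
        norm_cond = {
            k: np.asarray(v, dtype=float) / ref_mean for k, v in condition_fanos.items()
        }
    else:
        norm_cond = np.asarray(condition_fanos, dtype=float) / ref_mean
    return norm_cond, ref / ref_mean


def coloc_pearson(sample_a: PixelSample, sample_b: PixelSample) -> ColocResult:
    """Pearson correlation of paired corrected intensities of one nucleus.

    Both samples must come from the same mask in identical pixel order.
    """
    if sample_a.n != sample_b.n:
        raise ValueError(f"mismatched pixel counts ({sample_a.n} vs {sample_b.n})")
    if sample_a.n < 3:
        raise ValueError("need at least 3 paired pixels")
    a = np.asarray(sample_a.corrected_intensities, dtype=float)
    b = np.asarray(sample_b.corrected_intensities, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a channel; correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    return ColocResult(r=r, n_pixels=sample_a.n)


def compare_groups(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed equal-variance Student t-test, df = nA + nB - 2.

    Degenerate zero-pooled-variance inputs follow the convention
    (t=0, p=1) for equal means and (±inf, p=0) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
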