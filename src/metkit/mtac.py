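"""MTAC chromatin-proximity calling.

MTAC (Methyltransferase Targeting-based chromosome Architecture
Capture) infers physical proximity to a genomic viewpoint (VP, the
locus carrying a LacO array that tethers LacI-M.CviPI) from elevated
GC methylation at nucleosome-depleted regions (NDRs) in a targeted
strain relative to an untargeted control strain.

Per NDR, methylation counts (targeted vs control replicates, with
library-size normalisation) are compared with a negative-binomial Wald
test; p-values are Benjamini-Hochberg adjusted across all NDRs; and
each NDR is geometrically classified relative to the VP as

* ``local``   — same chromosome, midpoint within 30 kb of the VP,
* ``far_cis`` — same chromosome, beyond 30 kb,
* ``trans``   — different chromosome.

An NDR is called proximal ("significant") when q < q_threshold **and**
the fold change is positive: only higher methylation in the targeted
strain is evidence of proximity.

The enrichment test is an intentionally simple from-scratch NB Wald
approximation (method-of-moments dispersion, delta-method standard
error, no shrinkage); it is not expected to match DESeq2 numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NDRRecord",
    "ViewPoint",
    "MTACCall",
    "classify_interaction",
    "test_enrichment",
    "adjust_fdr",
    "call_interactions",
    "volcano_table",
    "pooled_dispersion",
]

LOCAL_THRESHOLD_BP = 30_000
ALPHA_MIN = 0.01  # dispersion floor


@dataclass(frozen=True)
class ViewPoint:
    """Array insertion coordinate anchoring the tethered methyltransferase."""

    chrom: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("viewpoint position must be >= 0")


@dataclass
class NDRRecord:
    """One NDR with its methylation counts (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    counts_targeted: np.ndarray
    counts_control: np.ndarray
    library_sizes_targeted: np.ndarray | None = None
    library_sizes_control: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.chrom}:{self.start}-{self.end})")
        self.counts_targeted = np.asarray(self.counts_targeted, dtype=float)
        self.counts_control = np.asarray(self.counts_control, dtype=float)
        for c in (self.counts_targeted, self.counts_control):
            if c.ndim != 1 or len(c) < 1:
                raise ValueError("each condition needs >= 1 replicate")
            if np.any(c < 0) or np.any(c != np.floor(c)):
                raise ValueError("counts must be nonnegative integers")
        if self.library_sizes_targeted is None:
            self.library_sizes_targeted = np.ones_like(self.counts_targeted)
        else:
            self.library_sizes_targeted = np.asarray(self.library_sizes_targeted, dtype=float)
        if self.library_sizes_control is None:
            self.library_sizes_control = np.ones_like(self.counts_control)
        else:
            self.library_sizes_control = np.asarray(self.library_sizes_control, dtype=float)
        for s, c in (
            (self.library_sizes_targeted, self.counts_targeted),
            (self.library_sizes_control, self.counts_control),
        ):
            if s.shape != c.shape:
                raise ValueError("library sizes must match replicate count")
            if np.any(s <= 0):
                raise ValueError("library sizes must be positive")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class MTACCall:
    """Per-NDR enrichment result."""

    ndr: NDRRecord
    log2fc: float
    p: float
    q: float
    distance: float | None  # bp to VP; None across chromosomes
    klass: str  # local | far_cis | trans
    significant: bool


def classify_interaction(
    ndr: NDRRecord, vp: ViewPoint, local_threshold: int = LOCAL_THRESHOLD_BP
) -> str:
    """Geometric class of an NDR relative to the viewpoint.

    Different chromosome -> ``trans``; same chromosome with midpoint
    within ``local_threshold`` bp (inclusive) -> ``local``; otherwise
    ``far_cis``.  Independent of the counts.
    """
    if ndr.chrom != vp.chrom:
        return "trans"
    if abs(ndr.midpoint - vp.position) <= local_threshold:
        return "local"
    return "far_cis"


def _normalized_counts(counts: np.ndarray, sizes: np.ndarray, scale: float) -> np.ndarray:
    return counts * (scale / sizes)


def _moments_dispersion(y: np.ndarray) -> float | None:
    """Method-of-moments NB dispersion from normalised counts; None if <2 reps."""
    if len(y) < 2:
        return None
    m = y.mean()
    if m <= 0:
        return None
    v = y.var(ddof=1)
    return float((v - m) / m**2)


def pooled_dispersion(ndrs: Iterable[NDRRecord], alpha_min: float = ALPHA_MIN) -> float:
    """Mean method-of-moments dispersion across all NDRs and conditions.

    With few replicates the per-NDR moment estimator is extremely
    noisy (a single degree of freedom at biological duplicates);
    averaging over the whole NDR set gives a stable trend value.
    Negative per-NDR estimates (apparent underdispersion) are kept in
    the average so it stays unbiased; the result is floored at
    ``alpha_min``.
    """
    vals: list[float] = []
    for ndr in ndrs:
        scale = float(np.mean(np.r_[ndr.library_sizes_targeted, ndr.library_sizes_control]))
        for counts, sizes in (
            (ndr.counts_targeted, ndr.library_sizes_targeted),
            (ndr.counts_control, ndr.library_sizes_control),
        ):
            a = _moments_dispersion(_normalized_counts(counts, sizes, scale))
            if a is not None:
                vals.append(a)
    if not vals:
        return alpha_min
    return max(float(np.mean(vals)), alpha_min)


def test_enrichment(
    ndr: NDRRecord,
    alpha_min: float = ALPHA_MIN,
    pooled_alpha: float | None = None,
) -> tuple[float, float]:
    """Negative-binomial Wald test of targeted-vs-control enrichment.

    Counts are normalised by library size to a common scale; the log2
    fold change is ``log2(mean targeted / mean control)`` with a 0.5
    pseudocount added to both condition means when either is zero.  The
    Wald statistic divides the log2 fold change by a delta-method
    standard error derived from the NB variance ``mu + alpha mu^2``.
    The dispersion is the per-NDR method-of-moments estimate floored
    at ``pooled_alpha`` (a trend value averaged over the full NDR set,
    see :func:`pooled_dispersion`) and at ``alpha_min``; the floor
    keeps the test calibrated when the per-NDR estimate collapses at
    small replicate counts.  With fewer than two replicates per
    condition only the pooled value is used.  Two-sided normal
    p-value.

    Returns ``(log2fc, p)``.  Zero counts in both conditions are
    uninformative and return ``(0.0, 1.0)``.
    """
    scale = float(np.mean(np.r_[ndr.library_sizes_targeted, ndr.library_sizes_control]))
    yt = _normalized_counts(ndr.counts_targeted, ndr.library_sizes_targeted, scale)
    yc = _normalized_counts(ndr.counts_control, ndr.library_sizes_control, scale)
    mt, mc = float(yt.mean()), float(yc.mean())
    if mt == 0.0 and mc == 0.0:
        return 0.0, 1.0

    if mt == 0.0 or mc == 0.0:
        lt, lc = mt + 0.5, mc + 0.5
    else:
        lt, lc = mt, mc
    log2fc = float(np.log2(lt / lc))

    disps = [d for d in (_moments_dispersion(yt), _moments_dispersion(yc)) if d is not None]
    floor = max(pooled_alpha if pooled_alpha is not None else 0.0, alpha_min)
    alpha = max(float(np.mean(disps)), floor) if disps else floor

    ln2sq = np.log(2.0) ** 2
    var_l2 = 0.0
    for m_obs, mean_used, sizes in (
        (mt, lt, ndr.library_sizes_targeted),
        (mc, lc, ndr.library_sizes_control),
    ):
        n = len(sizes)
        mu = max(m_obs, 0.5)  # rate floor keeps the SE finite at zero counts
        # Var(normalised count) = mu * scale / s_i + alpha * mu^2 per replicate
        var_mean = float(np.sum(mu * scale / sizes + alpha * mu**2)) / n**2
        var_l2 += var_mean / (mean_used**2 * ln2sq)
    se = float(np.sqrt(var_l2))
    if se == 0.0:
        return log2fc, 1.0 if log2fc == 0.0 else 0.0
    z = log2fc / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return log2fc, p


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_interactions(
    ndrs: Sequence[NDRRecord],
    vp: ViewPoint,
    q_threshold: float = 0.05,
    local_threshold: int = LOCAL_THRESHOLD_BP,
    alpha_min: float = ALPHA_MIN,
) -> list[MTACCall]:
    """Full proximity caller: test every NDR, BH-adjust, classify.

    ``significant`` requires q < q_threshold AND log2fc > 0 (only
    higher-in-targeted methylation indicates proximity to the VP).
    """
    if len(ndrs) == 0:
        raise ValueError("no NDRs supplied")
    pool = pooled_dispersion(ndrs, alpha_min)
    results = [test_enrichment(n, alpha_min=alpha_min, pooled_alpha=pool) for n in ndrs]
    qvals = adjust_fdr([p for _, p in results])
    calls = []
    for ndr, (lfc, p), q in zip(ndrs, results, qvals):
        klass = classify_interaction(ndr, vp, local_threshold)
        dist = abs(ndr.midpoint - vp.position) if klass != "trans" else None
        calls.append(
            MTACCall(
                ndr=ndr,
                log2fc=lfc,
                p=p,
                q=float(q),
                distance=dist,
                klass=klass,
                significant=bool(q < q_threshold and lfc > 0),
            )
        )
    return calls


def volcano_table(calls: Sequence[MTACCall]) -> pd.DataFrame:
    """Flat per-NDR result table (volcano-plot input), sorted by q."""
    cols = ["chrom", "start", "end", "distance", "klass", "log2fc", "p", "q", "significant"]
    if not calls:
        return pd.DataFrame(columns=cols)
    rows = [
        {
            "chrom": c.ndr.chrom,
            "start": c.ndr.start,
            "end": c.ndr.end,
            "distance": c.distance,
            "klass": c.klass,
            "log2fc": c.log2fc,
            "p": c.p,
            "q": c.q,
            "significant": c.significant,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=cols).sort_values("q", kind="stable").reset_index(drop=True)
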