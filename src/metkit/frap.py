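"""FRAP (fluorescence recovery after photobleaching) kinetics.

A FRAP experiment monitors a bleached spot at fixed intervals (here 3 s
over 270 s by default, with bleaching after three pre-bleach frames).
Each trace is normalised to percent of its pre-bleach mean, traces are
averaged pointwise, and the averaged post-bleach recovery is fitted to a
single-exponential

    I(t) = B + (A - B) * (1 - exp(-k t)),

with ``t`` re-zeroed at the first post-bleach frame.  The half-recovery
time is ``t_half = ln(2) / k``, i.e. the time to reach halfway between
the post-bleach floor ``B`` and the plateau ``A``.  The mobile fraction
is ``(A - B) / (100 - B)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FRAPTrace",
    "FRAPFit",
    "NoRecoveryError",
    "normalize_trace",
    "average_traces",
    "fit_recovery",
]

_K_BOUNDS = (1e-5, 10.0)  # 1/s


class NoRecoveryError(ValueError):
    """Post-bleach signal never rises above the noise floor."""


@dataclass
class FRAPTrace:
    """One bleach-recovery time series.

    ``times`` must be uniformly spaced and strictly increasing; the
    first ``n_prebleach`` frames precede the bleach.  ``normalized`` is
    filled by :func:`normalize_trace` (percent of pre-bleach mean).
    """

    times: np.ndarray
    intensities: np.ndarray
    n_prebleach: int = 3
    normalized: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must be 1-D and congruent")
        if len(self.times) < 2:
            raise ValueError("trace needs at least two frames")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("times must be uniformly spaced")
        if not (1 <= self.n_prebleach < len(self.times)):
            raise ValueError("n_prebleach must be >= 1 and < trace length")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class FRAPFit:
    """Fitted single-exponential recovery parameters (percent units)."""

    floor: float  # B, post-bleach intercept
    plateau: float  # A
    k: float  # 1/s
    t_half: float  # ln 2 / k, seconds
    mobile_fraction: float  # (A - B) / (100 - B)
    rss: float


def recovery_model(t: np.ndarray, floor: float, plateau: float, k: float) -> np.ndarray:
    """Single-exponential recovery ``B + (A - B)(1 - exp(-kt))``."""
    t = np.asarray(t, dtype=float)
    return floor + (plateau - floor) * (1.0 - np.exp(-k * t))


def normalize_trace(trace: FRAPTrace) -> FRAPTrace:
    """Normalise to percent of the pre-bleach mean.

    ``normalized[i] = 100 * intensities[i] / mean(first n_prebleach)``.
    Idempotent: a trace already in percent units (pre-bleach mean 100)
    maps onto itself.
    """
    pre = float(np.mean(trace.intensities[: trace.n_prebleach]))
    if pre <= 0:
        raise ValueError(f"non-positive pre-bleach mean ({pre:g}); cannot normalise")
    return replace(trace, normalized=100.0 * trace.intensities / pre)


def average_traces(traces: list[FRAPTrace]) -> tuple[FRAPTrace, np.ndarray]:
    """Pointwise mean and sample SD of normalised traces.

    All traces must share the same time grid and pre-bleach count.  The
    returned mean trace carries the averaged values both as intensities
    and as ``normalized``; the SD uses the n-1 denominator (0 for a
    single trace).
    """
    if not traces:
        raise ValueError("no traces to average")
    ref = traces[0]
    mat = []
    for tr in traces:
        if tr.normalized is None:
            raise ValueError("traces must be normalised first (normalize_trace)")
        if tr.times.shape != ref.times.shape or not np.allclose(tr.times, ref.times):
            raise ValueError("mismatched time grids")
        if tr.n_prebleach != ref.n_prebleach:
            raise ValueError("mismatched n_prebleach")
        mat.append(tr.normalized)
    stack = np.vstack(mat)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(traces) > 1 else np.zeros_like(mean)
    out = FRAPTrace(ref.times.copy(), mean.copy(), ref.n_prebleach, normalized=mean)
    return out, sd


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    b0 = float(y[0])
    a0 = float(y[-1])
    half = (a0 + b0) / 2.0
    above = np.nonzero(y >= half)[0]
    k0 = np.log(2.0) / max(t[-1] / 2.0, 1e-9)
    for i in above:
        if i == 0:
            break
        # linear interpolation of the crossing time between frames i-1, i
        y0, y1 = y[i - 1], y[i]
        if y1 > y0:
            tc = t[i - 1] + (half - y0) / (y1 - y0) * (t[i] - t[i - 1])
            if tc > 0:
                k0 = np.log(2.0) / tc
            break
    k0 = float(np.clip(k0, *_K_BOUNDS))
    return b0, a0, k0


def fit_recovery(mean_trace: FRAPTrace, min_recovery: float = 2.0) -> FRAPFit:
    """Fit the post-bleach portion of a normalised trace.

    Parameters
    ----------
    mean_trace
        Normalised (percent-of-pre-bleach) trace, typically the output
        of :func:`average_traces`.  At least 10 post-bleach points.
    min_recovery
        Minimum plateau-minus-floor amplitude, in percent, below which
        the trace is declared flat and :class:`NoRecoveryError` is
        raised instead of an unstable half-time.
    """
    if mean_trace.normalized is None:
        raise ValueError("trace must be normalised before fitting")
    post = slice(mean_trace.n_prebleach, None)
    t = mean_trace.times[post] - mean_trace.times[mean_trace.n_prebleach]
    y = mean_trace.normalized[post]
    if len(t) < 10:
        raise ValueError(f"need >= 10 post-bleach points, got {len(t)}")

    b0, a0, k0 = _initial_guess(t, y)
    if a0 - b0 < min_recovery:
        raise NoRecoveryError(
            f"recovery amplitude {a0 - b0:.3g}% below noise floor {min_recovery:g}%"
        )
    lo = [-50.0, -50.0, _K_BOUNDS[0]]
    hi = [200.0, 200.0, _K_BOUNDS[1]]
    p0 = [np.clip(b0, lo[0], hi[0]), np.clip(a0, lo[1], hi[1]), k0]
    try:
        popt, _ = curve_fit(recovery_model, t, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy non-convergence
        raise RuntimeError(
            f"recovery fit failed to converge (p0={p0}, n={len(t)}): {exc}"
        ) from exc
    floor, plateau, k = map(float, popt)
    if plateau - floor < min_recovery:
        raise NoRecoveryError(
            f"fitted amplitude {plateau - floor:.3g}% below noise floor"
        )
    resid = y - recovery_model(t, floor, plateau, k)
    return FRAPFit(
        floor=floor,
        plateau=plateau,
        k=k,
        t_half=float(np.log(2.0) / k),
        mobile_fraction=float((plateau - floor) / (100.0 - floor)),
        rss=float(np.sum(resid**2)),
    )
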