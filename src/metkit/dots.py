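"""Dot-centered image alignment and averaging (DotTracker procedure).

A bright marker dot (e.g. a tetO array bound by tetR-mCherry) labels a
genomic locus in one channel of a z-stack.  Per cell, the dot is
located as the global maximum of the Gaussian-smoothed stack, the
second channel is reduced to 2-D either at the dot's z-plane (same-z)
or by maximum-intensity projection (MIP), windows are aligned on the
dot at integer-pixel precision, averaged across cells, and profiled
along a line through the center.  A population whose puncta sit at the
dot produces an averaged image peaking at the center pixel; randomly
offset puncta average out to the diffuse background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "DotDetection",
    "DotAlignment",
    "LineProfile",
    "NoDotFoundError",
    "find_dot",
    "extract_second_channel",
    "align_and_average",
    "line_profile",
]


class NoDotFoundError(ValueError):
    """No voxel stands out of the smoothed stack by the required prominence."""


@dataclass(frozen=True)
class DotDetection:
    """Marker-dot coordinates: (x, y) in-plane pixels and the z plane."""

    x: int
    y: int
    z_index: int
    dot_intensity: float


@dataclass
class DotAlignment:
    """Population-averaged dot-centered window ((2w+1) square)."""

    window_halfwidth: int
    n_cells: int
    averaged_image: np.ndarray
    mode: Literal["same_z", "mip"] = "mip"
    n_dropped: int = 0


@dataclass
class LineProfile:
    """Intensity along a line through the window center (offset 0)."""

    offsets: np.ndarray
    intensities: np.ndarray
    peak_center_value: float


def find_dot(
    stack: np.ndarray, smoothing_sigma: float = 1.0, min_prominence: float = 0.5
) -> DotDetection:
    """Locate the dominant dot of a (Z, Y, X) stack.

    Each plane is Gaussian-smoothed in-plane; the detection is the
    global maximum over (z, y, x).  Ties resolve to the lowest z, then
    the smallest (row, col).  The maximum must exceed
    ``(1 + min_prominence) * median`` of the smoothed stack, otherwise
    :class:`NoDotFoundError` is raised.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a (Z, Y, X) stack with >= 1 plane")
    smoothed = ndimage.gaussian_filter(stack, sigma=(0.0, smoothing_sigma, smoothing_sigma))
    peak = float(smoothed.max())
    med = float(np.median(smoothed))
    if not peak > (1.0 + min_prominence) * med:
        raise NoDotFoundError(
            f"peak {peak:g} fails prominence gate (1+{min_prominence:g}) x median {med:g}"
        )
    z, y, x = np.unravel_index(int(np.argmax(smoothed)), smoothed.shape)
    return DotDetection(x=int(x), y=int(y), z_index=int(z), dot_intensity=peak)


def extract_second_channel(
    stack_gfp: np.ndarray, detection: DotDetection, mode: Literal["same_z", "mip"]
) -> np.ndarray:
    """Reduce the second channel to 2-D at the detected dot.

    ``same_z`` returns the plane at ``detection.z_index``; ``mip``
    returns the per-pixel maximum over all z.
    """
    stack_gfp = np.asarray(stack_gfp, dtype=float)
    if stack_gfp.ndim != 3:
        raise ValueError("expected a (Z, Y, X) stack")
    if not (0 <= detection.z_index < stack_gfp.shape[0]):
        raise ValueError("detection z_index outside the stack")
    if mode == "same_z":
        return stack_gfp[detection.z_index].copy()
    if mode == "mip":
        return stack_gfp.max(axis=0)
    raise ValueError(f"unknown mode {mode!r}")


def align_and_average(
    images: Sequence[np.ndarray],
    centers: Sequence[tuple[int, int]],
    window_halfwidth: int,
    mode: Literal["same_z", "mip"] = "mip",
) -> DotAlignment:
    """Average dot-centered windows across cells (integer alignment).

    ``centers`` are (x, y) per image.  Cells whose window would exceed
    the image bounds are dropped and counted in ``n_dropped``; zero
    usable cells is an error.
    """
    if len(images) != len(centers):
        raise ValueError("images and centers must pair up")
    w = int(window_halfwidth)
    if w < 0:
        raise ValueError("window_halfwidth must be >= 0")
    acc = np.zeros((2 * w + 1, 2 * w + 1))
    used = dropped = 0
    for img, (cx, cy) in zip(images, centers):
        img = np.asarray(img, dtype=float)
        r, c = int(cy), int(cx)
        if r - w < 0 or c - w < 0 or r + w >= img.shape[0] or c + w >= img.shape[1]:
            dropped += 1
            continue
        acc += img[r - w : r + w + 1, c - w : c + w + 1]
        used += 1
    if used == 0:
        raise ValueError("no usable cells (all windows out of bounds)")
    return DotAlignment(
        window_halfwidth=w,
        n_cells=used,
        averaged_image=acc / used,
        mode=mode,
        n_dropped=dropped,
    )


def line_profile(alignment: DotAlignment, angle: float = 0.0) -> LineProfile:
    """Sample the averaged image along a line through the center.

    ``angle`` in degrees, 0 = horizontal; nearest-pixel sampling at
    signed offsets -w..w from the center.
    """
    img = alignment.averaged_image
    if img.ndim != 2 or img.shape[0] != img.shape[1] or img.shape[0] % 2 == 0:
        raise ValueError("averaged image must be square with odd side")
    w = alignment.window_halfwidth
    offsets = np.arange(-w, w + 1)
    theta = np.deg2rad(angle)
    rows = np.rint(w - offsets * np.sin(theta)).astype(int)
    cols = np.rint(w + offsets * np.cos(theta)).astype(int)
    rows = np.clip(rows, 0, img.shape[0] - 1)
    cols = np.clip(cols, 0, img.shape[1] - 1)
    intensities = img[rows, cols]
    return LineProfile(
        offsets=offsets,
        intensities=intensities,
        peak_center_value=float(img[w, w]),
    )
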