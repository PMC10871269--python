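"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the downstream
analyses assume, not the optics of a particular microscope:

* nuclei as disks with a diffuse fluorophore pool plus a configurable
  fraction of the signal concentrated in Gaussian (PSF-limited) puncta,
  under Poisson shot noise and additive Gaussian read noise;
* coupled or independent two-channel nuclei for colocalization tests;
* z-stacks containing a bright marker dot (tetO/tetR-mCherry style) at
  a known in-plane offset from a GFP punctum;
* single-exponential FRAP recovery with an immobile fraction;
* negative-binomial MTAC count tables with enrichment planted at
  designated NDRs.

All randomness flows through the explicit ``seed`` field of each spec;
identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .frap import FRAPTrace
from .mtac import NDRRecord, ViewPoint, classify_interaction

__all__ = [
    "NucleusImageSpec",
    "TwoChannelSpec",
    "DotStackSpec",
    "FRAPSimSpec",
    "MTACSimSpec",
    "gen_nucleus_image",
    "gen_two_channel",
    "gen_dot_stack",
    "gen_frap_traces",
    "gen_mtac_counts",
]


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class NucleusImageSpec:
    """Parameters of one synthetic nucleus image (square field).

    ``total_intensity`` is the expected number of photons emitted inside
    the nucleus; ``puncta_fraction`` of it is concentrated in
    ``puncta_count`` isotropic Gaussian puncta of width ``psf_sigma``,
    the rest is uniform (diffuse).  ``background_rate`` photons/pixel
    are added across the whole field.
    """

    image_size: int = 128
    nucleus_center: tuple[float, float] = (64.0, 64.0)  # (row, col)
    nucleus_radius: float = 24.0
    total_intensity: float = 200_000.0
    puncta_count: int = 0
    puncta_fraction: float = 0.0
    psf_sigma: float = 2.0
    background_rate: float = 2.0
    read_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.puncta_fraction <= 1.0):
            raise ValueError("puncta_fraction must be in [0, 1]")
        if self.puncta_count < 0:
            raise ValueError("puncta_count must be >= 0")
        if self.total_intensity < 0 or self.background_rate < 0 or self.read_noise_sd < 0:
            raise ValueError("intensities and noise levels must be >= 0")
        r, c = self.nucleus_center
        rad = self.nucleus_radius
        if rad <= 0:
            raise ValueError("nucleus_radius must be positive")
        if not (rad <= r <= self.image_size - 1 - rad and rad <= c <= self.image_size - 1 - rad):
            raise ValueError("nucleus does not fit inside the image")

    @property
    def effective_puncta_fraction(self) -> float:
        """puncta_count == 0 forces the punctate fraction to zero."""
        return self.puncta_fraction if self.puncta_count > 0 else 0.0


@dataclass(frozen=True)
class TwoChannelSpec:
    """Two co-registered nucleus channels, coupled or independent puncta."""

    base_a: NucleusImageSpec
    base_b: NucleusImageSpec
    coupling: Literal["shared_puncta", "independent"] = "shared_puncta"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling not in ("shared_puncta", "independent"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        a, b = self.base_a, self.base_b
        if (
            a.image_size != b.image_size
            or a.nucleus_center != b.nucleus_center
            or a.nucleus_radius != b.nucleus_radius
        ):
            raise ValueError("channels must share nucleus geometry")
        if self.coupling == "shared_puncta" and a.puncta_count != b.puncta_count:
            raise ValueError("shared_puncta requires equal puncta_count")


@dataclass(frozen=True)
class DotStackSpec:
    """A two-channel z-stack: a marker dot plus an offset GFP punctum.

    ``dot_position`` is (row, col, z_index).  The GFP channel carries a
    nucleus (diffuse signal split across planes) whose single punctum
    sits in the dot's z-plane, displaced in-plane by
    ``gfp_puncta_offset`` (row, col) pixels.
    """

    n_z: int = 14
    z_step: float = 0.4  # micrometres
    dot_position: tuple[float, float, int] = (64.0, 64.0, 7)
    dot_intensity: float = 50_000.0
    gfp_puncta_offset: tuple[float, float] = (0.0, 0.0)
    dot_sigma_z: float = 1.0  # planes
    base: NucleusImageSpec = field(
        default_factory=lambda: NucleusImageSpec(puncta_count=1, puncta_fraction=0.3)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        r, c, z = self.dot_position
        size = self.base.image_size
        if not (0 <= r < size and 0 <= c < size and 0 <= z < self.n_z):
            raise ValueError("dot position outside stack")
        pr, pc = r + self.gfp_puncta_offset[0], c + self.gfp_puncta_offset[1]
        if not (0 <= pr < size and 0 <= pc < size):
            raise ValueError("gfp_puncta_offset pushes the punctum outside the field")

    @property
    def depth_um(self) -> float:
        """Axial span of the stack, (n_z - 1) * z_step micrometres."""
        return (self.n_z - 1) * self.z_step


@dataclass(frozen=True)
class FRAPSimSpec:
    """Single-exponential FRAP recovery with an immobile fraction.

    Percent-of-pre-bleach units: pre-bleach frames are 100 (+ noise),
    the first post-bleach frame drops to the floor ``100*bleach_depth``,
    and recovery approaches ``floor + mobile_fraction*(100 - floor)``
    with half-time ``t_half_true`` seconds.
    """

    t_half_true: float = 64.0
    mobile_fraction: float = 0.9
    bleach_depth: float = 0.4
    dt: float = 3.0
    t_total: float = 270.0
    n_prebleach_frames: int = 3
    noise_sd: float = 2.0  # percent of pre-bleach
    n_traces: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_half_true <= 0:
            raise ValueError("t_half_true must be positive")
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ValueError("mobile_fraction must be in [0, 1]")
        if not (0.0 <= self.bleach_depth <= 1.0):
            raise ValueError("bleach_depth must be in [0, 1]")
        if self.dt <= 0 or self.t_total < self.dt:
            raise ValueError("need dt > 0 and t_total >= dt")
        if self.n_prebleach_frames < 1:
            raise ValueError("n_prebleach_frames must be >= 1")
        if self.noise_sd < 0 or self.n_traces < 1:
            raise ValueError("noise_sd >= 0 and n_traces >= 1 required")


@dataclass(frozen=True)
class MTACSimSpec:
    """Negative-binomial MTAC count tables with planted enrichment.

    ``enriched_ndrs`` maps NDR indices to per-NDR log2 fold changes
    applied in the targeted condition only.  Counts for NDR i,
    replicate j are NB with mean
    ``baseline_mean * library_size_j * 2**log2fc_i`` and dispersion
    ``dispersion`` (variance mu + dispersion * mu^2).
    """

    genome_layout: tuple[tuple[str, int], ...] = (("chr7", 1_090_000), ("chr10", 745_000))
    ndr_positions: tuple[tuple[str, int, int], ...] = ()
    vp: ViewPoint = field(default_factory=lambda: ViewPoint("chr7", 500_000))
    enriched_ndrs: tuple[tuple[int, float], ...] = ()
    dispersion: float = 0.05
    baseline_mean: float = 100.0
    library_sizes_targeted: tuple[float, ...] = (1.0, 1.0)
    library_sizes_control: tuple[float, ...] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if any(s <= 0 for s in self.library_sizes_targeted + self.library_sizes_control):
            raise ValueError("library sizes must be positive")
        chroms = {c for c, _ in self.genome_layout}
        lengths = dict(self.genome_layout)
        for chrom, start, end in self.ndr_positions:
            if chrom not in chroms:
                raise ValueError(f"NDR chromosome {chrom!r} not in genome layout")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"invalid NDR interval {chrom}:{start}-{end}")
        n = len(self.ndr_positions)
        for idx, lfc in self.enriched_ndrs:
            if not (0 <= idx < n):
                raise ValueError(f"enriched NDR index {idx} out of range")
            _ = float(lfc)


# --------------------------------------------------------------------------
# image generators


def _disk_mask(size: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _sample_puncta_positions(
    rng: np.random.Generator, spec: NucleusImageSpec
) -> np.ndarray:
    """Uniform positions in a disk of radius r - 2*psf_sigma (edge margin).

    Rejection-sampled from the bounding square; candidates falling
    outside the admissible disk are resampled.
    """
    if spec.puncta_count == 0:
        return np.empty((0, 2))
    r_eff = spec.nucleus_radius - 2.0 * spec.psf_sigma
    if r_eff <= 0:
        raise ValueError(
            "impossible geometry: nucleus_radius must exceed 2*psf_sigma to place puncta"
        )
    out = []
    cr, cc = spec.nucleus_center
    while len(out) < spec.puncta_count:
        cand = rng.uniform(-r_eff, r_eff, size=2)
        if cand[0] ** 2 + cand[1] ** 2 <= r_eff**2:
            out.append((cr + cand[0], cc + cand[1]))
    return np.array(out)


def _expected_image(spec: NucleusImageSpec, positions: np.ndarray) -> np.ndarray:
    size = spec.image_size
    mask = _disk_mask(size, spec.nucleus_center, spec.nucleus_radius)
    rate = np.full((size, size), float(spec.background_rate))
    pf = spec.effective_puncta_fraction
    area = int(mask.sum())
    if area > 0 and spec.total_intensity > 0:
        rate[mask] += spec.total_intensity * (1.0 - pf) / area
    if len(positions) and pf > 0:
        per_punctum = spec.total_intensity * pf / len(positions)
        rr, cc = np.mgrid[0:size, 0:size]
        s2 = spec.psf_sigma**2
        norm = per_punctum / (2.0 * np.pi * s2)
        for pr, pc in positions:
            rate += norm * np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2) / (2.0 * s2))
    return rate


def _render(rate: np.ndarray, read_noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    img = rng.poisson(rate).astype(float)
    if read_noise_sd > 0:
        img += rng.normal(0.0, read_noise_sd, size=rate.shape)
        # detector clamp: read noise cannot push reported counts below zero
        np.maximum(img, 0.0, out=img)
    return img


def gen_nucleus_image(
    spec: NucleusImageSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one nucleus.

    Returns ``(image, true_mask, puncta_positions)`` where ``image`` is
    a Poisson draw of (diffuse density + Gaussian puncta + background)
    plus Gaussian read noise, ``true_mask`` is the exact nucleus disk,
    and ``puncta_positions`` is an (n, 2) array of (row, col) centres.
    """
    rng = np.random.default_rng(spec.seed)
    positions = _sample_puncta_positions(rng, spec)
    rate = _expected_image(spec, positions)
    image = _render(rate, spec.read_noise_sd, rng)
    mask = _disk_mask(spec.image_size, spec.nucleus_center, spec.nucleus_radius)
    return image, mask, positions


def gen_two_channel(
    spec: TwoChannelSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a co-registered channel pair sharing one nucleus mask.

    ``shared_puncta`` draws puncta positions once and reuses them in
    both channels; ``independent`` draws them separately.  Shot and
    read noise are independent across channels in either mode.
    """
    rng = np.random.default_rng(spec.seed)
    pos_rng, noise_a, noise_b = rng.spawn(3)
    pos_a = _sample_puncta_positions(pos_rng, spec.base_a)
    if spec.coupling == "shared_puncta":
        pos_b = pos_a
    else:
        pos_b = _sample_puncta_positions(pos_rng, spec.base_b)
    image_a = _render(_expected_image(spec.base_a, pos_a), spec.base_a.read_noise_sd, noise_a)
    image_b = _render(_expected_image(spec.base_b, pos_b), spec.base_b.read_noise_sd, noise_b)
    mask = _disk_mask(
        spec.base_a.image_size, spec.base_a.nucleus_center, spec.base_a.nucleus_radius
    )
    return image_a, image_b, mask


def gen_dot_stack(spec: DotStackSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render an (mCherry, GFP) z-stack pair around a marker dot.

    The mCherry channel contains a single dominant 3-D Gaussian dot at
    ``spec.dot_position``; the GFP channel contains the nucleus (diffuse
    pool spread evenly across planes) plus one punctum displaced from
    the dot by ``gfp_puncta_offset`` in the dot's z-plane.  ``truth``
    records both positions, their in-plane separation, and the stack
    depth in micrometres.  Axis order is (Z, Y, X).
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.base.image_size
    dr, dc, dz = spec.dot_position
    rr, cc = np.mgrid[0:size, 0:size]
    s2 = spec.base.psf_sigma**2
    zw = np.exp(-((np.arange(spec.n_z) - dz) ** 2) / (2.0 * spec.dot_sigma_z**2))
    zw = zw / zw.sum()

    dot_plane = np.exp(-((rr - dr) ** 2 + (cc - dc) ** 2) / (2.0 * s2)) / (2.0 * np.pi * s2)
    mch_rate = spec.base.background_rate + spec.dot_intensity * zw[:, None, None] * dot_plane

    pf = spec.base.effective_puncta_fraction
    mask = _disk_mask(size, spec.base.nucleus_center, spec.base.nucleus_radius)
    area = int(mask.sum())
    diffuse = np.full((size, size), float(spec.base.background_rate))
    if area > 0:
        diffuse[mask] += spec.base.total_intensity * (1.0 - pf) / (area * spec.n_z)
    pr, pc = dr + spec.gfp_puncta_offset[0], dc + spec.gfp_puncta_offset[1]
    punctum = (
        spec.base.total_intensity
        * pf
        * np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2) / (2.0 * s2))
        / (2.0 * np.pi * s2)
    )
    gfp_rate = diffuse[None, :, :] + punctum[None, :, :] * zw[:, None, None]

    stack_mch = _render(mch_rate, spec.base.read_noise_sd, rng)
    stack_gfp = _render(gfp_rate, spec.base.read_noise_sd, rng)
    truth = {
        "dot": (dr, dc, dz),
        "gfp_punctum": (pr, pc, dz),
        "separation_px": float(np.hypot(*spec.gfp_puncta_offset)),
        "depth_um": spec.depth_um,
    }
    return stack_mch, stack_gfp, truth


# --------------------------------------------------------------------------
# FRAP and MTAC generators


def frap_expectation(spec: FRAPSimSpec, t_post: np.ndarray) -> np.ndarray:
    """Noiseless post-bleach expectation in percent of pre-bleach.

    ``floor + mobile_fraction * (100 - floor) * (1 - 2^(-t/t_half))``
    with floor = 100 * bleach_depth and t measured from the first
    post-bleach frame.
    """
    floor = 100.0 * spec.bleach_depth
    k = np.log(2.0) / spec.t_half_true
    return floor + spec.mobile_fraction * (100.0 - floor) * (1.0 - np.exp(-k * t_post))


def gen_frap_traces(spec: FRAPSimSpec) -> list[FRAPTrace]:
    """Simulate noisy FRAP traces in percent-of-pre-bleach units."""
    rng = np.random.default_rng(spec.seed)
    n_post = int(round(spec.t_total / spec.dt))
    n_pre = spec.n_prebleach_frames
    times = np.arange(n_pre + n_post) * spec.dt
    t_post = np.arange(n_post) * spec.dt
    expect = np.concatenate([np.full(n_pre, 100.0), frap_expectation(spec, t_post)])
    traces = []
    for _ in range(spec.n_traces):
        noisy = expect + rng.normal(0.0, spec.noise_sd, size=expect.shape) \
            if spec.noise_sd > 0 else expect.copy()
        traces.append(FRAPTrace(times.copy(), noisy, n_prebleach=n_pre))
    return traces


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float, n: int) -> np.ndarray:
    """NB draws with variance mu + alpha mu^2; Poisson in the alpha->0 limit."""
    if alpha <= 0:
        return rng.poisson(mean, size=n)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n)


def gen_mtac_counts(
    spec: MTACSimSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an MTAC count table.

    Returns ``(ndr_table, count_matrix, truth_labels)``:

    * ``ndr_table`` — chrom/start/end per NDR;
    * ``count_matrix`` — one row per NDR, columns ``targeted_i`` /
      ``control_i``;
    * ``truth_labels`` — planted log2fc, enrichment flag, and the
      geometric class of each NDR relative to the viewpoint.
    """
    rng = np.random.default_rng(spec.seed)
    lfc_by_idx = dict(spec.enriched_ndrs)
    rows_counts, rows_truth = [], []
    for i, (chrom, start, end) in enumerate(spec.ndr_positions):
        lfc = float(lfc_by_idx.get(i, 0.0))
        row: dict[str, float] = {}
        for j, s in enumerate(spec.library_sizes_targeted):
            mu = spec.baseline_mean * s * 2.0**lfc
            row[f"targeted_{j + 1}"] = int(_nb_draw(rng, mu, spec.dispersion, 1)[0])
        for j, s in enumerate(spec.library_sizes_control):
            mu = spec.baseline_mean * s
            row[f"control_{j + 1}"] = int(_nb_draw(rng, mu, spec.dispersion, 1)[0])
        rows_counts.append(row)
        ndr = NDRRecord(chrom, start, end, [0], [0])
        rows_truth.append(
            {
                "enriched": i in lfc_by_idx,
                "log2fc_true": lfc,
                "klass": classify_interaction(ndr, spec.vp),
            }
        )
    ndr_table = pd.DataFrame(
        [{"chrom": c, "start": s, "end": e} for c, s, e in spec.ndr_positions],
        columns=["chrom", "start", "end"],
    )
    count_matrix = pd.DataFrame(rows_counts)
    truth = pd.DataFrame(rows_truth, columns=["enriched", "log2fc_true", "klass"])
    return ndr_table, count_matrix, truth


def mtac_records_from_tables(
    ndr_table: pd.DataFrame,
    count_matrix: pd.DataFrame,
    library_sizes_targeted: Sequence[float] | None = None,
    library_sizes_control: Sequence[float] | None = None,
) -> list[NDRRecord]:
    """Assemble NDRRecords from the tabular form written by the simulator."""
    tcols = sorted(
        (c for c in count_matrix.columns if c.startswith("targeted_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    ccols = sorted(
        (c for c in count_matrix.columns if c.startswith("control_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if not tcols or not ccols:
        raise ValueError("count matrix needs targeted_* and control_* columns")
    records = []
    for (_, ndr), (_, counts) in zip(ndr_table.iterrows(), count_matrix.iterrows()):
        records.append(
            NDRRecord(
                chrom=str(ndr["chrom"]),
                start=int(ndr["start"]),
                end=int(ndr["end"]),
                counts_targeted=counts[tcols].to_numpy(dtype=float),
                counts_control=counts[ccols].to_numpy(dtype=float),
                library_sizes_targeted=library_sizes_targeted,
                library_sizes_control=library_sizes_control,
            )
        )
    return records
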