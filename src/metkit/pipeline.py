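"""Stage orchestration: reproducible runs bound by one config + seed.

``run_pipeline`` executes a subset of the named stages in canonical
order, logging parameters to stderr, and writes a manifest recording
the config hash, seed, software version and the SHA-256 of every
output file.  Identical config + seed reproduce identical content
hashes (timestamps are recorded but excluded from hashing).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dots, frap, io, mtac, puncta, segment, synthetic
from .config import RunConfig, config_hash

__all__ = ["ResultBundle", "run_pipeline", "STAGES"]

STAGES = ("simulate", "segment", "puncta", "coloc", "dotalign", "frap", "mtac-call")

logger = logging.getLogger("metkit")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class ResultBundle:
    """Run metadata plus stage outputs by path."""

    config_hash: str
    seed: int
    version: str
    outputs: dict[str, list[str]] = field(default_factory=dict)
    content_hashes: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def manifest(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "outputs": self.outputs,
            "content_hashes": self.content_hashes,
            "timestamp": self.timestamp,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _nucleus_spec(cfg: RunConfig, seed: int, **overrides) -> synthetic.NucleusImageSpec:
    sim = cfg.simulate
    base = dict(
        image_size=sim.image_size,
        nucleus_center=(sim.image_size / 2.0, sim.image_size / 2.0),
        nucleus_radius=sim.nucleus_radius,
        total_intensity=sim.total_intensity,
        puncta_count=sim.puncta_count,
        puncta_fraction=sim.puncta_fraction,
        psf_sigma=sim.psf_sigma,
        background_rate=sim.background_rate,
        read_noise_sd=sim.read_noise_sd,
        seed=seed,
    )
    base.update(overrides)
    return synthetic.NucleusImageSpec(**base)


def _stage_simulate(cfg: RunConfig, outdir: Path) -> list[Path]:
    seeds = np.random.SeedSequence(cfg.seed).generate_state(6) % (2**31)
    out = []

    image, mask, _ = synthetic.gen_nucleus_image(_nucleus_spec(cfg, int(seeds[0])))
    io.write_image(outdir / "image.tif", image.astype(np.float32))
    io.write_image(outdir / "true_mask.tif", mask.astype(np.uint8))
    out += [outdir / "image.tif", outdir / "true_mask.tif"]

    two = synthetic.TwoChannelSpec(
        base_a=_nucleus_spec(cfg, int(seeds[1])),
        base_b=_nucleus_spec(cfg, int(seeds[1])),
        coupling="shared_puncta",
        seed=int(seeds[1]),
    )
    cha, chb, _ = synthetic.gen_two_channel(two)
    io.write_image(outdir / "channel_a.tif", cha.astype(np.float32))
    io.write_image(outdir / "channel_b.tif", chb.astype(np.float32))
    out += [outdir / "channel_a.tif", outdir / "channel_b.tif"]

    stack_spec = synthetic.DotStackSpec(
        z_step=cfg.z_step, base=_nucleus_spec(cfg, int(seeds[2]), puncta_count=1), seed=int(seeds[2])
    )
    mch, gfp, _ = synthetic.gen_dot_stack(stack_spec)
    io.write_image(outdir / "dot_mcherry.tif", mch.astype(np.float32))
    io.write_image(outdir / "dot_gfp.tif", gfp.astype(np.float32))
    out += [outdir / "dot_mcherry.tif", outdir / "dot_gfp.tif"]

    traces = synthetic.gen_frap_traces(
        synthetic.FRAPSimSpec(dt=cfg.frap.dt, n_prebleach_frames=cfg.frap.n_prebleach, seed=int(seeds[3]))
    )
    io.write_frap_csv(outdir / "frap_traces.csv", traces)
    out.append(outdir / "frap_traces.csv")

    mt = synthetic.MTACSimSpec(
        ndr_positions=tuple(
            ("chr7", p, p + 500) for p in range(10_000, 1_010_000, 50_000)
        ),
        enriched_ndrs=((10, 2.5),),
        seed=int(seeds[4]),
    )
    ndr_table, counts, truth = synthetic.gen_mtac_counts(mt)
    io.write_ndr_bed(outdir / "ndrs.bed", ndr_table)
    counts.to_csv(outdir / "mtac_counts.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "mtac_truth.tsv", sep="\t", index=False)
    out += [outdir / "ndrs.bed", outdir / "mtac_counts.tsv", outdir / "mtac_truth.tsv"]
    return out


def _stage_segment(cfg: RunConfig, outdir: Path) -> list[Path]:
    image, _ = io.read_image(outdir / "image.tif")
    masks = segment.segment_nuclei(
        image,
        min_area=cfg.segmentation.min_area,
        max_area=cfg.segmentation.max_area,
        smoothing_sigma=cfg.segmentation.smoothing_sigma,
        split_touching=cfg.segmentation.split_touching,
    )
    labels = np.zeros(image.shape, dtype=np.int32)
    rows = []
    for m in masks:
        labels[m.pixel_coords[:, 0], m.pixel_coords[:, 1]] = m.label
        r, c = m.centroid
        rows.append({"label": m.label, "area": m.area, "centroid_row": r, "centroid_col": c})
    io.write_image(outdir / "labels.tif", labels)
    pd.DataFrame(rows, columns=["label", "area", "centroid_row", "centroid_col"]).to_csv(
        outdir / "nuclei.tsv", sep="\t", index=False
    )
    return [outdir / "labels.tif", outdir / "nuclei.tsv"]


def _masks_from_label_image(labels: np.ndarray) -> list[segment.NucleusMask]:
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        coords = np.argwhere(labels == lab)
        out.append(segment.NucleusMask(int(lab), coords, np.empty((0, 2)), len(coords)))
    return out


def _stage_puncta(cfg: RunConfig, outdir: Path) -> list[Path]:
    image, _ = io.read_image(outdir / "image.tif")
    labels, _ = io.read_image(outdir / "labels.tif")
    background = float(cfg.simulate.background_rate)
    rows = []
    for m in _masks_from_label_image(labels):
        s = puncta.compute_stats(segment.extract_pixels(image, m, background))
        rows.append(
            {"label": m.label, "n": m.area, "mean": s.mean, "sd": s.sd,
             "cv": s.cv, "fano": s.fano}
        )
    pd.DataFrame(rows, columns=["label", "n", "mean", "sd", "cv", "fano"]).to_csv(
        outdir / "puncta.tsv", sep="\t", index=False
    )
    return [outdir / "puncta.tsv"]


def _stage_coloc(cfg: RunConfig, outdir: Path) -> list[Path]:
    cha, _ = io.read_image(outdir / "channel_a.tif")
    chb, _ = io.read_image(outdir / "channel_b.tif")
    masks = segment.segment_nuclei(
        cha,
        min_area=cfg.segmentation.min_area,
        smoothing_sigma=cfg.segmentation.smoothing_sigma,
    )
    background = float(cfg.simulate.background_rate)
    rows = []
    for m in masks:
        res = puncta.coloc_pearson(
            segment.extract_pixels(cha, m, background),
            segment.extract_pixels(chb, m, background),
        )
        rows.append({"label": m.label, "n_pixels": res.n_pixels, "r": res.r})
    pd.DataFrame(rows, columns=["label", "n_pixels", "r"]).to_csv(
        outdir / "coloc.tsv", sep="\t", index=False
    )
    return [outdir / "coloc.tsv"]


def _stage_dotalign(cfg: RunConfig, outdir: Path) -> list[Path]:
    mch, _ = io.read_image(outdir / "dot_mcherry.tif")
    gfp, _ = io.read_image(outdir / "dot_gfp.tif")
    det = dots.find_dot(mch, cfg.dot.smoothing_sigma, cfg.dot.min_prominence)
    plane = dots.extract_second_channel(gfp, det, cfg.dot.mode)
    alignment = dots.align_and_average(
        [plane], [(det.x, det.y)], cfg.dot.window_halfwidth, mode=cfg.dot.mode
    )
    profile = dots.line_profile(alignment)
    io.write_image(outdir / "dot_average.tif", alignment.averaged_image.astype(np.float32))
    pd.DataFrame(
        [{"x": det.x, "y": det.y, "z_index": det.z_index, "dot_intensity": det.dot_intensity}]
    ).to_csv(outdir / "dot_detections.tsv", sep="\t", index=False)
    pd.DataFrame({"offset": profile.offsets, "intensity": profile.intensities}).to_csv(
        outdir / "dot_profile.tsv", sep="\t", index=False
    )
    return [outdir / "dot_average.tif", outdir / "dot_detections.tsv", outdir / "dot_profile.tsv"]


def _stage_frap(cfg: RunConfig, outdir: Path) -> list[Path]:
    traces = io.read_frap_csv(outdir / "frap_traces.csv", n_prebleach=cfg.frap.n_prebleach)
    normalized = [frap.normalize_trace(t) for t in traces]
    mean_trace, sd = frap.average_traces(normalized)
    fit = frap.fit_recovery(mean_trace, min_recovery=cfg.frap.min_recovery)
    pd.DataFrame(
        {"time": mean_trace.times, "mean": mean_trace.normalized, "sd": sd}
    ).to_csv(outdir / "frap_mean.csv", index=False)
    (outdir / "frap_fit.json").write_text(
        json.dumps(
            {
                "floor": fit.floor,
                "plateau": fit.plateau,
                "k": fit.k,
                "t_half": fit.t_half,
                "mobile_fraction": fit.mobile_fraction,
                "rss": fit.rss,
            },
            indent=2,
        )
    )
    return [outdir / "frap_mean.csv", outdir / "frap_fit.json"]


def _stage_mtac(cfg: RunConfig, outdir: Path) -> list[Path]:
    ndr_table = io.read_ndr_bed(outdir / "ndrs.bed")
    counts = pd.read_csv(outdir / "mtac_counts.tsv", sep="\t")
    records = synthetic.mtac_records_from_tables(ndr_table, counts)
    vp = mtac.ViewPoint("chr7", 500_000)
    calls = mtac.call_interactions(
        records,
        vp,
        q_threshold=cfg.mtac.q_threshold,
        local_threshold=cfg.mtac.local_threshold,
        alpha_min=cfg.mtac.alpha_min,
    )
    table = mtac.volcano_table(calls)
    table.to_csv(outdir / "mtac_volcano.tsv", sep="\t", index=False)
    summary = {
        k: int(((table["klass"] == k) & table["significant"]).sum())
        for k in ("local", "far_cis", "trans")
    }
    (outdir / "mtac_summary.json").write_text(json.dumps(summary, indent=2))
    return [outdir / "mtac_volcano.tsv", outdir / "mtac_summary.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "puncta": _stage_puncta,
    "coloc": _stage_coloc,
    "dotalign": _stage_dotalign,
    "frap": _stage_frap,
    "mtac-call": _stage_mtac,
}


def run_pipeline(
    config: RunConfig, stages: list[str], outdir: str | Path
) -> ResultBundle:
    """Execute the requested stages in canonical order.

    Unknown stage names raise before anything executes; a stage failure
    aborts with the failing stage named, retaining partial outputs.
    """
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(
        config_hash=config_hash(config),
        seed=config.seed,
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        logger.info("stage %s starting (seed=%d)", stage, config.seed)
        try:
            paths = _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        bundle.outputs[stage] = [str(p) for p in paths]
        for p in paths:
            bundle.content_hashes[p.name] = _sha256(p)
        logger.info("stage %s wrote %d file(s)", stage, len(paths))
    (outdir / "manifest.json").write_text(json.dumps(bundle.manifest(), indent=2))
    return bundle
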