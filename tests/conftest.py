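"""Shared fixtures: synthetic scenario builders used across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from metkit.mtac import ViewPoint
from metkit.synthetic import (
    MTACSimSpec,
    NucleusImageSpec,
    gen_mtac_counts,
    mtac_records_from_tables,
)


def diffuse_spec(seed: int = 0, **overrides) -> NucleusImageSpec:
    """A plain diffuse nucleus (no puncta), default geometry."""
    kw = dict(puncta_count=0, puncta_fraction=0.0, seed=seed)
    kw.update(overrides)
    return NucleusImageSpec(**kw)


def punctate_spec(seed: int = 0, **overrides) -> NucleusImageSpec:
    kw = dict(puncta_count=3, puncta_fraction=0.9, seed=seed)
    kw.update(overrides)
    return NucleusImageSpec(**kw)


def met13_vp_scenario(seed: int = 11):
    """MET13-viewpoint-style MTAC table on an induced (activated) background.

    A chr7 viewpoint with six enriched local NDRs (adjacent chromatin),
    two enriched far-cis promoter NDRs standing in for the STR3 and
    MUP1 promoters (log2fc 2.5, baseline 200), and null NDRs across
    three chromosomes.  Returns (records, vp, far_cis_starts).
    """
    layout = (("chr7", 1_090_000), ("chr5", 577_000), ("chr10", 745_000))
    vp = ViewPoint("chr7", 290_000)
    ndrs: list[tuple[str, int, int]] = []
    for off in (-24_000, -12_000, -4_000, 3_000, 11_000, 23_000):
        p = vp.position + off
        ndrs.append(("chr7", p, p + 500))
    far_cis_starts = (440_000, 600_000)  # +150 kb and +310 kb from the VP
    for p in far_cis_starts:
        ndrs.append(("chr7", p, p + 500))
    for p in range(50_000, 1_050_000, 25_000):
        if abs(p - vp.position) > 35_000 and all(abs(p - f) > 5_000 for f in far_cis_starts):
            ndrs.append(("chr7", p, p + 500))
    for chrom, length in layout[1:]:
        for p in range(40_000, length - 20_000, 30_000):
            ndrs.append((chrom, p, p + 500))
    enriched = tuple([(i, 3.0) for i in range(6)] + [(6, 2.5), (7, 2.5)])
    spec = MTACSimSpec(
        genome_layout=layout,
        ndr_positions=tuple(ndrs),
        vp=vp,
        enriched_ndrs=enriched,
        dispersion=0.05,
        baseline_mean=200.0,
        seed=seed,
    )
    table, counts, _ = gen_mtac_counts(spec)
    return mtac_records_from_tables(table, counts), vp, far_cis_starts


def met6_vp_trans_scenario(seed: int = 17):
    """MET6-viewpoint-style table: three enriched trans NDRs.

    The viewpoint sits on chr5; enrichment is planted at three NDRs on
    other chromosomes standing in for the MUP1, STR3 and YKG9 loci,
    plus local NDRs near the VP.  Returns (records, vp, trans_keys).
    """
    layout = (("chr5", 577_000), ("chr7", 1_090_000), ("chr11", 667_000))
    vp = ViewPoint("chr5", 300_000)
    ndrs: list[tuple[str, int, int]] = []
    for off in (-15_000, -3_000, 8_000, 21_000):
        p = vp.position + off
        ndrs.append(("chr5", p, p + 500))
    trans_keys = (("chr7", 440_000), ("chr7", 760_000), ("chr11", 210_000))
    for chrom, p in trans_keys:
        ndrs.append((chrom, p, p + 500))
    for p in range(40_000, 560_000, 30_000):
        if abs(p - vp.position) > 35_000:
            ndrs.append(("chr5", p, p + 500))
    for chrom, length in layout[1:]:
        for p in range(50_000, length - 20_000, 40_000):
            if all(not (chrom == tc and abs(p - tp) < 5_000) for tc, tp in trans_keys):
                ndrs.append((chrom, p, p + 500))
    enriched = tuple([(i, 3.0) for i in range(4)] + [(4, 2.5), (5, 2.5), (6, 2.5)])
    spec = MTACSimSpec(
        genome_layout=layout,
        ndr_positions=tuple(ndrs),
        vp=vp,
        enriched_ndrs=enriched,
        dispersion=0.05,
        baseline_mean=200.0,
        seed=seed,
    )
    table, counts, _ = gen_mtac_counts(spec)
    return mtac_records_from_tables(table, counts), vp, trans_keys


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240712)
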