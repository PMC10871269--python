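"""Shared readers and writers (TIFF, TSV, BED, CSV traces)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .frap import FRAPTrace
from .mtac import ViewPoint

__all__ = [
    "read_image",
    "write_image",
    "write_ndr_bed",
    "read_ndr_bed",
    "write_frap_csv",
    "read_frap_csv",
    "parse_viewpoint",
]


def read_image(path: str | Path) -> tuple[np.ndarray, str]:
    """Read a TIFF into an array plus its axis-order string.

    2-D images report axes ``"YX"``; multi-page stacks are returned as
    (Z, Y, X) with axes ``"ZYX"``.  dtype is preserved.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"unreadable TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        return arr, "YX"
    if arr.ndim == 3 and arr.size > 0:
        return arr, "ZYX"
    raise ValueError(f"unreadable TIFF {path}: unexpected shape {arr.shape}")


def write_image(path: str | Path, array: np.ndarray) -> None:
    """Write a 2-D image or a (Z, Y, X) stack as (multi-page) TIFF."""
    array = np.asarray(array)
    if array.ndim not in (2, 3):
        raise ValueError("only 2-D images or 3-D ZYX stacks supported")
    tifffile.imwrite(Path(path), array, photometric="minisblack")


def write_ndr_bed(path: str | Path, ndr_table: pd.DataFrame) -> None:
    """Write NDR intervals as BED6 (0-based half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": ndr_table["chrom"],
            "start": ndr_table["start"].astype(int),
            "end": ndr_table["end"].astype(int),
            "name": [f"NDR_{i + 1}" for i in range(len(ndr_table))],
            "score": 0,
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_ndr_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
    )
    return bed[["chrom", "start", "end"]]


def write_frap_csv(path: str | Path, traces: list[FRAPTrace]) -> None:
    """Long-format CSV: columns trace_id, time, intensity."""
    frames = []
    for i, tr in enumerate(traces):
        frames.append(
            pd.DataFrame(
                {"trace_id": i + 1, "time": tr.times, "intensity": tr.intensities}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_frap_csv(path: str | Path, n_prebleach: int = 3) -> list[FRAPTrace]:
    df = pd.read_csv(path)
    required = {"trace_id", "time", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"FRAP CSV needs columns {sorted(required)}")
    traces = []
    for _, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("time")
        traces.append(
            FRAPTrace(
                grp["time"].to_numpy(float),
                grp["intensity"].to_numpy(float),
                n_prebleach=n_prebleach,
            )
        )
    return traces


def parse_viewpoint(text: str) -> ViewPoint:
    """Parse ``chrom:position`` into a ViewPoint."""
    try:
        chrom, pos = text.rsplit(":", 1)
        return ViewPoint(chrom=chrom, position=int(pos))
    except (ValueError, TypeError) as exc:
        raise ValueError(f"viewpoint must be chrom:pos, got {text!r}") from exc
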