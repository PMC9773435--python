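"""Normalized depth of coverage (NDoC) in fixed windows, with CNV flags.

The recombinant's per-base depth is divided by the parent's and averaged in
windows (default 1 kb, non-overlapping; the step is configurable for a true
sliding window).  NDoC ≈ 1 in copy-neutral regions; windows are flagged as
potential deletions when NDoC < 0.5 and insertions when NDoC > 1.5 (strict
inequalities, user-adjustable).  Positions absent from a coverage table
count as depth 0 up to the chromosome length.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GenomeLayout

FLAG_LOSS = "loss"
FLAG_GAIN = "gain"
FLAG_NONE = "none"
FLAG_UNDEFINED = "undefined"

_NDOC_COLUMNS = ("chrom", "start", "end", "parent_mean", "recomb_mean", "ndoc", "flag")


def window_means(
    coverage: pd.DataFrame,
    layout: GenomeLayout,
    window_bp: int = 1000,
    step_bp: int = 1000,
) -> pd.DataFrame:
    """Mean depth per window tiling each chromosome from position 1.

    The last window may be shorter and is averaged over its actual span.
    Returns columns chrom, start, end (1-based inclusive), mean_depth.
    """
    if window_bp < 1 or step_bp < 1:
        raise ValueError("window_bp and step_bp must be >= 1")
    frames = []
    for chrom, length in layout.chromosomes:
        depth = np.zeros(length, dtype=float)
        sub = coverage[coverage["chrom"] == chrom]
        if len(sub):
            pos = sub["pos"].to_numpy(int)
            if pos.min() < 1 or pos.max() > length:
                raise ValueError(f"coverage position outside chromosome {chrom} (length {length})")
            depth[pos - 1] = sub["depth"].to_numpy(float)
        csum = np.concatenate(([0.0], np.cumsum(depth)))
        starts = np.arange(1, length + 1, step_bp, dtype=int)
        ends = np.minimum(starts + window_bp - 1, length)
        sums = csum[ends] - csum[starts - 1]
        spans = ends - starts + 1
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "mean_depth": sums / spans})
        )
    return pd.concat(frames, ignore_index=True)


def normalize(parent_windows: pd.DataFrame, recomb_windows: pd.DataFrame) -> pd.DataFrame:
    """Per-window NDoC = recombinant mean depth / parent mean depth.

    The two window grids must be identical; windows with zero parent depth
    get an undefined NDoC (NaN).
    """
    for col in ("chrom", "start", "end"):
        if len(parent_windows) != len(recomb_windows) or not (
            parent_windows[col].to_numpy() == recomb_windows[col].to_numpy()
        ).all():
            raise ValueError("parent and recombinant window grids differ")
    parent_mean = parent_windows["mean_depth"].to_numpy(float)
    recomb_mean = recomb_windows["mean_depth"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndoc = np.where(parent_mean > 0, recomb_mean / parent_mean, np.nan)
    return pd.DataFrame(
        {
            "chrom": parent_windows["chrom"].to_numpy(),
            "start": parent_windows["start"].to_numpy(int),
            "end": parent_windows["end"].to_numpy(int),
            "parent_mean": parent_mean,
            "recomb_mean": recomb_mean,
            "ndoc": ndoc,
        }
    )


def flag_cnv(
    windows: pd.DataFrame,
    loss_threshold: float = 0.5,
    gain_threshold: float = 1.5,
) -> pd.DataFrame:
    """Flag windows as loss (NDoC < loss_threshold) or gain (> gain_threshold).

    Strict inequalities: boundary values flag as none.  Windows with
    undefined NDoC flag as undefined.
    """
    if loss_threshold >= gain_threshold:
        raise ValueError("loss_threshold must be below gain_threshold")
    ndoc = windows["ndoc"].to_numpy(float)
    flag = np.full(len(windows), FLAG_NONE, dtype=object)
    flag[np.isnan(ndoc)] = FLAG_UNDEFINED
    flag[ndoc < loss_threshold] = FLAG_LOSS
    flag[ndoc > gain_threshold] = FLAG_GAIN
    out = windows.copy()
    out["flag"] = flag
    return out


def ndoc_windows(
    parent_coverage: pd.DataFrame,
    recomb_coverage: pd.DataFrame,
    layout: GenomeLayout,
    window_bp: int = 1000,
    step_bp: int = 1000,
    loss_threshold: float = 0.5,
    gain_threshold: float = 1.5,
) -> pd.DataFrame:
    """Window, normalize and flag in one call."""
    parent = window_means(parent_coverage, layout, window_bp, step_bp)
    recomb = window_means(recomb_coverage, layout, window_bp, step_bp)
    return flag_cnv(normalize(parent, recomb), loss_threshold, gain_threshold)


def normalized_filename(sample: str, legacy: bool = False) -> str:
    """Default NDoC output name; ``legacy`` selects the depthofCove alias."""
    return f"{sample}_depthofCove.txt" if legacy else f"{sample}_normalized1KB.txt"


def write_ndoc_file(windows: pd.DataFrame, path: str | Path) -> None:
    """Write the per-window NDoC table as TSV with a single header line."""
    out = windows.loc[:, list(_NDOC_COLUMNS)].copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ndoc_file(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(_NDOC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
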