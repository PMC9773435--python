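"""Genome-wide recombination profile with the NDoC overlay.

One horizontal panel per chromosome (x = position in bp), strains stacked as
bands.  Markers are drawn as vertical lines colored by status: gray for
invariant genotypes, red for LOH toward ratio 0, blue for LOH toward ratio
1, black for heterozygous recombination events (and for ploidy-change
candidates left unresolved by coverage).  NDoC windows flagged as potential
losses are drawn as orange dots, gains as green dots, above the marker
track.

Figures serialize deterministically (fixed SVG hash salt, no embedded
date), so tests assert on the vector output's elements rather than pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .io_formats import GenomeLayout
from .marker_compare import MarkerCall
from .ndoc import FLAG_GAIN, FLAG_LOSS

DEFAULT_STATUS_COLORS = {
    "invariant": "#808080",
    "LOH_0": "#ff0000",
    "LOH_1": "#0000ff",
    "het_change": "#000000",
    # unresolved ploidy-change candidates are drawn as heterozygous changes
    "ploidy_change_candidate": "#000000",
}

DEFAULT_NDOC_COLORS = {FLAG_LOSS: "#ffa500", FLAG_GAIN: "#008000"}


@dataclass(frozen=True)
class PlotStyle:
    status_colors: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_STATUS_COLORS))
    ndoc_colors: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_NDOC_COLORS))
    band_height: float = 0.6
    dot_size: float = 12.0
    panel_height: float = 1.1
    panel_width: float = 10.0


def _validate(calls_by_strain: Mapping[str, Sequence[MarkerCall]], layout: GenomeLayout, style: PlotStyle) -> None:
    names = set(layout.names)
    for strain, calls in calls_by_strain.items():
        for c in calls:
            if c.status not in style.status_colors:
                raise ValueError(f"no color defined for marker status {c.status!r} (strain {strain})")
            if c.chrom not in names:
                raise ValueError(f"marker on unknown chromosome {c.chrom!r} (strain {strain})")


def plot_profile(
    calls,
    windows: pd.DataFrame | None,
    layout: GenomeLayout,
    style: PlotStyle | None = None,
    out: str | Path | None = None,
):
    """Render the per-chromosome recombination profile; returns the figure.

    ``calls`` is either a single sequence of :class:`MarkerCall` or a mapping
    of strain name to calls (strains are stacked in input order).  When
    ``out`` is given the figure is also saved there (.svg/.pdf/.png by
    extension).
    """
    style = style or PlotStyle()
    if isinstance(calls, Mapping):
        calls_by_strain = dict(calls)
    else:
        calls_by_strain = {"sample": list(calls)}
    _validate(calls_by_strain, layout, style)

    n_chrom = len(layout.chromosomes)
    n_strains = max(len(calls_by_strain), 1)
    fig, axes = plt.subplots(
        n_chrom,
        1,
        figsize=(style.panel_width, style.panel_height * n_chrom * max(n_strains, 1) * 0.7 + 1),
        squeeze=False,
        constrained_layout=True,
    )
    max_len = max(l for _, l in layout.chromosomes)

    for ci, (chrom, length) in enumerate(layout.chromosomes):
        ax = axes[ci][0]
        for si, (strain, strain_calls) in enumerate(calls_by_strain.items()):
            y0 = float(si)
            chrom_calls = [c for c in strain_calls if c.chrom == chrom]
            by_status: dict[str, list[int]] = {}
            for c in chrom_calls:
                by_status.setdefault(c.status, []).append(c.pos)
            for status in sorted(by_status):
                ax.vlines(
                    by_status[status],
                    y0,
                    y0 + style.band_height,
                    colors=style.status_colors[status],
                    linewidth=0.8,
                )
        if windows is not None and "flag" in windows.columns:
            sub = windows[windows["chrom"] == chrom]
            y_dots = float(n_strains) - 1 + style.band_height + 0.25
            for flag, color in style.ndoc_colors.items():
                flagged = sub[sub["flag"] == flag]
                if len(flagged):
                    mid = (flagged["start"].to_numpy(float) + flagged["end"].to_numpy(float)) / 2
                    ax.scatter(mid, [y_dots] * len(mid), s=style.dot_size, c=color, zorder=3)
        ax.set_xlim(0, max_len)
        ax.axvline(length, color="#d0d0d0", linewidth=0.5)
        ax.set_ylim(-0.3, n_strains - 1 + style.band_height + 0.6)
        ax.set_yticks([si + style.band_height / 2 for si in range(n_strains)])
        ax.set_yticklabels(list(calls_by_strain))
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
    axes[-1][0].set_xlabel("position (bp)")

    if out is not None:
        save_figure(fig, out)
    return fig


def save_figure(fig, out: str | Path) -> None:
    """Save deterministically: fixed SVG hash salt, no embedded date."""
    out = Path(out)
    with matplotlib.rc_context({"svg.hashsalt": "ugdr"}):
        if out.suffix.lower() == ".svg":
            fig.savefig(out, metadata={"Date": None})
        else:
            fig.savefig(out)
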