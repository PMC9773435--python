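"""End-to-end orchestration: filter, pair, segment, corroborate, report.

``run_in_memory`` wires the stages together on parsed inputs and is what the
tests and the recovery harness drive; ``run_files`` adds the file I/O around
it (reads the two VCFs and coverage tables, writes the named output files, a
genome profile plot and a reproducibility manifest).

Window flags keep the conventional 0.5 / 1.5 NDoC cutoffs; candidate
arbitration (both marker-level gating and region-level resolution) defaults
to the ploidy-aware midpoints (p−0.5)/p and (p+0.5)/p, because a single
whole-chromosome gain moves the expected NDoC to (p+1)/p — e.g. 4/3 in a
triploid — which the fixed 1.5 cutoff would never reach for p > 2.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io_formats import (
    GenomeLayout,
    layout_from_doc,
    layout_from_vcf,
    read_doc,
    read_vcf,
    write_alleles_file,
    write_regions_file,
)
from .marker_compare import (
    MarkerCall,
    filter_records,
    mean_depth,
    pair_markers,
    write_variant_invariant_files,
)
from .ndoc import ndoc_windows, normalized_filename, write_ndoc_file
from .ratio_model import FilterThresholds, PloidyModel
from .region_caller import MarkerTrack, RecombinationRegion, attach_ndoc, build_tracks, call_regions

logger = logging.getLogger("ugdr")


@dataclass
class PipelineResult:
    """Everything the pipeline derived from one parent/recombinant pair."""

    model: PloidyModel
    thresholds: FilterThresholds
    layout: GenomeLayout
    parent_kept: list
    recomb_kept: list
    calls: list[MarkerCall]
    tracks: list[MarkerTrack]
    regions: list[RecombinationRegion]
    windows: pd.DataFrame
    stats: dict = field(default_factory=dict)


def arbitration_thresholds(ploidy: int) -> tuple[float, float]:
    """(loss, gain) NDoC midpoints between ploidy p and p∓1 copy states."""
    return (ploidy - 0.5) / ploidy, (ploidy + 0.5) / ploidy


def run_in_memory(
    parent_records,
    recomb_records,
    parent_coverage: pd.DataFrame,
    recomb_coverage: pd.DataFrame,
    layout: GenomeLayout,
    *,
    ploidy: int,
    theta: float = 0.04,
    thresholds: FilterThresholds | None = None,
    window_bp: int = 1000,
    step_bp: int = 1000,
    flag_loss: float = 0.5,
    flag_gain: float = 1.5,
    min_variant: int = 4,
    max_invariant_gap: int = 2,
    ndoc_loss: float | None = None,
    ndoc_gain: float | None = None,
) -> PipelineResult:
    """Run the full marker/region/NDoC analysis on parsed inputs."""
    model = PloidyModel(ploidy, theta)
    thresholds = thresholds or FilterThresholds()
    if ndoc_loss is None or ndoc_gain is None:
        default_loss, default_gain = arbitration_thresholds(ploidy)
        ndoc_loss = default_loss if ndoc_loss is None else ndoc_loss
        ndoc_gain = default_gain if ndoc_gain is None else ndoc_gain

    parent_mean = mean_depth(parent_coverage) if len(parent_coverage) else float(thresholds.ao_reference_coverage)
    recomb_mean = mean_depth(recomb_coverage) if len(recomb_coverage) else float(thresholds.ao_reference_coverage)
    parent_kept = filter_records(parent_records, thresholds, parent_mean)
    recomb_kept = filter_records(recomb_records, thresholds, recomb_mean)

    windows = ndoc_windows(
        parent_coverage, recomb_coverage, layout, window_bp, step_bp, flag_loss, flag_gain
    )

    stats: dict = {}
    calls = pair_markers(
        parent_kept,
        recomb_records,
        recomb_coverage,
        model,
        thresholds,
        recomb_mean_dp=recomb_mean,
        ndoc_windows=windows,
        gain_gate=ndoc_gain,
        loss_gate=ndoc_loss,
        stats=stats,
    )
    tracks = build_tracks(calls)
    regions: list[RecombinationRegion] = []
    for track in tracks:
        regions.extend(
            attach_ndoc(call_regions(track, min_variant, max_invariant_gap), windows, ndoc_loss, ndoc_gain)
        )
    regions.sort(key=lambda g: (layout.rank(g.chrom) if g.chrom in layout.names else len(layout.names), g.start))
    stats["regions"] = len(regions)
    stats["parent_mean_depth"] = parent_mean
    stats["recomb_mean_depth"] = recomb_mean
    return PipelineResult(
        model=model,
        thresholds=thresholds,
        layout=layout,
        parent_kept=parent_kept,
        recomb_kept=recomb_kept,
        calls=calls,
        tracks=tracks,
        regions=regions,
        windows=windows,
        stats=stats,
    )


def run_files(
    parent_vcf: str | Path,
    recomb_vcf: str | Path,
    parent_doc: str | Path,
    recomb_doc: str | Path,
    out_dir: str | Path,
    *,
    ploidy: int,
    sample_name: str = "sample",
    layout: GenomeLayout | None = None,
    plot: bool = True,
    legacy_ndoc_name: bool = False,
    **kwargs,
) -> PipelineResult:
    """Read the four inputs, analyse, and write the named output files.

    Outputs in ``out_dir``: parental_alleles.txt, recombined_alleles.txt,
    variant_alleles.txt, invariant_alleles.txt, regions_of_recombination.txt,
    <sample>_normalized1KB.txt, <sample>_profile.svg and manifest.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    parent_records = read_vcf(parent_vcf)
    recomb_records = read_vcf(recomb_vcf)
    parent_coverage = read_doc(parent_doc)
    recomb_coverage = read_doc(recomb_doc)
    if layout is None:
        try:
            layout = layout_from_vcf(parent_vcf)
        except ValueError:
            layout = layout_from_doc(parent_coverage)

    result = run_in_memory(
        parent_records,
        recomb_records,
        parent_coverage,
        recomb_coverage,
        layout,
        ploidy=ploidy,
        **kwargs,
    )

    write_alleles_file(result.parent_kept, "parental", out_dir / "parental_alleles.txt", layout)
    write_alleles_file(result.recomb_kept, "recombined", out_dir / "recombined_alleles.txt", layout)
    write_variant_invariant_files(
        result.calls, out_dir / "variant_alleles.txt", out_dir / "invariant_alleles.txt"
    )
    write_regions_file(result.regions, out_dir / "regions_of_recombination.txt", layout)
    write_ndoc_file(result.windows, out_dir / normalized_filename(sample_name, legacy_ndoc_name))

    if plot:
        from .plotting import plot_profile

        plotted = [c for c in result.calls if c.status != "ambiguous"]
        fig = plot_profile({sample_name: plotted}, result.windows, layout, out=out_dir / f"{sample_name}_profile.svg")
        import matplotlib.pyplot as plt

        plt.close(fig)

    manifest = {
        "tool": "ugdr",
        "version": __version__,
        "python": platform.python_version(),
        "inputs": {
            "parent_vcf": str(parent_vcf),
            "recomb_vcf": str(recomb_vcf),
            "parent_doc": str(parent_doc),
            "recomb_doc": str(recomb_doc),
        },
        "parameters": {
            "ploidy": ploidy,
            "theta": result.model.theta,
            "min_dp": result.thresholds.min_dp,
            "min_qual": result.thresholds.min_qual,
            "min_ao": result.thresholds.min_ao,
            "ao_reference_coverage": result.thresholds.ao_reference_coverage,
            **{k: v for k, v in kwargs.items() if not hasattr(v, "__dict__")},
        },
        "stats": {k: v for k, v in result.stats.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8")
    return result
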