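"""Pair parent and recombinant markers and classify each pair.

Every filtered parent marker is looked up in the recombinant strain by
(chromosome, position, alternate allele).  A matched marker is classified by
where its recombinant ratio lands among the expected ratio-group centers; a
marker absent from the recombinant VCF but well covered there is imputed as
ratio 0 (variant callers are silent at homozygous-reference positions, so
LOH toward the reference allele is only visible through this imputation).
The pair is then labelled invariant, LOH_0, LOH_1, het_change, or — when the
recombinant ratio is only explicable by a center of an adjacent ploidy —
ploidy_change_candidate, pending corroboration by the normalized depth of
coverage.

Also houses the tetrad segregation classifier (2:2 / 4:0 / 3:1 ... counts of
the two parental genotypes across four spores).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlleleRecord
from .ratio_model import (
    EVENT_CHROM_GAIN,
    EVENT_CHROM_LOSS,
    NDOC_GAIN,
    NDOC_LOSS,
    NDOC_NONE,
    FilterThresholds,
    PloidyModel,
    RatioTransition,
    apply_filters,
    effective_ao_threshold,
    expected_groups,
    nearest_center,
)

logger = logging.getLogger("ugdr")

STATUS_INVARIANT = "invariant"
STATUS_LOH_0 = "LOH_0"
STATUS_LOH_1 = "LOH_1"
STATUS_HET_CHANGE = "het_change"
STATUS_PLOIDY_CANDIDATE = "ploidy_change_candidate"
STATUS_AMBIGUOUS = "ambiguous"

VARIANT_STATUSES = frozenset({STATUS_LOH_0, STATUS_LOH_1, STATUS_HET_CHANGE, STATUS_PLOIDY_CANDIDATE})

_VARIANT_INVARIANT_COLUMNS = ("chrom", "pos", "parent_ratio", "parent_center", "recomb_ratio", "recomb_center", "status")


@dataclass(frozen=True)
class MarkerCall:
    """A parent/recombinant-paired marker with its classification."""

    chrom: str
    pos: int
    alt_allele: str
    parent_ratio: float
    parent_center: float
    recomb_ratio: float | None
    recomb_center: float | None
    status: str
    matched_transition: RatioTransition | None = None


@dataclass(frozen=True)
class SegregationPattern:
    """Counts of alternate:reference genotypes across the four spores of a tetrad."""

    pattern: str | None  # e.g. "2:2"; None when a spore call is missing
    mendelian: bool | None

    @property
    def defined(self) -> bool:
        return self.pattern is not None


def mean_depth(coverage: pd.DataFrame) -> float:
    """Genome-wide mean per-base depth of a coverage table."""
    if len(coverage) == 0:
        raise ValueError("empty coverage table")
    return float(coverage["depth"].mean())


def filter_records(
    records: Iterable[AlleleRecord],
    thresholds: FilterThresholds,
    observed_mean_dp: float,
) -> list[AlleleRecord]:
    """Keep records passing the depth/QUAL/AO cutoffs (parent-side filtering)."""
    return [r for r in records if apply_filters(r, thresholds, observed_mean_dp).passed]


def cross_ploidy_centers(model: PloidyModel) -> tuple[float, ...]:
    """Centers of the adjacent ploidies (p−1, p+1) not already centers of p."""
    centers: list[float] = []
    for q in (model.ploidy - 1, model.ploidy + 1):
        if 1 <= q <= 4:
            for c in expected_groups(q):
                if c not in model.group_centers and c not in centers:
                    centers.append(c)
    return tuple(sorted(centers))


def classify_recombinant(ratio: float, model: PloidyModel) -> tuple[float | None, bool]:
    """Classify a recombinant ratio, preferring the strain's own ploidy.

    Returns ``(center, is_cross_ploidy)``.  Same-ploidy centers win whenever
    one is within θ (parsimony); only otherwise are the adjacent-ploidy
    centers consulted.  ``(None, False)`` means ambiguous.
    """
    own = model.classify(ratio)
    if own is not None:
        return own, False
    cross = nearest_center(ratio, cross_ploidy_centers(model), model.theta)
    if cross is not None:
        return cross, True
    return None, False


def label_marker(
    parent_center: float,
    recomb_center: float,
    transitions: Sequence[RatioTransition],
) -> tuple[str, RatioTransition | None]:
    """Label a center pair: invariant, a same-ploidy event, a ploidy-change
    candidate, or ambiguous when no enumerated transition explains it."""
    if parent_center == recomb_center:
        return STATUS_INVARIANT, None
    same = [
        t
        for t in transitions
        if t.from_center == parent_center and t.to_center == recomb_center and t.requires_ndoc == NDOC_NONE
    ]
    if same:
        t = same[0]
        return t.event_type, t
    cross = [
        t
        for t in transitions
        if t.from_center == parent_center and t.to_center == recomb_center and t.requires_ndoc != NDOC_NONE
    ]
    if cross:
        return STATUS_PLOIDY_CANDIDATE, cross[0]
    return STATUS_AMBIGUOUS, None


def _check_sorted(records: Sequence[AlleleRecord], label: str) -> None:
    seen: set[str] = set()
    last_chrom = None
    last_pos = -1
    for r in records:
        if r.chrom != last_chrom:
            if r.chrom in seen:
                raise ValueError(f"{label} records not grouped by chromosome (chromosome {r.chrom} reappears)")
            seen.add(r.chrom)
            last_chrom = r.chrom
            last_pos = -1
        if r.pos < last_pos:
            raise ValueError(f"{label} records not sorted by position at {r.chrom}:{r.pos}")
        last_pos = r.pos


def coverage_lookup(coverage: pd.DataFrame) -> dict[tuple[str, int], int]:
    """Per-base depth lookup keyed on (chrom, pos)."""
    return dict(zip(zip(coverage["chrom"], coverage["pos"].astype(int)), coverage["depth"].astype(int)))


def _window_ndoc_lookup(windows: pd.DataFrame):
    """Return a function (chrom, pos) -> NDoC of the covering window (nan if none)."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in windows.groupby("chrom", sort=False):
        by_chrom[chrom] = (
            sub["start"].to_numpy(int),
            sub["end"].to_numpy(int),
            sub["ndoc"].to_numpy(float),
        )

    def at(chrom: str, pos: int) -> float:
        entry = by_chrom.get(chrom)
        if entry is None:
            return float("nan")
        starts, ends, ndoc = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos > ends[i]:
            return float("nan")
        return float(ndoc[i])

    return at


def pair_markers(
    parent: Sequence[AlleleRecord],
    recomb: Sequence[AlleleRecord],
    recomb_coverage: pd.DataFrame,
    model: PloidyModel,
    thresholds: FilterThresholds,
    *,
    recomb_mean_dp: float | None = None,
    ndoc_windows: pd.DataFrame | None = None,
    gain_gate: float | None = None,
    loss_gate: float | None = None,
    stats: dict | None = None,
) -> list[MarkerCall]:
    """Pair each filtered parent marker with the recombinant strain and call it.

    ``parent`` must already be filtered; ``recomb`` is the *raw* record set,
    so that a position genuinely absent from the recombinant VCF (imputed as
    ratio 0 when its coverage there is at least ``min_dp``) can be told apart
    from one that is present but fails the quality cutoffs (dropped).  A
    matched record must pass the depth/QUAL filters, and the AO cutoff unless
    its ratio classifies to center 0.

    When ``ndoc_windows`` is given, ploidy-change candidates are kept only if
    the NDoC of the window covering the marker corroborates the direction the
    matched transition requires (above ``gain_gate`` resp. below
    ``loss_gate``, defaulting to the midpoints (p±0.5)/p); otherwise the
    marker is demoted to ambiguous.  Without windows, arbitration is left to
    the region level.
    """
    _check_sorted(parent, "parent")
    _check_sorted(recomb, "recombinant")
    if recomb_mean_dp is None:
        if len(recomb_coverage) > 0:
            recomb_mean_dp = mean_depth(recomb_coverage)
        elif recomb:
            recomb_mean_dp = float(np.mean([r.dp for r in recomb]))
        else:
            recomb_mean_dp = float(thresholds.ao_reference_coverage)
    p = model.ploidy
    if gain_gate is None:
        gain_gate = (p + 0.5) / p
    if loss_gate is None:
        loss_gate = (p - 0.5) / p

    rec_by_key = {(r.chrom, r.pos, r.alt_allele): r for r in recomb}
    depth_at = coverage_lookup(recomb_coverage)
    ndoc_at = _window_ndoc_lookup(ndoc_windows) if ndoc_windows is not None else None
    ao_cut = effective_ao_threshold(thresholds, recomb_mean_dp)

    calls: list[MarkerCall] = []
    n_parent_ambiguous = 0
    n_dropped_filters = 0
    n_dropped_coverage = 0
    for r in parent:
        if r.ratio is None:
            n_dropped_filters += 1
            continue
        parent_center = model.classify(r.ratio)
        if parent_center is None:
            n_parent_ambiguous += 1
            continue
        key = (r.chrom, r.pos, r.alt_allele)
        match = rec_by_key.get(key)
        if match is not None:
            if not apply_filters(match, thresholds, recomb_mean_dp, waive_ao=True):
                n_dropped_filters += 1
                continue
            if match.ratio is None:
                n_dropped_filters += 1
                continue
            recomb_center, _ = classify_recombinant(match.ratio, model)
            if recomb_center != 0.0 and match.ao < ao_cut:
                n_dropped_filters += 1
                continue
            if recomb_center is None:
                calls.append(
                    MarkerCall(r.chrom, r.pos, r.alt_allele, r.ratio, parent_center, match.ratio, None, STATUS_AMBIGUOUS)
                )
                continue
            status, transition = label_marker(parent_center, recomb_center, model.transitions)
            if status == STATUS_PLOIDY_CANDIDATE and ndoc_at is not None:
                nd = ndoc_at(r.chrom, r.pos)
                candidates = [
                    t
                    for t in model.transitions
                    if t.from_center == parent_center and t.to_center == recomb_center and t.requires_ndoc != NDOC_NONE
                ]
                picked = None
                if not math.isnan(nd):
                    for t in candidates:
                        if t.requires_ndoc == NDOC_GAIN and nd > gain_gate:
                            picked = t
                            break
                        if t.requires_ndoc == NDOC_LOSS and nd < loss_gate:
                            picked = t
                            break
                if picked is None:
                    status, transition = STATUS_AMBIGUOUS, None
                else:
                    transition = picked
            calls.append(
                MarkerCall(
                    r.chrom, r.pos, r.alt_allele, r.ratio, parent_center, match.ratio, recomb_center, status, transition
                )
            )
        else:
            depth = depth_at.get((r.chrom, r.pos), 0)
            if depth >= thresholds.min_dp:
                status, transition = label_marker(parent_center, 0.0, model.transitions)
                calls.append(
                    MarkerCall(r.chrom, r.pos, r.alt_allele, r.ratio, parent_center, 0.0, 0.0, status, transition)
                )
            else:
                n_dropped_coverage += 1
    if stats is not None:
        stats["parent_markers"] = len(parent)
        stats["parent_ambiguous"] = n_parent_ambiguous
        stats["dropped_filters"] = n_dropped_filters
        stats["dropped_low_coverage"] = n_dropped_coverage
        stats["calls"] = len(calls)
    return calls


def tetrad_segregation(
    spore_centers: Sequence[float | None],
    parent_heterozygous: bool = True,
) -> SegregationPattern:
    """Classify one marker's segregation across the four spores of a tetrad.

    Spore genotypes must be haploid centers (0 or 1).  A missing spore call
    leaves the pattern undefined.  Mendelian segregation is 2:2 at
    heterozygous parental sites and 4:0 (or 0:4) at homozygous ones; 3:1 and
    1:3 mark gene-conversion candidates.
    """
    if len(spore_centers) != 4:
        raise ValueError(f"a tetrad has four spores, got {len(spore_centers)} calls")
    if any(c is None for c in spore_centers):
        return SegregationPattern(None, None)
    if any(c not in (0, 1, 0.0, 1.0) for c in spore_centers):
        raise ValueError(f"spore centers must be 0 or 1, got {spore_centers}")
    n_alt = sum(1 for c in spore_centers if c == 1)
    pattern = f"{n_alt}:{4 - n_alt}"
    if parent_heterozygous:
        mendelian = pattern == "2:2"
    else:
        mendelian = pattern in ("4:0", "0:4")
    return SegregationPattern(pattern, mendelian)


def genotype_spores(
    marker_keys: Iterable[tuple[str, int, str]],
    spore_records: Sequence[AlleleRecord],
    spore_coverage: pd.DataFrame,
    thresholds: FilterThresholds,
    *,
    theta: float = 0.04,
    spore_mean_dp: float | None = None,
) -> dict[tuple[str, int, str], float | None]:
    """Haploid genotypes (0/1/None) of one spore at the hybrid's heterozygous markers.

    A marker is 1 when the spore's VCF carries it with a ratio classifying to
    1, 0 when the VCF lacks it but the spore is covered there (>= min_dp),
    and None (no call) otherwise.
    """
    model = PloidyModel(1, theta)
    if spore_mean_dp is None:
        spore_mean_dp = mean_depth(spore_coverage) if len(spore_coverage) else float(thresholds.ao_reference_coverage)
    rec_by_key = {(r.chrom, r.pos, r.alt_allele): r for r in spore_records}
    depth_at = coverage_lookup(spore_coverage)
    out: dict[tuple[str, int, str], float | None] = {}
    for key in marker_keys:
        match = rec_by_key.get(key)
        if match is not None and apply_filters(match, thresholds, spore_mean_dp, waive_ao=True).passed:
            out[key] = model.classify(match.ratio) if match.ratio is not None else None
        else:
            chrom, pos, _ = key
            out[key] = 0.0 if depth_at.get((chrom, pos), 0) >= thresholds.min_dp else None
    return out


def write_variant_invariant_files(
    calls: Sequence[MarkerCall],
    variants_path: str | Path,
    invariants_path: str | Path,
) -> None:
    """Write the variants / invariant alleles files (ambiguous calls go to neither)."""

    def _write(path, rows):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_VARIANT_INVARIANT_COLUMNS) + "\n")
            for c in rows:
                fh.write(
                    "\t".join(
                        [
                            c.chrom,
                            str(c.pos),
                            repr(float(c.parent_ratio)),
                            repr(float(c.parent_center)),
                            "NA" if c.recomb_ratio is None else repr(float(c.recomb_ratio)),
                            "NA" if c.recomb_center is None else repr(float(c.recomb_center)),
                            c.status,
                        ]
                    )
                    + "\n"
                )

    _write(variants_path, [c for c in calls if c.status in VARIANT_STATUSES])
    _write(invariants_path, [c for c in calls if c.status == STATUS_INVARIANT])
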