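"""Segment the per-marker variant/invariant track into recombined regions.

A region is a maximal run of ratio-variant markers: it grows while the next
variant marker is separated from the previous one by at most
``max_invariant_gap`` consecutive invariant markers, is trimmed so both ends
are variant, and is kept only when it holds at least ``min_variant`` variant
markers (defaults 2 and 4, i.e. "at least 4 adjacent variant alleles,
tolerating up to two invariant alleles between a pair of variant ones").
Adjacency is marker-index adjacency in the filtered track, not base-pair
distance.

``oracle_call_regions`` re-derives the same segmentation by exhaustive
enumeration of candidate sub-segments and exists for testing only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .marker_compare import (
    STATUS_AMBIGUOUS,
    STATUS_HET_CHANGE,
    STATUS_INVARIANT,
    STATUS_PLOIDY_CANDIDATE,
    VARIANT_STATUSES,
    MarkerCall,
)

GENERIC_VARIANT = "V"
GENERIC_INVARIANT = "I"

_INVARIANT_LABELS = frozenset({GENERIC_INVARIANT, STATUS_INVARIANT})
_VARIANT_LABELS = VARIANT_STATUSES | {GENERIC_VARIANT}
# fixed priority for breaking event-type majority ties, most specific first
_EVENT_PRIORITY = ("LOH_0", "LOH_1", "het_change", "ploidy_change_candidate", GENERIC_VARIANT)


def is_variant_label(label: str) -> bool:
    if label in _VARIANT_LABELS:
        return True
    if label in _INVARIANT_LABELS:
        return False
    raise ValueError(f"unknown marker label {label!r}")


@dataclass(frozen=True)
class MarkerTrack:
    """Ordered (position, label) markers of one chromosome; labels are
    'I'/'invariant' or a variant status ('V' for a generic variant)."""

    chrom: str
    markers: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple((int(p), str(s)) for p, s in self.markers))
        for (p1, _), (p2, _) in zip(self.markers, self.markers[1:]):
            if p2 <= p1:
                raise ValueError(f"track positions must be strictly increasing ({self.chrom}: {p1} then {p2})")
        for _, label in self.markers:
            is_variant_label(label)  # raises on unknown labels


@dataclass(frozen=True)
class RecombinationRegion:
    """A called recombined segment, delimited by its outermost variant markers."""

    chrom: str
    start: int
    end: int
    n_variant: int
    n_invariant_inside: int
    event_type: str
    mean_ndoc: float | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("region end precedes start")
        if self.n_variant < 1:
            raise ValueError("a region holds at least one variant marker")


def build_tracks(calls: Sequence[MarkerCall]) -> list[MarkerTrack]:
    """Per-chromosome tracks from marker calls; ambiguous calls are excluded
    entirely (treated as if filtered)."""
    grouped: dict[str, list[tuple[int, str]]] = {}
    for c in calls:
        if c.status == STATUS_AMBIGUOUS:
            continue
        grouped.setdefault(c.chrom, []).append((c.pos, c.status))
    return [MarkerTrack(chrom, tuple(markers)) for chrom, markers in grouped.items()]


def _dominant_event(statuses: Sequence[str]) -> str:
    counts = Counter(statuses)
    order = {s: i for i, s in enumerate(_EVENT_PRIORITY)}
    return max(counts, key=lambda s: (counts[s], -order.get(s, len(order))))


def call_regions(
    track: MarkerTrack,
    min_variant: int = 4,
    max_invariant_gap: int = 2,
) -> list[RecombinationRegion]:
    """Greedy left-to-right maximal segmentation of one chromosome's track."""
    if min_variant < 1:
        raise ValueError("min_variant must be >= 1")
    if max_invariant_gap < 0:
        raise ValueError("max_invariant_gap must be >= 0")

    regions: list[RecombinationRegion] = []
    variant_markers: list[tuple[int, str]] = []
    inside_invariant = 0
    pending_invariant = 0

    def close() -> None:
        nonlocal variant_markers, inside_invariant
        if len(variant_markers) >= min_variant:
            regions.append(
                RecombinationRegion(
                    chrom=track.chrom,
                    start=variant_markers[0][0],
                    end=variant_markers[-1][0],
                    n_variant=len(variant_markers),
                    n_invariant_inside=inside_invariant,
                    event_type=_dominant_event([s for _, s in variant_markers]),
                )
            )
        variant_markers = []
        inside_invariant = 0

    for pos, label in track.markers:
        if is_variant_label(label):
            if variant_markers and pending_invariant > max_invariant_gap:
                close()
            if variant_markers:
                inside_invariant += pending_invariant
            pending_invariant = 0
            variant_markers.append((pos, label))
        else:
            if variant_markers:
                pending_invariant += 1
    close()
    return regions


def oracle_call_regions(
    track: MarkerTrack,
    min_variant: int = 4,
    max_invariant_gap: int = 2,
) -> list[RecombinationRegion]:
    """Exhaustive re-derivation of :func:`call_regions` for tiny tracks.

    Enumerates every variant-bounded sub-segment whose internal invariant
    runs never exceed the gap and whose variant count meets the minimum,
    then keeps the segments not strictly contained in another valid one.
    """
    markers = track.markers
    if len(markers) > 20:
        raise ValueError("oracle_call_regions is for tracks of length <= 20")
    variant = [is_variant_label(s) for _, s in markers]

    valid: list[tuple[int, int]] = []
    n = len(markers)
    for i in range(n):
        if not variant[i]:
            continue
        n_v = 0
        run_i = 0
        ok = True
        for j in range(i, n):
            if variant[j]:
                n_v += 1
                run_i = 0
            else:
                run_i += 1
                if run_i > max_invariant_gap:
                    ok = False
            if not ok:
                break
            if variant[j] and n_v >= min_variant:
                valid.append((i, j))
    maximal = [
        (i, j)
        for i, j in valid
        if not any((i2 <= i and j <= j2 and (i2, j2) != (i, j)) for i2, j2 in valid)
    ]
    regions = []
    for i, j in sorted(maximal):
        statuses = [markers[k][1] for k in range(i, j + 1) if variant[k]]
        regions.append(
            RecombinationRegion(
                chrom=track.chrom,
                start=markers[i][0],
                end=markers[j][0],
                n_variant=len(statuses),
                n_invariant_inside=sum(1 for k in range(i, j + 1) if not variant[k]),
                event_type=_dominant_event(statuses),
            )
        )
    return regions


def attach_ndoc(
    regions: Iterable[RecombinationRegion],
    windows: pd.DataFrame,
    loss_threshold: float = 0.5,
    gain_threshold: float = 1.5,
) -> list[RecombinationRegion]:
    """Attach the mean NDoC of overlapping windows and resolve candidates.

    Ploidy-change candidate regions become ``chrom_gain`` when the mean NDoC
    exceeds ``gain_threshold``, ``chrom_loss`` below ``loss_threshold``, and
    are demoted to ``het_change`` when the coverage is neutral.  A candidate
    with no overlapping window stays unresolved (mean_ndoc None).
    """
    if loss_threshold >= gain_threshold:
        raise ValueError("loss_threshold must be below gain_threshold")
    out = []
    for region in regions:
        sub = windows[
            (windows["chrom"] == region.chrom)
            & (windows["end"] >= region.start)
            & (windows["start"] <= region.end)
        ]
        values = sub["ndoc"].dropna()
        mean = float(values.mean()) if len(values) else None
        event = region.event_type
        if event == STATUS_PLOIDY_CANDIDATE and mean is not None:
            if mean > gain_threshold:
                event = "chrom_gain"
            elif mean < loss_threshold:
                event = "chrom_loss"
            else:
                event = STATUS_HET_CHANGE
        out.append(replace(region, mean_ndoc=mean, event_type=event))
    return out
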