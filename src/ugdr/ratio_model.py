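"""Ploidy-dependent allele-ratio groups, the θ tolerance, marker filters and
the table of allowed ratio transitions.

At a marker with ``a`` alternate copies among ``p`` homologs the expected
allele ratio is ``a/p``, so each ploidy defines a small set of ratio-group
centers (diploid: 0, 0.5, 1; triploid: 0, 0.33, 0.67, 1; tetraploid adds
0.25 and 0.75).  Centers are rounded to two decimals so that printed values
like 0.33 and interval arithmetic agree exactly.  An observed ratio is
assigned to the unique center within ±θ of it, and is ambiguous otherwise;
the default θ = 0.04 is half the distance between the closest adjacent
centers across ploidies (0.25 vs 0.33, or 0.67 vs 0.75), which is where
ratio groups start to overlap.

Recombination and aneuploidy move a marker between centers.  The allowed
moves are enumerated by copy-number arithmetic: within a fixed total copy
number a heterozygous state (a, p) can convert to any other (a′, p),
reaching 0 (LOH toward reference), p (LOH toward the alternate) or another
heterozygous ratio; losing or gaining one homolog reaches (a′, p∓1) with
a′ ∈ {a−1, a} resp. {a, a+1}, and such a move is only credible when the
depth of coverage drops or rises accordingly (``requires_ndoc``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_PLOIDIES = (1, 2, 3, 4)
MAX_PLOIDY = 4
DEFAULT_THETA = 0.04

EVENT_INVARIANT = "invariant"
EVENT_LOH_0 = "LOH_0"
EVENT_LOH_1 = "LOH_1"
EVENT_HET_CHANGE = "het_change"
EVENT_CHROM_LOSS = "chrom_loss"
EVENT_CHROM_GAIN = "chrom_gain"

NDOC_NONE = "none"
NDOC_LOSS = "loss"
NDOC_GAIN = "gain"


def _check_ploidy(ploidy: int) -> None:
    if ploidy not in VALID_PLOIDIES:
        raise ValueError(f"ploidy must be one of {VALID_PLOIDIES} (at most {MAX_PLOIDY}n), got {ploidy!r}")


def expected_groups(ploidy: int) -> tuple[float, ...]:
    """Expected ratio-group centers {round(k/ploidy, 2) : k = 0..ploidy}."""
    _check_ploidy(ploidy)
    return tuple(round(k / ploidy, 2) for k in range(ploidy + 1))


def derive_theta(center_a: float, center_b: float) -> float:
    """Half the distance between two adjacent group centers.

    With the closest adjacent centers across ploidies, 0.25/0.33 or
    0.67/0.75, this yields the default tolerance 0.04.
    """
    if center_a == center_b:
        raise ValueError("centers must be distinct to derive a tolerance")
    return abs(center_a - center_b) / 2


@dataclass(frozen=True)
class RatioTransition:
    """One allowed move between ratio-group centers, with its copy-number reading."""

    from_center: float
    to_center: float
    from_copies: tuple[int, int]  # (alternate copies, total copies)
    to_copies: tuple[int, int]
    event_type: str
    requires_ndoc: str  # none | loss | gain

    def __post_init__(self) -> None:
        if round(self.from_copies[0] / self.from_copies[1], 2) != self.from_center:
            raise ValueError(f"from_center {self.from_center} inconsistent with copies {self.from_copies}")
        if round(self.to_copies[0] / self.to_copies[1], 2) != self.to_center:
            raise ValueError(f"to_center {self.to_center} inconsistent with copies {self.to_copies}")


def enumerate_transitions(ploidy: int) -> tuple[RatioTransition, ...]:
    """Exhaustively enumerate the allowed ratio transitions for one ploidy.

    Same-total moves from each heterozygous state (a, p), plus single-homolog
    losses and gains (the latter capped at total ploidy 4).  For haploids the
    only moves are the marker flips 1→0 and 0→1 (a spore either carries the
    alternate allele or does not).
    """
    _check_ploidy(ploidy)
    if ploidy == 1:
        return (
            RatioTransition(1.0, 0.0, (1, 1), (0, 1), EVENT_LOH_0, NDOC_NONE),
            RatioTransition(0.0, 1.0, (0, 1), (1, 1), EVENT_LOH_1, NDOC_NONE),
        )
    p = ploidy
    out: list[RatioTransition] = []
    for a in range(1, p):
        fc = round(a / p, 2)
        for a2 in range(0, p + 1):
            if a2 == a:
                continue
            if a2 == 0:
                event = EVENT_LOH_0
            elif a2 == p:
                event = EVENT_LOH_1
            else:
                event = EVENT_HET_CHANGE
            out.append(RatioTransition(fc, round(a2 / p, 2), (a, p), (a2, p), event, NDOC_NONE))
        if p - 1 >= 1:
            for a2 in (a - 1, a):
                if 0 <= a2 <= p - 1:
                    out.append(
                        RatioTransition(fc, round(a2 / (p - 1), 2), (a, p), (a2, p - 1), EVENT_CHROM_LOSS, NDOC_LOSS)
                    )
        if p + 1 <= MAX_PLOIDY:
            for a2 in (a, a + 1):
                out.append(
                    RatioTransition(fc, round(a2 / (p + 1), 2), (a, p), (a2, p + 1), EVENT_CHROM_GAIN, NDOC_GAIN)
                )
    return tuple(out)


def nearest_center(ratio: float, centers: Sequence[float], theta: float) -> float | None:
    """The unique center within ±theta of ``ratio``; ``None`` when no center
    qualifies or the two nearest qualifying centers tie exactly.

    Distances are rounded to nine decimals before the comparison so that the
    interval arithmetic behaves like the printed two-decimal quantities
    (0.29 is exactly on the 0.25 + θ boundary, not a hair past it)."""
    within = [c for c in centers if round(abs(ratio - c), 9) <= theta]
    if not within:
        return None
    if len(within) == 1:
        return within[0]
    ranked = sorted((round(abs(ratio - c), 9), c) for c in within)
    if ranked[0][0] < ranked[1][0]:
        return ranked[0][1]
    return None


@dataclass(frozen=True)
class PloidyModel:
    """Expected ratio-group centers and classification tolerance for one ploidy."""

    ploidy: int
    theta: float = DEFAULT_THETA
    group_centers: tuple[float, ...] = field(init=False)
    transitions: tuple[RatioTransition, ...] = field(init=False)

    def __post_init__(self) -> None:
        _check_ploidy(self.ploidy)
        centers = expected_groups(self.ploidy)
        min_gap = min(b - a for a, b in zip(centers, centers[1:]))
        if not (0 < self.theta) or 2 * self.theta >= min_gap:
            raise ValueError(
                f"theta={self.theta} invalid for ploidy {self.ploidy}: "
                f"intervals around centers must stay disjoint (need 0 < theta < {min_gap / 2})"
            )
        object.__setattr__(self, "group_centers", centers)
        object.__setattr__(self, "transitions", enumerate_transitions(self.ploidy))

    def classify(self, ratio: float) -> float | None:
        return classify_ratio(ratio, self)


def classify_ratio(ratio: float, model: PloidyModel) -> float | None:
    """Assign a ratio to the unique group center within ±θ, else ``None`` (ambiguous)."""
    if not (0.0 <= ratio <= 1.0):
        raise ValueError(f"ratio must be within [0, 1], got {ratio}")
    return nearest_center(ratio, model.group_centers, model.theta)


@dataclass(frozen=True)
class FilterThresholds:
    """Marker-quality cutoffs: minimum depth, site QUAL, and an AO floor
    stated at a reference coverage of 80x and rescaled to the sample's own
    genome-wide mean depth."""

    min_dp: int = 20
    min_qual: float = 200.0
    min_ao: int = 20
    ao_reference_coverage: int = 80

    def __post_init__(self) -> None:
        if min(self.min_dp, self.min_qual, self.min_ao) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.ao_reference_coverage <= 0:
            raise ValueError("ao_reference_coverage must be positive")


def effective_ao_threshold(thresholds: FilterThresholds, observed_mean_dp: float) -> int:
    """AO cutoff scaled proportionally from the reference coverage, floored at 5."""
    if observed_mean_dp < 0:
        raise ValueError("observed mean depth must be non-negative")
    scaled = math.ceil(thresholds.min_ao * observed_mean_dp / thresholds.ao_reference_coverage)
    return max(5, scaled)


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.passed


def apply_filters(
    record,
    thresholds: FilterThresholds,
    observed_mean_dp: float,
    *,
    waive_ao: bool = False,
) -> FilterResult:
    """Check one record against the depth, QUAL and AO cutoffs.

    Returns the first failing reason (``min_dp``, ``min_qual`` or ``min_ao``).
    The AO check can be waived for candidate LOH-to-reference positions,
    where AO is zero by construction.
    """
    if record.dp < thresholds.min_dp:
        return FilterResult(False, "min_dp")
    if record.qual is None or not (record.qual > thresholds.min_qual):
        return FilterResult(False, "min_qual")
    if not waive_ao and record.ao < effective_ao_threshold(thresholds, observed_mean_dp):
        return FilterResult(False, "min_ao")
    return FilterResult(True)
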