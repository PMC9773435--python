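"""Matched parent/recombinant fixtures with known planted events.

The generator emulates the data a FreeBayes + GATK DepthOfCoverage run
produces for a parent strain and a potentially recombined derivative.  At a
marker carrying ``a`` alternate copies among ``t`` local total copies (the
strain's ploidy, modified by any copy-number event) the total depth is
DP ~ Poisson(mean_depth · t / ploidy) and the alternate observations are
AO ~ Binomial(DP, a/t); an optional beta-binomial overdispersion knob
widens the ratio spread beyond pure counting noise.  Coverage tables are
independent per-base Poisson draws with the same local copy scaling.
Recombinant markers whose alternate copy count drops to zero are omitted
from the recombinant VCF — mimicking a variant caller's silence at
homozygous-reference sites — but remain covered in its depth table.  A
configurable fraction of sites is emitted with low QUAL in both strains
(locus-driven quality loss) to exercise the QUAL filter.

Everything is reproducible from the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlleleRecord, GenomeLayout
from .ratio_model import MAX_PLOIDY, enumerate_transitions

DEFAULT_LAYOUT = GenomeLayout((("chrI", 200_000), ("chrII", 150_000), ("chrIII", 100_000)))

EVENT_KINDS = (
    "LOH_0",
    "LOH_1",
    "het_change",
    "chrom_loss",
    "chrom_gain",
    "segmental_dup",
    "segmental_del",
)

# planted kind -> event type of the transition that must license it
_KIND_TO_TRANSITION_EVENT = {
    "LOH_0": "LOH_0",
    "LOH_1": "LOH_1",
    "het_change": "het_change",
    "chrom_loss": "chrom_loss",
    "segmental_del": "chrom_loss",
    "chrom_gain": "chrom_gain",
    "segmental_dup": "chrom_gain",
}

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PlantedEvent:
    """A ground-truth event: every marker in [start, end] moves from
    ``from_copies`` = (alt copies, total copies) to ``to_copies``."""

    kind: str
    chrom: str
    start: int
    end: int
    from_copies: tuple[int, int]
    to_copies: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid event interval {self.start}-{self.end}")


def event_for_kind(kind: str, ploidy: int, chrom: str, start: int, end: int) -> PlantedEvent:
    """Canonical copy change for a kind, starting from the (1, ploidy) state."""
    p = ploidy
    if kind == "LOH_0":
        copies = ((1, p), (0, p))
    elif kind == "LOH_1":
        copies = ((1, p), (p, p))
    elif kind == "het_change":
        if p < 3:
            raise ValueError("het_change needs ploidy >= 3 (diploids have a single heterozygous center)")
        copies = ((1, p), (2, p))
    elif kind in ("chrom_loss", "segmental_del"):
        if p < 2:
            raise ValueError(f"{kind} needs ploidy >= 2")
        copies = ((1, p), (1, p - 1))
    elif kind in ("chrom_gain", "segmental_dup"):
        if p + 1 > MAX_PLOIDY:
            raise ValueError(f"{kind} would exceed the {MAX_PLOIDY}n ploidy limit")
        copies = ((1, p), (2, p + 1))  # the alternate-bearing homolog is duplicated
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    return PlantedEvent(kind, chrom, start, end, *copies)


def _validate_events(events: Sequence[PlantedEvent], ploidy: int, layout: GenomeLayout) -> None:
    transitions = enumerate_transitions(ploidy)
    by_chrom: dict[str, list[PlantedEvent]] = {}
    for ev in events:
        if ev.chrom not in layout.names:
            raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
        if ev.end > layout.length(ev.chrom):
            raise ValueError(f"event {ev.kind} extends past the end of {ev.chrom}")
        if ev.from_copies[1] != ploidy:
            raise ValueError(f"event {ev.kind} starts from total copies {ev.from_copies[1]}, ploidy is {ploidy}")
        wanted = _KIND_TO_TRANSITION_EVENT[ev.kind]
        licensed = any(
            t.from_copies == ev.from_copies and t.to_copies == ev.to_copies and t.event_type == wanted
            for t in transitions
        )
        if not licensed:
            raise ValueError(
                f"event {ev.kind} {ev.from_copies}->{ev.to_copies} is not an allowed transition for ploidy {ploidy}"
            )
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start)
        for e1, e2 in zip(evs, evs[1:]):
            if e2.start <= e1.end:
                raise ValueError(f"overlapping events on {chrom}: {e1.kind} and {e2.kind}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated parent/recombinant pair."""

    seed: int = 0
    ploidy: int = 2
    layout: GenomeLayout = DEFAULT_LAYOUT
    marker_density: float = 2.0  # heterozygous markers per kb
    mean_depth: float = 80.0  # reads at baseline copy number
    events: tuple[PlantedEvent, ...] = ()
    low_qual_fraction: float = 0.02  # shared low-QUAL decoy sites
    low_qual_value: float = 50.0
    qual_value: float = 1000.0
    indel_fraction: float = 0.05
    overdispersion: float | None = None  # beta-binomial intraclass correlation, off by default

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.marker_density <= 0:
            raise ValueError("marker_density must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0 <= self.low_qual_fraction <= 1):
            raise ValueError("low_qual_fraction must be within [0, 1]")
        if self.overdispersion is not None and not (0 < self.overdispersion < 1):
            raise ValueError("overdispersion must be in (0, 1)")
        _validate_events(self.events, self.ploidy, self.layout)


@dataclass
class SimulatedPair:
    """In-memory fixture pair plus the truth table (and file paths when written)."""

    config: SimulationConfig
    parent_records: list[AlleleRecord]
    recomb_records: list[AlleleRecord]
    parent_coverage: pd.DataFrame
    recomb_coverage: pd.DataFrame
    truth: pd.DataFrame
    parent_genotypes: list[tuple[int, int]]
    recomb_genotypes: list[tuple[int, int]]
    paths: dict[str, Path] | None = None


def _sample_ao(rng: np.random.Generator, dp: np.ndarray, prob: np.ndarray, rho: float | None) -> np.ndarray:
    if rho is None:
        return rng.binomial(dp, prob)
    # beta-binomial with mean prob and intraclass correlation rho
    conc = (1 - rho) / rho
    alpha = np.maximum(prob * conc, 1e-9)
    beta = np.maximum((1 - prob) * conc, 1e-9)
    p_draw = rng.beta(alpha, beta)
    return rng.binomial(dp, p_draw)


def _marker_positions(rng: np.random.Generator, length: int, density: float) -> np.ndarray:
    n = int(round(length / 1000 * density))
    n = min(n, length)
    pos = rng.choice(length, size=n, replace=False) + 1
    pos.sort()
    return pos


def _alleles(rng: np.random.Generator, n: int, indel_fraction: float) -> tuple[list[str], list[str]]:
    refs, alts = [], []
    base_idx = rng.integers(0, 4, size=n)
    shift = rng.integers(1, 4, size=n)
    is_indel = rng.random(n) < indel_fraction
    extra_idx = rng.integers(0, 4, size=n)
    for i in range(n):
        ref = _BASES[base_idx[i]]
        alt = _BASES[(base_idx[i] + shift[i]) % 4]
        if is_indel[i]:
            alt = alt + _BASES[extra_idx[i]]
        refs.append(ref)
        alts.append(alt)
    return refs, alts


def simulate_pair(config: SimulationConfig, out_dir: str | Path | None = None) -> SimulatedPair:
    """Generate a parent/recombinant pair with the configured planted events.

    Returns in-memory records, coverage tables and a truth table; when
    ``out_dir`` is given the VCFs, coverage tables and truth are also
    written there (parent.vcf, recomb.vcf, parent.doc, recomb.doc,
    truth.tsv) and the paths recorded on the result.
    """
    rng = np.random.default_rng(config.seed)
    p = config.ploidy

    parent_records: list[AlleleRecord] = []
    recomb_records: list[AlleleRecord] = []
    parent_gts: list[tuple[int, int]] = []
    recomb_gts: list[tuple[int, int]] = []
    truth_rows: list[dict] = []
    cov_frames_parent = []
    cov_frames_recomb = []

    for chrom, length in config.layout.chromosomes:
        events = sorted((e for e in config.events if e.chrom == chrom), key=lambda e: e.start)
        positions = _marker_positions(rng, length, config.marker_density)
        n = len(positions)
        refs, alts = _alleles(rng, n, config.indel_fraction)

        parent_a = np.ones(n, dtype=int) if p <= 2 else rng.integers(1, p, size=n)
        recomb_a = parent_a.copy()
        recomb_t = np.full(n, p, dtype=int)
        kind = np.array([""] * n, dtype=object)
        for ev in events:
            inside = (positions >= ev.start) & (positions <= ev.end)
            parent_a[inside] = ev.from_copies[0]
            recomb_a[inside] = ev.to_copies[0]
            recomb_t[inside] = ev.to_copies[1]
            kind[inside] = ev.kind

        low_qual = rng.random(n) < config.low_qual_fraction
        qual = np.where(low_qual, config.low_qual_value, config.qual_value)

        parent_dp = rng.poisson(config.mean_depth, size=n)
        parent_ao = _sample_ao(rng, parent_dp, parent_a / p, config.overdispersion)
        recomb_dp = rng.poisson(config.mean_depth * recomb_t / p)
        recomb_ao = _sample_ao(rng, recomb_dp, np.where(recomb_t > 0, recomb_a / np.maximum(recomb_t, 1), 0.0), config.overdispersion)

        for i in range(n):
            pos = int(positions[i])
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": refs[i],
                    "alt": alts[i],
                    "parent_a": int(parent_a[i]),
                    "parent_total": p,
                    "recomb_a": int(recomb_a[i]),
                    "recomb_total": int(recomb_t[i]),
                    "parent_center": round(int(parent_a[i]) / p, 2),
                    "recomb_center": round(int(recomb_a[i]) / int(recomb_t[i]), 2) if recomb_t[i] > 0 else None,
                    "event_kind": kind[i],
                }
            )
            if parent_dp[i] > 0 and parent_ao[i] > 0:
                parent_records.append(
                    AlleleRecord.from_counts(chrom, pos, refs[i], alts[i], int(parent_ao[i]), int(parent_dp[i]), float(qual[i]))
                )
                parent_gts.append((int(parent_a[i]), p))
            if recomb_a[i] > 0 and recomb_dp[i] > 0 and recomb_ao[i] > 0:
                recomb_records.append(
                    AlleleRecord.from_counts(chrom, pos, refs[i], alts[i], int(recomb_ao[i]), int(recomb_dp[i]), float(qual[i]))
                )
                recomb_gts.append((int(recomb_a[i]), int(recomb_t[i])))

        # per-base coverage: baseline copies for the parent, event-scaled for the recombinant
        recomb_copies = np.full(length, p, dtype=float)
        for ev in events:
            recomb_copies[ev.start - 1 : ev.end] = ev.to_copies[1]
        parent_depth = rng.poisson(config.mean_depth, size=length)
        recomb_depth = rng.poisson(config.mean_depth * recomb_copies / p)
        base_pos = np.arange(1, length + 1, dtype=int)
        cov_frames_parent.append(pd.DataFrame({"chrom": chrom, "pos": base_pos, "depth": parent_depth}))
        cov_frames_recomb.append(pd.DataFrame({"chrom": chrom, "pos": base_pos, "depth": recomb_depth}))

    pair = SimulatedPair(
        config=config,
        parent_records=parent_records,
        recomb_records=recomb_records,
        parent_coverage=pd.concat(cov_frames_parent, ignore_index=True),
        recomb_coverage=pd.concat(cov_frames_recomb, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        parent_genotypes=parent_gts,
        recomb_genotypes=recomb_gts,
    )
    if out_dir is not None:
        pair.paths = write_pair(pair, out_dir)
    return pair


def _genotype_string(a: int, t: int) -> str:
    return "/".join(["1"] * a + ["0"] * (t - a)) if t > 0 else "."


def write_vcf(
    records: Sequence[AlleleRecord],
    layout: GenomeLayout,
    path: str | Path,
    sample_name: str = "sample",
    genotypes: Sequence[tuple[int, int]] | None = None,
) -> None:
    """Emit records as a single-sample VCF with FreeBayes-style AO/DP FORMAT keys."""
    if genotypes is not None and len(genotypes) != len(records):
        raise ValueError("one genotype per record required")
    lines = [
        "##fileformat=VCFv4.2",
        "##source=ugdr-synthetic",
    ]
    for name, length in layout.chromosomes:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">',
        "#" + "\t".join(["CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT", sample_name]),
    ]
    for i, r in enumerate(records):
        gt = _genotype_string(*genotypes[i]) if genotypes is not None else "./."
        qual = f"{r.qual:g}"
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    str(r.pos),
                    ".",
                    r.ref_allele,
                    r.alt_allele,
                    qual,
                    ".",
                    f"DP={r.dp};AO={r.ao}",
                    "GT:DP:AO",
                    f"{gt}:{r.dp}:{r.ao}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_doc(coverage: pd.DataFrame, path: str | Path) -> None:
    """Emit a coverage table in the GATK DepthOfCoverage per-locus dialect."""
    locus = coverage["chrom"].astype(str) + ":" + coverage["pos"].astype(str)
    pd.DataFrame({"Locus": locus, "Total_Depth": coverage["depth"].astype(int)}).to_csv(
        path, sep="\t", index=False
    )


def write_pair(pair: SimulatedPair, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "parent_vcf": out_dir / "parent.vcf",
        "recomb_vcf": out_dir / "recomb.vcf",
        "parent_doc": out_dir / "parent.doc",
        "recomb_doc": out_dir / "recomb.doc",
        "truth": out_dir / "truth.tsv",
    }
    layout = pair.config.layout
    write_vcf(pair.parent_records, layout, paths["parent_vcf"], "parent", pair.parent_genotypes)
    write_vcf(pair.recomb_records, layout, paths["recomb_vcf"], "recomb", pair.recomb_genotypes)
    write_doc(pair.parent_coverage, paths["parent_doc"])
    write_doc(pair.recomb_coverage, paths["recomb_doc"])
    pair.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


@dataclass
class SimulatedTetrad:
    """Four haploid spores of one meiosis, with ground-truth segregation."""

    config: SimulationConfig
    spore_records: list[list[AlleleRecord]]
    spore_coverage: list[pd.DataFrame]
    truth: pd.DataFrame
    paths: dict[str, Path] | None = None


def make_tetrad(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    crossovers_per_chrom: int = 1,
    conversion_fraction: float = 0.0,
) -> SimulatedTetrad:
    """Simulate the four spores of a diploid hybrid's meiosis.

    Every heterozygous marker segregates 2:2 by default; reciprocal
    crossovers exchange spore haplotypes at random breakpoints (conserving
    the 2:2 counts) and a configurable fraction of markers undergoes gene
    conversion in one spore, producing 3:1 or 1:3 patterns.  Spores are
    emitted as haploid VCFs carrying only their alternate markers.
    """
    if config.ploidy != 2:
        raise ValueError("tetrads are simulated from a diploid hybrid parent")
    if not (0 <= conversion_fraction <= 1):
        raise ValueError("conversion_fraction must be within [0, 1]")
    rng = np.random.default_rng(config.seed)

    spore_records: list[list[AlleleRecord]] = [[] for _ in range(4)]
    cov_frames: list[list[pd.DataFrame]] = [[] for _ in range(4)]
    truth_rows: list[dict] = []

    for chrom, length in config.layout.chromosomes:
        positions = _marker_positions(rng, length, config.marker_density)
        n = len(positions)
        refs, alts = _alleles(rng, n, config.indel_fraction)
        low_qual = rng.random(n) < config.low_qual_fraction
        qual = np.where(low_qual, config.low_qual_value, config.qual_value)

        # haplotype of each spore along the chromosome: start 2x hapA, 2x hapB
        haps = np.zeros((4, n), dtype=int)  # 0 = hapA (carries alt), 1 = hapB
        haps[2] = 1
        haps[3] = 1
        breakpoints = np.sort(rng.integers(1, length + 1, size=crossovers_per_chrom))
        for bp in breakpoints:
            tail = positions >= bp
            a_spores = [s for s in range(4) if haps[s, tail.argmax()] == 0] if tail.any() else []
            b_spores = [s for s in range(4) if s not in a_spores]
            if not tail.any() or not a_spores or not b_spores:
                continue
            sa = a_spores[rng.integers(0, len(a_spores))]
            sb = b_spores[rng.integers(0, len(b_spores))]
            haps[sa, tail], haps[sb, tail] = haps[sb, tail].copy(), haps[sa, tail].copy()

        carries_alt = haps == 0
        convert = rng.random(n) < conversion_fraction
        conv_spore = rng.integers(0, 4, size=n)
        for i in np.nonzero(convert)[0]:
            carries_alt[conv_spore[i], i] = not carries_alt[conv_spore[i], i]

        for s in range(4):
            dp = rng.poisson(config.mean_depth, size=n)
            for i in range(n):
                if carries_alt[s, i] and dp[i] > 0:
                    spore_records[s].append(
                        AlleleRecord.from_counts(chrom, int(positions[i]), refs[i], alts[i], int(dp[i]), int(dp[i]), float(qual[i]))
                    )
            base_pos = np.arange(1, length + 1, dtype=int)
            cov_frames[s].append(
                pd.DataFrame({"chrom": chrom, "pos": base_pos, "depth": rng.poisson(config.mean_depth, size=length)})
            )

        for i in range(n):
            centers = tuple(1.0 if carries_alt[s, i] else 0.0 for s in range(4))
            n_alt = sum(int(c) for c in centers)
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": int(positions[i]),
                    "ref": refs[i],
                    "alt": alts[i],
                    "spore1": centers[0],
                    "spore2": centers[1],
                    "spore3": centers[2],
                    "spore4": centers[3],
                    "pattern": f"{n_alt}:{4 - n_alt}",
                    "converted": bool(convert[i]),
                    "low_qual": bool(low_qual[i]),
                }
            )

    tetrad = SimulatedTetrad(
        config=config,
        spore_records=spore_records,
        spore_coverage=[pd.concat(frames, ignore_index=True) for frames in cov_frames],
        truth=pd.DataFrame(truth_rows),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for s in range(4):
            paths[f"spore{s + 1}_vcf"] = out_dir / f"spore{s + 1}.vcf"
            write_vcf(tetrad.spore_records[s], config.layout, paths[f"spore{s + 1}_vcf"], f"spore{s + 1}")
            paths[f"spore{s + 1}_doc"] = out_dir / f"spore{s + 1}.doc"
            write_doc(tetrad.spore_coverage[s], paths[f"spore{s + 1}_doc"])
        paths["truth"] = out_dir / "truth.tsv"
        tetrad.truth.to_csv(paths["truth"], sep="\t", index=False)
        tetrad.paths = paths
    return tetrad


def recovery_harness(
    kind: str,
    ploidy: int = 3,
    n_seeds: int = 100,
    base_seed: int = 0,
    chrom_length: int = 60_000,
    event_span: tuple[int, int] = (20_001, 35_000),
    marker_density: float = 2.0,
    mean_depth: float = 80.0,
) -> dict:
    """Plant one event per simulation and measure how well the pipeline recovers it.

    Interstitial kinds are planted over ``event_span`` (15 kb, ~30 markers at
    the default density); whole-chromosome kinds (chrom_gain/chrom_loss) span
    the chromosome.  An event counts as recovered when at least one called
    region overlaps it; breakpoints count as exact when every overlapping
    region starts and ends on planted-event marker positions.  Regions not
    overlapping the event are false positives (feeding precision).
    """
    from .pipeline import run_in_memory

    layout = GenomeLayout((("chrI", chrom_length),))
    if kind in ("chrom_gain", "chrom_loss"):
        event = event_for_kind(kind, ploidy, "chrI", 1, chrom_length)
    else:
        event = event_for_kind(kind, ploidy, "chrI", *event_span)
    recovered = 0
    exact = 0
    kind_matched = 0
    false_regions = 0
    true_regions = 0
    for i in range(n_seeds):
        config = SimulationConfig(
            seed=base_seed + i,
            ploidy=ploidy,
            layout=layout,
            marker_density=marker_density,
            mean_depth=mean_depth,
            events=(event,),
        )
        pair = simulate_pair(config)
        result = run_in_memory(
            pair.parent_records,
            pair.recomb_records,
            pair.parent_coverage,
            pair.recomb_coverage,
            layout,
            ploidy=ploidy,
        )
        event_positions = set(pair.truth.loc[pair.truth["event_kind"] == kind, "pos"])
        overlapping = [r for r in result.regions if r.end >= event.start and r.start <= event.end]
        false_regions += len(result.regions) - len(overlapping)
        true_regions += len(overlapping)
        if overlapping:
            recovered += 1
            if all(r.start in event_positions and r.end in event_positions for r in overlapping):
                exact += 1
            if any(r.event_type == _KIND_TO_TRANSITION_EVENT[kind] for r in overlapping):
                kind_matched += 1
    called = true_regions + false_regions
    return {
        "kind": kind,
        "n_seeds": n_seeds,
        "sensitivity": recovered / n_seeds,
        "breakpoint_exact_rate": exact / n_seeds,
        "kind_match_rate": kind_matched / n_seeds,
        "precision": true_regions / called if called else float("nan"),
        "false_regions": false_regions,
    }


def read_events_table(path: str | Path, ploidy: int) -> tuple[PlantedEvent, ...]:
    """Parse a planted-events TSV (kind, chrom, start, end[, from_a, from_total, to_a, to_total])."""
    df = pd.read_csv(path, sep="\t")
    required = {"kind", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: events table needs columns {sorted(required)}")
    events = []
    explicit = {"from_a", "from_total", "to_a", "to_total"}.issubset(df.columns)
    for _, row in df.iterrows():
        if explicit and not pd.isna(row["from_a"]):
            events.append(
                PlantedEvent(
                    str(row["kind"]),
                    str(row["chrom"]),
                    int(row["start"]),
                    int(row["end"]),
                    (int(row["from_a"]), int(row["from_total"])),
                    (int(row["to_a"]), int(row["to_total"])),
                )
            )
        else:
            events.append(event_for_kind(str(row["kind"]), ploidy, str(row["chrom"]), int(row["start"]), int(row["end"])))
    return tuple(events)
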