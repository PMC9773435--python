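"""Readers and writers for the pipeline's tabular input and output formats.

Inputs are a FreeBayes-style VCF per strain (site QUAL plus AO/DP counts in
either the single-sample FORMAT fields or INFO) and a GATK
DepthOfCoverage-style per-locus table (``chrom:pos`` locus, total depth).
Outputs are plain UTF-8 TSV files with a single header line: the parental /
recombined alleles files, and the region-of-recombination file.

All coordinates are 1-based and inclusive, as in VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger("ugdr")

SNP = "SNP"
INDEL = "indel"

_ALLELES_COLUMNS = ("chrom", "pos", "ref", "alt", "type", "AO", "DP", "QUAL", "ratio")
_REGIONS_COLUMNS = ("chrom", "start", "end", "n_variant_alleles", "event_type", "mean_ndoc")


@dataclass(frozen=True)
class AlleleRecord:
    """One polymorphic marker from one strain.

    ``ratio`` is AO/DP, the fraction of aligned reads supporting the
    alternate allele (the analogue of a B-allele frequency); it is ``None``
    when DP is zero.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_type: str
    ao: int
    dp: int
    qual: float
    ratio: float | None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ao < 0 or self.dp < 0:
            raise ValueError("AO and DP must be non-negative")
        if self.ao > self.dp:
            raise ValueError(f"AO ({self.ao}) exceeds DP ({self.dp}) at {self.chrom}:{self.pos}")

    @classmethod
    def from_counts(
        cls,
        chrom: str,
        pos: int,
        ref_allele: str,
        alt_allele: str,
        ao: int,
        dp: int,
        qual: float,
    ) -> "AlleleRecord":
        """Build a record, deriving ``variant_type`` and ``ratio`` from the counts."""
        variant_type = SNP if len(ref_allele) == 1 and len(alt_allele) == 1 else INDEL
        ratio = ao / dp if dp > 0 else None
        return cls(chrom, int(pos), ref_allele, alt_allele, variant_type, int(ao), int(dp), float(qual), ratio)


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths; fixes output and plotting order."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_lengths(cls, lengths: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths.items()))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length(self, name: str) -> int:
        for n, l in self.chromosomes:
            if n == name:
                return l
        raise KeyError(name)

    def rank(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(name) from None


def _chrom_sort_key(layout: GenomeLayout | None):
    if layout is None:
        return lambda chrom: (0, chrom)
    names = layout.names

    def key(chrom: str):
        try:
            return (0, names.index(chrom))
        except ValueError:
            return (1, chrom)

    return key


def read_vcf(
    path: str | Path,
    allow_multiallelic: bool = False,
    stats: dict | None = None,
) -> list[AlleleRecord]:
    """Parse a FreeBayes-style VCF into :class:`AlleleRecord` objects.

    AO/DP are taken from the per-sample FORMAT fields when the file carries a
    single sample, and from INFO otherwise.  Multi-sample files are rejected.
    Multiallelic sites are skipped by default; with ``allow_multiallelic``
    the alternate allele with the largest AO is kept (ties: first listed).
    Records missing AO, DP or QUAL are skipped with a logged warning and
    counted in ``stats``.

    Records are returned sorted by (chromosome, position) using the header's
    contig order.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc

    samples = list(vcf.header.samples)
    if len(samples) > 1:
        raise ValueError(
            f"{path}: multi-sample VCF ({len(samples)} samples); one VCF per strain is required"
        )
    sample = samples[0] if samples else None
    contig_rank = {name: i for i, name in enumerate(vcf.header.contigs)}

    records: list[AlleleRecord] = []
    n_skipped = 0
    n_multiallelic_skipped = 0
    for i, rec in enumerate(vcf):
        try:
            alts = rec.alts
            if alts is None or len(alts) == 0:
                n_skipped += 1
                logger.warning("%s record %d (%s:%s): no alternate allele, skipped", path.name, i + 1, rec.chrom, rec.pos)
                continue
            ao, dp, alt = _extract_counts(rec, sample, alts, allow_multiallelic)
            if ao is None:
                if len(alts) > 1 and not allow_multiallelic:
                    n_multiallelic_skipped += 1
                    logger.warning(
                        "%s record %d (%s:%s): multiallelic site skipped", path.name, i + 1, rec.chrom, rec.pos
                    )
                else:
                    n_skipped += 1
                    logger.warning(
                        "%s record %d (%s:%s): missing AO/DP, skipped", path.name, i + 1, rec.chrom, rec.pos
                    )
                continue
            if rec.qual is None:
                n_skipped += 1
                logger.warning("%s record %d (%s:%s): missing QUAL, skipped", path.name, i + 1, rec.chrom, rec.pos)
                continue
            records.append(
                AlleleRecord.from_counts(rec.chrom, rec.pos, rec.ref, alt, min(ao, dp), dp, rec.qual)
            )
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"malformed VCF {path}, record {i + 1}: {exc}") from exc

    big = len(contig_rank)
    records.sort(key=lambda r: (contig_rank.get(r.chrom, big), r.chrom, r.pos))
    if stats is not None:
        stats["records"] = len(records)
        stats["skipped"] = n_skipped + n_multiallelic_skipped
        stats["multiallelic_skipped"] = n_multiallelic_skipped
    return records


def _extract_counts(rec, sample, alts, allow_multiallelic):
    """Return (AO, DP, alt) for one VCF record, or (None, None, None)."""
    if sample is not None:
        fields = rec.samples[sample]
        ao_values = fields.get("AO")
        dp = fields.get("DP")
    else:
        ao_values = rec.info.get("AO")
        dp = rec.info.get("DP")
    if ao_values is None or dp is None:
        return None, None, None
    if isinstance(ao_values, (int, float)):
        ao_values = (ao_values,)
    ao_values = [int(a) for a in ao_values]
    if isinstance(dp, (tuple, list)):
        dp = dp[0]
    dp = int(dp)
    if len(alts) == 1:
        return ao_values[0], dp, alts[0]
    if not allow_multiallelic:
        return None, None, None
    idx = max(range(len(ao_values)), key=lambda j: (ao_values[j], -j))
    return ao_values[idx], dp, alts[idx]


def read_doc(path: str | Path) -> pd.DataFrame:
    """Parse a GATK DepthOfCoverage per-locus table.

    Expects one header line and a tab-separated body whose first column is
    ``chrom:pos`` and whose second column is the total depth.  Returns a
    DataFrame with columns ``chrom`` (str), ``pos`` (int, 1-based) and
    ``depth`` (int), checked for strictly ascending positions within each
    chromosome.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 tab-separated columns")
    if len(df) == 0:
        return pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=int), "depth": pd.Series(dtype=int)})
    locus = df.iloc[:, 0].astype(str)
    parts = locus.str.rsplit(":", n=1, expand=True)
    bad = parts.shape[1] < 2
    if not bad:
        pos_ok = parts[1].fillna("").str.fullmatch(r"\d+")
        if not pos_ok.all():
            line_no = int(pos_ok.idxmin()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path} line {line_no}: unparsable locus {locus.iloc[int(pos_ok.idxmin())]!r}")
    else:
        raise ValueError(f"{path} line 2: unparsable locus {locus.iloc[0]!r}")
    depth = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if depth.isna().any():
        line_no = int(depth.isna().idxmax()) + 2
        raise ValueError(f"{path} line {line_no}: unparsable depth {df.iloc[:, 1].iloc[line_no - 2]!r}")
    out = pd.DataFrame(
        {
            "chrom": parts[0].astype(str),
            "pos": parts[1].astype(int),
            "depth": depth.astype(int),
        }
    )
    if (out["depth"] < 0).any():
        raise ValueError(f"{path}: negative depth values")
    # strictly ascending positions within each chromosome block
    same_chrom = out["chrom"].values[1:] == out["chrom"].values[:-1]
    non_increasing = out["pos"].values[1:] <= out["pos"].values[:-1]
    violation = same_chrom & non_increasing
    if violation.any():
        line_no = int(violation.argmax()) + 3
        raise ValueError(f"{path} line {line_no}: positions not sorted ascending within chromosome")
    return out


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_alleles_file(
    records: Iterable[AlleleRecord],
    role: str,
    path: str | Path,
    layout: GenomeLayout | None = None,
) -> None:
    """Write the parental/recombined alleles file (TSV, one header line).

    ``role`` must be ``"parental"`` or ``"recombined"`` and only documents the
    caller's intent; the format is identical.  Ordering is deterministic:
    chromosomes in ``layout`` order (lexicographic when no layout is given),
    then position, then alternate allele.
    """
    if role not in ("parental", "recombined"):
        raise ValueError(f"role must be 'parental' or 'recombined', got {role!r}")
    key = _chrom_sort_key(layout)
    ordered = sorted(records, key=lambda r: (key(r.chrom), r.pos, r.alt_allele))
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_ALLELES_COLUMNS) + "\n")
        for r in ordered:
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.pos),
                        r.ref_allele,
                        r.alt_allele,
                        r.variant_type,
                        str(r.ao),
                        str(r.dp),
                        _fmt(r.qual),
                        _fmt(r.ratio),
                    ]
                )
                + "\n"
            )


def read_alleles_file(path: str | Path) -> list[AlleleRecord]:
    """Read back a file produced by :func:`write_alleles_file` (lossless round-trip)."""
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _ALLELES_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            chrom, pos, ref, alt, vtype, ao, dp, qual, ratio = line.rstrip("\n").split("\t")
            rec = AlleleRecord(
                chrom,
                int(pos),
                ref,
                alt,
                vtype,
                int(ao),
                int(dp),
                float(qual),
                None if ratio == "NA" else float(ratio),
            )
            records.append(rec)
    return records


def write_regions_file(
    regions: Iterable,
    path: str | Path,
    layout: GenomeLayout | None = None,
) -> None:
    """Write the region-of-recombination file (chrom, start, end, marker count,
    dominant event type, mean NDoC)."""
    key = _chrom_sort_key(layout)
    ordered = sorted(regions, key=lambda g: (key(g.chrom), g.start, g.end))
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_REGIONS_COLUMNS) + "\n")
        for g in ordered:
            fh.write(
                "\t".join(
                    [g.chrom, str(g.start), str(g.end), str(g.n_variant), g.event_type, _fmt(g.mean_ndoc)]
                )
                + "\n"
            )


def layout_from_vcf(path: str | Path) -> GenomeLayout:
    """Derive a :class:`GenomeLayout` from the contig lines of a VCF header."""
    vcf = pysam.VariantFile(str(path))
    chroms = []
    for name, contig in vcf.header.contigs.items():
        if contig.length is None:
            raise ValueError(f"{path}: contig {name} has no length in the header")
        chroms.append((name, contig.length))
    if not chroms:
        raise ValueError(f"{path}: no contig lines in header")
    return GenomeLayout(tuple(chroms))


def layout_from_doc(coverage: pd.DataFrame) -> GenomeLayout:
    """Derive a layout from a coverage table (chromosome length = last covered position)."""
    if len(coverage) == 0:
        raise ValueError("empty coverage table")
    chroms = []
    for chrom in coverage["chrom"].unique():
        chroms.append((chrom, int(coverage.loc[coverage["chrom"] == chrom, "pos"].max())))
    return GenomeLayout(tuple(chroms))
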