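from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ugdr.io_formats import AlleleRecord, GenomeLayout

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chrI,length=30000>
##contig=<ID=chrII,length=20000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate observations">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate observations">
"""


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout((("chrI", 30000), ("chrII", 20000)))


@pytest.fixture
def write_vcf_text(tmp_path):
    """Write a VCF from header + body lines; returns the path."""

    def _write(body_lines, name="test.vcf", sample="s1", with_sample_column=True):
        path = tmp_path / name
        if with_sample_column:
            columns = f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
        else:
            columns = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        path.write_text(VCF_HEADER + columns + "".join(line + "\n" for line in body_lines))
        return path

    return _write


def make_record(
    chrom="chrI",
    pos=100,
    ref="A",
    alt="T",
    ao=40,
    dp=80,
    qual=900.0,
) -> AlleleRecord:
    return AlleleRecord.from_counts(chrom, pos, ref, alt, ao, dp, qual)


def uniform_coverage(layout: GenomeLayout, depth: int = 80) -> pd.DataFrame:
    frames = []
    for chrom, length in layout.chromosomes:
        frames.append(
            pd.DataFrame({"chrom": chrom, "pos": np.arange(1, length + 1), "depth": depth})
        )
    return pd.concat(frames, ignore_index=True)
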