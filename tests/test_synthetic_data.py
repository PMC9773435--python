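from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ugdr.io_formats import GenomeLayout, read_doc, read_vcf
from ugdr.marker_compare import genotype_spores, tetrad_segregation
from ugdr.ratio_model import FilterThresholds
from ugdr.synthetic_data import (
    PlantedEvent,
    SimulationConfig,
    event_for_kind,
    make_tetrad,
    read_events_table,
    simulate_pair,
)

SMALL = GenomeLayout((("chrI", 30_000), ("chrII", 20_000)))


class TestConfigValidation:
    def test_overlapping_events_rejected(self):
        events = (
            event_for_kind("LOH_0", 3, "chrI", 1000, 6000),
            event_for_kind("LOH_1", 3, "chrI", 5000, 9000),
        )
        with pytest.raises(ValueError, match="overlap"):
            SimulationConfig(ploidy=3, layout=SMALL, events=events)

    def test_event_must_match_an_allowed_transition(self):
        bad = PlantedEvent("het_change", "chrI", 1000, 2000, (1, 3), (3, 3))
        with pytest.raises(ValueError, match="allowed transition"):
            SimulationConfig(ploidy=3, layout=SMALL, events=(bad,))

    def test_het_change_needs_two_het_centers(self):
        with pytest.raises(ValueError, match="ploidy"):
            event_for_kind("het_change", 2, "chrI", 1, 100)

    def test_gain_beyond_tetraploid_rejected(self):
        with pytest.raises(ValueError, match="4n"):
            event_for_kind("chrom_gain", 4, "chrI", 1, 100)


class TestSimulatePair:
    def test_deterministic_from_seed(self, tmp_path):
        config = SimulationConfig(seed=42, ploidy=3, layout=SMALL, events=(event_for_kind("LOH_0", 3, "chrI", 5000, 15000),))
        a = simulate_pair(config, tmp_path / "a")
        b = simulate_pair(config, tmp_path / "b")
        for name in ("parent_vcf", "recomb_vcf", "parent_doc", "recomb_doc", "truth"):
            assert a.paths[name].read_bytes() == b.paths[name].read_bytes()

    def test_null_simulation_keeps_parent_centers(self):
        pair = simulate_pair(SimulationConfig(seed=1, ploidy=3, layout=SMALL))
        assert (pair.truth["recomb_center"] == pair.truth["parent_center"]).all()
        assert (pair.truth["event_kind"] == "").all()

    def test_planted_loh0_markers_in_truth(self):
        event = event_for_kind("LOH_0", 3, "chrI", 5000, 15000)
        pair = simulate_pair(SimulationConfig(seed=2, ploidy=3, layout=SMALL, events=(event,)))
        inside = pair.truth[pair.truth["event_kind"] == "LOH_0"]
        assert len(inside) > 0
        assert (inside["parent_center"] == 0.33).all() and (inside["recomb_center"] == 0.0).all()
        assert inside["pos"].between(5000, 15000).all()
        # homozygous-reference markers are silent in the recombinant VCF
        recomb_positions = {r.pos for r in pair.recomb_records if r.chrom == "chrI"}
        assert not (set(inside["pos"]) & recomb_positions)

    def test_sampled_ratios_center_on_truth(self):
        layout = GenomeLayout((("chrI", 300_000),))
        pair = simulate_pair(SimulationConfig(seed=3, ploidy=2, layout=layout, marker_density=2.0))
        ratios = np.array([r.ratio for r in pair.parent_records])
        assert len(ratios) >= 500
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.5) < 3 * se

    def test_emitted_files_parse_back_to_memory_records(self, tmp_path):
        config = SimulationConfig(seed=4, ploidy=2, layout=SMALL)
        pair = simulate_pair(config, tmp_path)
        assert read_vcf(pair.paths["parent_vcf"]) == pair.parent_records
        assert read_vcf(pair.paths["recomb_vcf"]) == pair.recomb_records
        doc = read_doc(pair.paths["parent_doc"])
        pd.testing.assert_frame_equal(doc, pair.parent_coverage)

    def test_coverage_tracks_local_copy_number(self):
        event = event_for_kind("chrom_gain", 3, "chrI", 1, 30_000)
        pair = simulate_pair(SimulationConfig(seed=5, ploidy=3, layout=SMALL, events=(event,)))
        gained = pair.recomb_coverage.loc[pair.recomb_coverage["chrom"] == "chrI", "depth"].mean()
        neutral = pair.recomb_coverage.loc[pair.recomb_coverage["chrom"] == "chrII", "depth"].mean()
        assert gained / neutral == pytest.approx(4 / 3, rel=0.03)


class TestMakeTetrad:
    def test_no_crossover_no_conversion_whole_haplotypes(self):
        config = SimulationConfig(seed=6, ploidy=2, layout=SMALL, low_qual_fraction=0.0)
        tetrad = make_tetrad(config, crossovers_per_chrom=0)
        assert (tetrad.truth["pattern"] == "2:2").all()
        # each spore carries either every marker of a chromosome or none of it
        for s, records in enumerate(tetrad.spore_records):
            for chrom in SMALL.names:
                n_markers = (tetrad.truth["chrom"] == chrom).sum()
                n_carried = sum(1 for r in records if r.chrom == chrom)
                assert n_carried in (0, n_markers)

    def test_crossover_conserves_two_two_segregation(self):
        config = SimulationConfig(seed=7, ploidy=2, layout=SMALL, low_qual_fraction=0.0)
        tetrad = make_tetrad(config, crossovers_per_chrom=1)
        assert (tetrad.truth["pattern"] == "2:2").all()
        # at least one spore switches haplotype along some chromosome
        switched = False
        for s in range(4):
            for chrom in SMALL.names:
                chrom_truth = tetrad.truth[tetrad.truth["chrom"] == chrom]
                carried = chrom_truth[f"spore{s + 1}"].to_numpy()
                if 0 < carried.sum() < len(carried):
                    switched = True
        assert switched

    def test_conversion_fraction_recovered(self):
        layout = GenomeLayout((("chrI", 500_000), ("chrII", 500_000)))
        config = SimulationConfig(seed=8, ploidy=2, layout=layout, marker_density=2.0, low_qual_fraction=0.0)
        tetrad = make_tetrad(config, crossovers_per_chrom=1, conversion_fraction=0.05)
        n = len(tetrad.truth)
        assert n >= 2000
        non_mendelian = (tetrad.truth["pattern"] != "2:2").mean()
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(non_mendelian - 0.05) < 3 * se

    def test_spore_genotypes_recover_truth_segregation(self):
        layout = GenomeLayout((("chrI", 30_000),))
        config = SimulationConfig(seed=9, ploidy=2, layout=layout, low_qual_fraction=0.0)
        tetrad = make_tetrad(config, crossovers_per_chrom=1, conversion_fraction=0.1)
        thresholds = FilterThresholds()
        genotypes = [
            genotype_spores(
                [(row.chrom, row.pos, row.alt) for row in tetrad.truth.itertuples()],
                tetrad.spore_records[s],
                tetrad.spore_coverage[s],
                thresholds,
            )
            for s in range(4)
        ]
        n_checked = 0
        for row in tetrad.truth.itertuples():
            key = (row.chrom, row.pos, row.alt)
            centers = tuple(genotypes[s][key] for s in range(4))
            if any(c is None for c in centers):
                continue
            pattern = tetrad_segregation(centers)
            assert pattern.pattern == row.pattern
            n_checked += 1
        assert n_checked >= 0.9 * len(tetrad.truth)

    def test_requires_diploid_parent(self):
        with pytest.raises(ValueError, match="diploid"):
            make_tetrad(SimulationConfig(ploidy=3, layout=SMALL))


def test_events_table_round_trip(tmp_path):
    path = tmp_path / "events.tsv"
    path.write_text("kind\tchrom\tstart\tend\nLOH_0\tchrI\t1000\t5000\nchrom_gain\tchrII\t1\t20000\n")
    events = read_events_table(path, ploidy=3)
    assert [e.kind for e in events] == ["LOH_0", "chrom_gain"]
    assert events[0].to_copies == (0, 3)
    assert events[1].to_copies == (2, 4)
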