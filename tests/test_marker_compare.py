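from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tests.conftest import make_record, uniform_coverage
from ugdr.io_formats import GenomeLayout
from ugdr.marker_compare import (
    STATUS_AMBIGUOUS,
    STATUS_HET_CHANGE,
    STATUS_INVARIANT,
    STATUS_LOH_0,
    STATUS_LOH_1,
    STATUS_PLOIDY_CANDIDATE,
    VARIANT_STATUSES,
    genotype_spores,
    label_marker,
    pair_markers,
    tetrad_segregation,
    write_variant_invariant_files,
)
from ugdr.ratio_model import FilterThresholds, PloidyModel


def coverage_df(entries):
    return pd.DataFrame(entries, columns=["chrom", "pos", "depth"])


class TestLabelMarker:
    def test_loh_to_alternate_in_diploid(self):
        model = PloidyModel(2)
        status, transition = label_marker(0.5, 1.0, model.transitions)
        assert status == STATUS_LOH_1 and transition.to_copies == (2, 2)

    def test_het_change_in_triploid(self):
        status, transition = label_marker(0.33, 0.67, PloidyModel(3).transitions)
        assert status == STATUS_HET_CHANGE and transition.to_copies == (2, 3)

    def test_cross_ploidy_center_is_candidate(self):
        status, transition = label_marker(0.33, 0.25, PloidyModel(3).transitions)
        assert status == STATUS_PLOIDY_CANDIDATE and transition.requires_ndoc == "gain"

    def test_equal_centers_invariant(self):
        assert label_marker(0.5, 0.5, PloidyModel(2).transitions) == (STATUS_INVARIANT, None)

    def test_inexplicable_pair_ambiguous(self):
        status, _ = label_marker(1.0, 0.5, PloidyModel(2).transitions)
        assert status == STATUS_AMBIGUOUS


def _diploid_parent(n=10, chrom="chrI"):
    return [make_record(chrom=chrom, pos=1000 * (i + 1), ao=40, dp=80, qual=900) for i in range(n)]


class TestPairMarkers:
    def test_identical_inputs_all_invariant(self):
        parent = _diploid_parent()
        cov = coverage_df([("chrI", r.pos, 80) for r in parent])
        calls = pair_markers(parent, parent, cov, PloidyModel(2), FilterThresholds(), recomb_mean_dp=80)
        assert len(calls) == len(parent)
        assert all(c.status == STATUS_INVARIANT for c in calls)

    def test_absent_with_ample_coverage_imputed_loh0(self):
        parent = _diploid_parent(1)
        cov = coverage_df([("chrI", parent[0].pos, 60)])
        (call,) = pair_markers(parent, [], cov, PloidyModel(2), FilterThresholds(), recomb_mean_dp=80)
        assert call.status == STATUS_LOH_0 and call.recomb_ratio == 0.0

    def test_absent_with_poor_coverage_dropped(self):
        parent = _diploid_parent(1)
        cov = coverage_df([("chrI", parent[0].pos, 8)])
        stats: dict = {}
        calls = pair_markers(parent, [], cov, PloidyModel(2), FilterThresholds(), recomb_mean_dp=80, stats=stats)
        assert calls == [] and stats["dropped_low_coverage"] == 1

    def test_low_coverage_fraction_of_fixture_dropped(self):
        parent = _diploid_parent(100)
        cov = coverage_df(
            [("chrI", r.pos, 8 if i < 10 else 60) for i, r in enumerate(parent)]
        )
        calls = pair_markers(parent, [], cov, PloidyModel(2), FilterThresholds(), recomb_mean_dp=80)
        assert len(calls) == 90

    def test_different_alt_treated_as_absent(self):
        parent = _diploid_parent(1)
        other_alt = make_record(pos=parent[0].pos, alt="G", ao=40, dp=80)
        cov = coverage_df([("chrI", parent[0].pos, 60)])
        (call,) = pair_markers(parent, [other_alt], cov, PloidyModel(2), FilterThresholds(), recomb_mean_dp=80)
        assert call.status == STATUS_LOH_0

    def test_matched_failing_filters_dropped_not_imputed(self):
        parent = _diploid_parent(1)
        low_qual = make_record(pos=parent[0].pos, ao=40, dp=80, qual=50)
        cov = coverage_df([("chrI", parent[0].pos, 80)])
        stats: dict = {}
        calls = pair_markers(parent, [low_qual], cov, PloidyModel(2), FilterThresholds(), recomb_mean_dp=80, stats=stats)
        assert calls == [] and stats["dropped_filters"] == 1

    def test_counts_partition_parent_markers(self):
        rng = np.random.default_rng(11)
        parent = []
        for i in range(200):
            dp = int(rng.poisson(80))
            ao = int(rng.binomial(dp, 0.5))
            parent.append(make_record(pos=100 * (i + 1), ao=min(ao, dp), dp=dp, qual=900))
        recomb = parent[:100]
        cov = coverage_df([("chrI", r.pos, 60 if i % 3 else 8) for i, r in enumerate(parent)])
        stats: dict = {}
        pair_markers(parent, recomb, cov, PloidyModel(2), FilterThresholds(), recomb_mean_dp=80, stats=stats)
        assert (
            stats["calls"]
            + stats["parent_ambiguous"]
            + stats["dropped_filters"]
            + stats["dropped_low_coverage"]
            == stats["parent_markers"]
        )

    def test_het_change_symmetric_under_swap(self):
        parent = [make_record(pos=1000, ao=27, dp=81, qual=900)]
        recomb = [make_record(pos=1000, ao=54, dp=81, qual=900)]
        cov = coverage_df([("chrI", 1000, 80)])
        model = PloidyModel(3)
        (forward,) = pair_markers(parent, recomb, cov, model, FilterThresholds(), recomb_mean_dp=80)
        (backward,) = pair_markers(recomb, parent, cov, model, FilterThresholds(), recomb_mean_dp=80)
        assert forward.status == backward.status == STATUS_HET_CHANGE
        assert (forward.parent_center, forward.recomb_center) == (backward.recomb_center, backward.parent_center)

    def test_unsorted_parent_rejected(self):
        parent = list(reversed(_diploid_parent(3)))
        with pytest.raises(ValueError, match="sorted"):
            pair_markers(parent, [], coverage_df([]), PloidyModel(2), FilterThresholds(), recomb_mean_dp=80)


class TestCandidateGating:
    def _inputs(self):
        parent = [make_record(pos=1500, ao=27, dp=81, qual=900)]
        recomb = [make_record(pos=1500, ao=27, dp=108, qual=900)]  # ratio 0.25
        cov = coverage_df([("chrI", 1500, 107)])
        return parent, recomb, cov

    def _windows(self, ndoc):
        return pd.DataFrame(
            {"chrom": ["chrI"], "start": [1001], "end": [2000], "ndoc": [ndoc], "flag": ["none"]}
        )

    def test_candidate_kept_when_coverage_corroborates(self):
        parent, recomb, cov = self._inputs()
        (call,) = pair_markers(
            parent, recomb, cov, PloidyModel(3), FilterThresholds(), recomb_mean_dp=80,
            ndoc_windows=self._windows(4 / 3),
        )
        assert call.status == STATUS_PLOIDY_CANDIDATE
        assert call.matched_transition.requires_ndoc == "gain"

    def test_candidate_demoted_when_coverage_neutral(self):
        parent, recomb, cov = self._inputs()
        (call,) = pair_markers(
            parent, recomb, cov, PloidyModel(3), FilterThresholds(), recomb_mean_dp=80,
            ndoc_windows=self._windows(1.0),
        )
        assert call.status == STATUS_AMBIGUOUS

    def test_candidate_kept_without_windows(self):
        parent, recomb, cov = self._inputs()
        (call,) = pair_markers(parent, recomb, cov, PloidyModel(3), FilterThresholds(), recomb_mean_dp=80)
        assert call.status == STATUS_PLOIDY_CANDIDATE


class TestTetradSegregation:
    def test_two_two_is_mendelian_at_het_sites(self):
        pattern = tetrad_segregation((1.0, 1.0, 0.0, 0.0))
        assert pattern.pattern == "2:2" and pattern.mendelian

    def test_four_zero_is_mendelian_at_homozygous_sites(self):
        pattern = tetrad_segregation((1.0, 1.0, 1.0, 1.0), parent_heterozygous=False)
        assert pattern.pattern == "4:0" and pattern.mendelian

    def test_three_one_marks_gene_conversion(self):
        pattern = tetrad_segregation((1.0, 1.0, 1.0, 0.0))
        assert pattern.pattern == "3:1" and not pattern.mendelian

    def test_missing_spore_call_undefined(self):
        pattern = tetrad_segregation((1.0, None, 0.0, 0.0))
        assert not pattern.defined and pattern.mendelian is None

    def test_wrong_spore_count_rejected(self):
        with pytest.raises(ValueError, match="four"):
            tetrad_segregation((1.0, 0.0))


class TestGenotypeSpores:
    def test_present_absent_and_nocall(self):
        keys = [("chrI", 100, "T"), ("chrI", 200, "T"), ("chrI", 300, "T")]
        records = [make_record(pos=100, ao=78, dp=80, qual=900)]
        cov = coverage_df([("chrI", 100, 80), ("chrI", 200, 75), ("chrI", 300, 5)])
        genotypes = genotype_spores(keys, records, cov, FilterThresholds(), spore_mean_dp=80)
        assert genotypes[keys[0]] == 1.0
        assert genotypes[keys[1]] == 0.0
        assert genotypes[keys[2]] is None


def test_variant_invariant_files_partition_calls(tmp_path):
    parent = _diploid_parent(6)
    recomb = [
        make_record(pos=r.pos, ao=r.dp if i < 2 else 40, dp=r.dp, qual=900) for i, r in enumerate(parent)
    ]
    cov = coverage_df([("chrI", r.pos, 80) for r in parent])
    calls = pair_markers(parent, recomb, cov, PloidyModel(2), FilterThresholds(), recomb_mean_dp=80)
    v_path, i_path = tmp_path / "variants.tsv", tmp_path / "invariant.tsv"
    write_variant_invariant_files(calls, v_path, i_path)
    n_variant = len(v_path.read_text().splitlines()) - 1
    n_invariant = len(i_path.read_text().splitlines()) - 1
    assert n_variant == sum(c.status in VARIANT_STATUSES for c in calls) == 2
    assert n_invariant == sum(c.status == STATUS_INVARIANT for c in calls) == 4
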