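import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from swatcna import (
    MRI,
    ClassificationTable,
    cluster_samples,
    consensus_merge,
    intersect_prioritizations,
    region_heatmap_matrix,
)
from swatcna.regions import CRI

from conftest import make_probe_matrix


def _mri(chrom, start_bp, end_bp, direction="gain"):
    return MRI(chrom, direction, 0, 0, start_bp, end_bp, 0.5, 3)


class TestConsensusMerge:
    def test_overlapping_mris_pool_across_methods(self):
        merged = consensus_merge(
            {"A": [_mri("1", 100, 200)], "B": [_mri("1", 150, 250)]}, min_methods=2
        )
        assert len(merged) == 1
        region = merged[0]
        assert (region.start_bp, region.end_bp) == (100, 250)
        assert region.methods == frozenset({"A", "B"})

    def test_single_method_region_dropped(self):
        merged = consensus_merge(
            {"A": [_mri("1", 100, 200)], "B": [_mri("2", 100, 200)]}, min_methods=2
        )
        assert merged == []

    def test_opposite_directions_never_merge(self):
        merged = consensus_merge(
            {"A": [_mri("1", 100, 200, "gain")], "B": [_mri("1", 150, 250, "loss")]},
            min_methods=1,
        )
        assert len(merged) == 2

    def test_transitive_pooling(self):
        merged = consensus_merge(
            {
                "A": [_mri("1", 100, 200)],
                "B": [_mri("1", 180, 300)],
                "C": [_mri("1", 290, 400)],
            },
            min_methods=3,
        )
        assert len(merged) == 1
        assert (merged[0].start_bp, merged[0].end_bp) == (100, 400)

    def test_order_independence(self):
        lists = {
            "A": [_mri("1", 100, 200), _mri("2", 50, 80)],
            "B": [_mri("2", 60, 90), _mri("1", 150, 250)],
        }
        reversed_lists = {k: list(reversed(v)) for k, v in reversed(lists.items())}
        a = consensus_merge(lists, 2)
        b = consensus_merge(reversed_lists, 2)
        assert [(r.chromosome, r.start_bp, r.end_bp) for r in a] == [
            (r.chromosome, r.start_bp, r.end_bp) for r in b
        ]

    def test_fewer_than_two_methods_rejected(self):
        with pytest.raises(ValueError, match="2 methods"):
            consensus_merge({"A": []}, 2)


class TestIntersectPrioritizations:
    def test_region_in_both_lists_kept(self):
        amp = consensus_merge({"A": [_mri("1", 100, 200)], "B": [_mri("1", 150, 250)]}, 2)
        gdw = consensus_merge({"A": [_mri("1", 190, 260)], "B": [_mri("1", 195, 240)]}, 2)
        final = intersect_prioritizations(amp, gdw)
        assert len(final) == 1
        assert final[0].in_amplitude_list and final[0].in_gdw_list

    def test_amplitude_only_region_dropped(self):
        amp = consensus_merge({"A": [_mri("1", 100, 200)], "B": [_mri("1", 150, 250)]}, 2)
        gdw = consensus_merge({"A": [_mri("2", 100, 200)], "B": [_mri("2", 120, 220)]}, 2)
        assert intersect_prioritizations(amp, gdw) == []

    def test_empty_gdw_list_empties_final(self):
        amp = consensus_merge({"A": [_mri("1", 100, 200)], "B": [_mri("1", 150, 250)]}, 2)
        assert intersect_prioritizations(amp, []) == []


def _cri(chrom, lo, hi, at, direction="gain", index=1):
    return CRI(chrom, direction, lo, hi, lo * 100_000, hi * 100_000 + 60,
               index, 80.0, 3, at=at)


class TestClusterSamples:
    def _planted_cohort(self, noise=0.0, n_per_group=4, seed=0):
        """Three sample subgroups with distinct CNA profiles on 60 probes."""
        rng = np.random.default_rng(seed)
        n = 3 * n_per_group
        calls = np.zeros((60, n), dtype=np.int8)
        groups = np.repeat([0, 1, 2], n_per_group)
        calls[5:15, groups == 0] = 1
        calls[25:35, groups == 1] = -1
        calls[45:55, groups == 2] = 2
        table = ClassificationTable(
            calls=pd.DataFrame(calls, columns=[f"S{i}" for i in range(n)])
        )
        cris = [_cri("1", 5, 14, 80.0), _cri("1", 25, 34, 80.0, "loss"), _cri("1", 45, 54, 70.0)]
        return table, cris, groups

    def test_recovers_planted_subgroups(self):
        table, cris, truth = self._planted_cohort()
        result = cluster_samples(table, cris, min_at=40.0, n_groups=3)
        assert adjusted_rand_score(truth, result.labels.to_numpy()) == 1.0

    def test_invariant_under_sample_permutation(self):
        table, cris, truth = self._planted_cohort()
        rng = np.random.default_rng(1)
        perm = rng.permutation(table.calls.shape[1])
        permuted = ClassificationTable(calls=table.calls.iloc[:, perm])
        a = cluster_samples(table, cris, n_groups=3).labels
        b = cluster_samples(permuted, cris, n_groups=3).labels
        # same partition up to relabelling
        assert adjusted_rand_score(a[b.index].to_numpy(), b.to_numpy()) == 1.0

    def test_identical_samples_zero_height_tree(self):
        calls = np.ones((20, 4), dtype=np.int8)
        table = ClassificationTable(calls=pd.DataFrame(calls, columns=list("abcd")))
        result = cluster_samples(table, [_cri("1", 0, 19, 80.0)], n_groups=1)
        assert result.linkage_matrix[:, 2].max() == 0.0
        assert result.n_groups == 1

    def test_low_at_cris_excluded_from_features(self):
        table, cris, _ = self._planted_cohort()
        cris[0].at = 20.0  # below the 40% stringency floor
        result = cluster_samples(table, cris, min_at=40.0, n_groups=3)
        assert not np.isin(np.arange(5, 15), result.feature_probes).any()

    def test_no_stringent_cri_is_an_error(self):
        table, cris, _ = self._planted_cohort()
        for c in cris:
            c.at = 20.0
        with pytest.raises(ValueError, match="adaptive threshold"):
            cluster_samples(table, cris, min_at=40.0)

    def test_newick_export_contains_all_samples(self):
        table, cris, _ = self._planted_cohort()
        result = cluster_samples(table, cris, n_groups=3)
        newick = result.to_newick()
        assert all(s in newick for s in table.sample_ids)


class TestRegionHeatmapMatrix:
    def _table(self, calls):
        return ClassificationTable(
            calls=pd.DataFrame(np.asarray(calls, dtype=np.int8),
                               columns=[f"S{i}" for i in range(np.asarray(calls).shape[1])])
        )

    def test_fraction_arithmetic(self):
        # 10 probes, 1 sample per scenario: all gain, half gain, 30% gain/20% loss
        calls = np.zeros((10, 3), dtype=int)
        calls[:, 0] = 1
        calls[:5, 1] = 1
        calls[:3, 2] = 1
        calls[3:5, 2] = -1
        pm = make_probe_matrix(np.zeros((10, 3), dtype=float))
        table = self._table(calls)
        matrix = region_heatmap_matrix(table, [_cri("1", 0, 9, 80.0)], pm)
        np.testing.assert_allclose(matrix.iloc[0].to_numpy(), [1.0, 0.5, 0.1])

    def test_empty_region_list_rejected(self):
        pm = make_probe_matrix(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="no regions"):
            region_heatmap_matrix(self._table(np.zeros((5, 2), dtype=int)), [], pm)
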