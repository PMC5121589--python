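"""ANCOVA with age covariate and cluster-based permutation tests."""

import numpy as np
import pytest

from alphaband.cohort import build_source_grid
from alphaband.errors import DegenerateModelError, ParameterError
from alphaband.group_stats import (ancova_group_effect,
                                   cluster_permutation_test,
                                   run_contrast_battery)

GRID4 = build_source_grid(4, 10.0)


class TestAncova:
    def test_pure_covariate_signal(self):
        rng = np.random.default_rng(0)
        groups = np.repeat(["a", "b", "c"], 30)
        age = rng.normal(70, 4, 90)
        vals = 2.0 * age + rng.normal(0, 1e-6, 90)
        res = ancova_group_effect(vals, groups, age)
        assert res.p_value > 0.05
        assert res.age_coefficient == pytest.approx(2.0, abs=1e-3)

    def test_separated_groups_and_tukey(self):
        rng = np.random.default_rng(1)
        groups = np.repeat(["a", "b", "c"], 30)
        age = rng.normal(70, 4, 90)
        vals = np.concatenate([rng.normal(0, 0.1, 30), rng.normal(0, 0.1, 30),
                               rng.normal(1, 0.1, 30)])
        res = ancova_group_effect(vals, groups, age)
        assert res.p_value < 0.05
        assert res.pairwise[("a", "c")] < 0.05
        assert res.pairwise[("b", "c")] < 0.05
        assert res.pairwise[("a", "b")] > 0.05

    def test_type_one_error_calibration(self):
        """Null rejection rate of the group factor stays near 5%."""
        rng = np.random.default_rng(2)
        groups = np.repeat(["a", "b", "c"], 20)
        age = rng.normal(70, 4, 60)
        rejections = sum(
            ancova_group_effect(rng.standard_normal(60), groups, age).p_value < 0.05
            for _ in range(1000)
        )
        assert abs(rejections / 1000 - 0.05) <= 0.02

    def test_constant_response_rejected(self):
        groups = np.repeat(["a", "b"], 5)
        with pytest.raises(DegenerateModelError):
            ancova_group_effect(np.ones(10), groups, np.arange(10.0))

    def test_tiny_group_rejected(self):
        groups = np.array(["a", "a", "a", "b", "b"])
        with pytest.raises(ParameterError, match="n >= 3"):
            ancova_group_effect(np.arange(5.0), groups, np.arange(5.0))


def _null_dataset(seed, n_per_group=20, n_sources=64):
    rng = np.random.default_rng(seed)
    maps = rng.standard_normal((2 * n_per_group, n_sources))
    groups = np.repeat(["a", "b"], n_per_group)
    age = rng.normal(70, 4, 2 * n_per_group)
    return maps, groups, age


class TestClusterPermutation:
    def test_deterministic_under_fixed_seed(self):
        maps, groups, age = _null_dataset(0)
        maps[20:, :8] += 0.8
        r1 = cluster_permutation_test(maps, groups, age, GRID4, n_perm=200, seed=9)
        r2 = cluster_permutation_test(maps, groups, age, GRID4, n_perm=200, seed=9)
        assert [(c[0], c[2]) for c in r1.clusters] == [(c[0], c[2]) for c in r2.clusters]

    def test_pvalue_floor(self):
        maps, groups, age = _null_dataset(1)
        maps[20:] += 2.5
        res = cluster_permutation_test(maps, groups, age, GRID4, n_perm=100, seed=0)
        assert res.clusters
        for _, _, p in res.clusters:
            assert p >= 1 / (100 + 1) - 1e-12

    def test_clusters_are_connected(self):
        maps, groups, age = _null_dataset(2)
        maps[20:, [0, 1, 4, 5, 63]] += 2.0
        res = cluster_permutation_test(maps, groups, age, GRID4, n_perm=100, seed=0)
        from scipy.sparse.csgraph import connected_components
        from scipy import sparse
        for members, _, _ in res.clusters:
            idx = list(members)
            sub = sparse.csr_matrix(GRID4.adjacency[np.ix_(idx, idx)])
            n_comp, _ = connected_components(sub, directed=False)
            assert n_comp == 1

    def test_relabeling_sources_is_equivariant(self):
        maps, groups, age = _null_dataset(3)
        maps[20:, :10] += 1.2
        res = cluster_permutation_test(maps, groups, age, GRID4, n_perm=300, seed=5)
        perm = np.random.default_rng(0).permutation(64)
        grid_p = build_source_grid(4, 10.0)
        grid_p.adjacency = GRID4.adjacency[np.ix_(perm, perm)]
        res_p = cluster_permutation_test(maps[:, perm], groups, age, grid_p,
                                         n_perm=300, seed=5)
        def canon(res, mapper):
            return sorted((tuple(sorted(mapper(m) for m in c[0])), round(c[2], 6))
                          for c in res.clusters)
        inv = np.argsort(perm)
        assert canon(res, lambda m: m) == canon(res_p, lambda m: int(perm[m]))

    def test_exact_enumeration_matches_monte_carlo(self):
        """Small-sample oracle: full label enumeration vs Monte-Carlo p-values."""
        grid = build_source_grid(3, 10.0)
        rng = np.random.default_rng(4)
        maps = rng.standard_normal((10, 27))
        maps[5:, :9] += 1.2
        groups = np.repeat(["a", "b"], 5)
        mc = cluster_permutation_test(maps, groups, None, grid, n_perm=500,
                                      seed=3, exact=False)
        ex = cluster_permutation_test(maps, groups, None, grid, exact=True)
        assert len(mc.clusters) == len(ex.clusters)
        for (m_mem, _, m_p), (e_mem, _, e_p) in zip(mc.clusters, ex.clusters):
            assert m_mem == e_mem
            assert abs(m_p - e_p) <= 2 / np.sqrt(500)

    def test_no_suprathreshold_sources_is_not_an_error(self):
        maps = np.tile(np.arange(64.0), (40, 1))  # groups identical by column
        maps += np.random.default_rng(5).normal(0, 1e-9, maps.shape)
        groups = np.repeat(["a", "b"], 20)
        res = cluster_permutation_test(maps, groups, None, GRID4, n_perm=100, seed=0)
        assert not res.sig_mask.any()

    def test_missing_entries_and_coverage_filter(self):
        maps, groups, age = _null_dataset(6)
        maps[20:, :8] += 1.5
        maps[:30, 63] = np.nan          # 25% coverage: excluded
        maps[0, 10] = np.nan            # sporadic missing: subject dropped there
        res = cluster_permutation_test(maps, groups, age, GRID4, n_perm=200, seed=1)
        assert 63 not in res.tested_sources
        assert 10 in res.tested_sources
        assert np.isnan(res.statistic_map[63])


class TestBattery:
    def test_identical_copies_yield_no_clusters(self):
        rng = np.random.default_rng(7)
        block = rng.standard_normal((15, 27))
        maps = np.vstack([block, block])
        groups = np.repeat(["a", "b"], 15)
        age = np.tile(rng.normal(70, 4, 15), 2)
        grid = build_source_grid(3, 10.0)
        res = run_contrast_battery(maps, groups, age, grid, [("a", "b")],
                                   n_perm=100, seed=0)
        assert res[("a", "b")].clusters == []

    def test_unknown_label_rejected(self):
        maps, groups, age = _null_dataset(8)
        with pytest.raises(ParameterError, match="unknown group"):
            run_contrast_battery(maps, groups, age, GRID4, [("a", "zzz")])

    def test_empty_contrast_list(self):
        maps, groups, age = _null_dataset(9)
        assert run_contrast_battery(maps, groups, age, GRID4, []) == {}
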