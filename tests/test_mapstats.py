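"""Map correlation, Bonferroni r-threshold, clustering, Moran's I patterns."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import masp
from masp import mapstats

from conftest import quant


def vec_map(grid, values, pid="p", tag="zscore"):
    return masp.ProteinMap(grid, pid, dict(zip(grid.sorted_wells(), values)), tag)


def brute_force_pearson(x, y):
    """Independent oracle: explicit sum-of-products definition of r."""
    n = len(x)
    sx, sy, sxx, syy, sxy = sum(x), sum(y), sum(v * v for v in x), sum(v * v for v in y), sum(
        a * b for a, b in zip(x, y)
    )
    num = n * sxy - sx * sy
    den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
    return num / den


@pytest.fixture(scope="module")
def grid5():
    return masp.generate_grid(3, 2, "full", target_wells=5)


class TestMapCorrelation:
    def test_identical_maps(self, grid5):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        for method in ("pearson", "cosine"):
            res = masp.map_correlation(vec_map(grid5, v, "a"), vec_map(grid5, v, "b"), method)
            assert res.r == pytest.approx(1.0)
            assert res.n_pairs == 5

    def test_negation_gives_minus_one(self, grid5):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = masp.map_correlation(vec_map(grid5, v, "a"), vec_map(grid5, -v, "b"))
        assert res.r == pytest.approx(-1.0)
        assert res.p_raw == pytest.approx(0.0, abs=1e-12)

    def test_hand_examples(self, grid2x2):
        a = vec_map(grid2x2, [1.0, 2.0, 3.0, 4.0], "a")
        b = vec_map(grid2x2, [1.0, 3.0, 2.0, 4.0], "b")
        assert masp.map_correlation(a, b, "pearson").r == pytest.approx(0.8)
        g1 = masp.generate_grid(2, 2, "full", target_wells=2)
        c = vec_map(g1, [1.0, 2.0], "c")
        d = vec_map(g1, [2.0, 1.0], "d")
        assert masp.map_correlation(c, d, "cosine").r == pytest.approx(0.8)

    def test_pairwise_complete_only(self, grid5):
        a = vec_map(grid5, [1.0, 2.0, 3.0, 4.0, np.nan], "a")
        b = vec_map(grid5, [np.nan, 3.0, 2.0, 4.0, 9.0], "b")
        res = masp.map_correlation(a, b)
        assert res.n_pairs == 3

    def test_too_few_joint_wells_raises(self, grid5):
        a = vec_map(grid5, [1.0, 2.0, np.nan, np.nan, np.nan], "a")
        b = vec_map(grid5, [1.0, 2.0, np.nan, np.nan, np.nan], "b")
        with pytest.raises(ValueError, match="jointly observed"):
            masp.map_correlation(a, b, "pearson")
        res = masp.map_correlation(a, b, "cosine")  # cosine only needs one
        assert res.n_pairs == 2

    def test_agrees_with_brute_force_oracle(self, grid5):
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(300):
            x, y = rng.normal(size=5), rng.normal(size=5)
            r = masp.map_correlation(vec_map(grid5, x, "a"), vec_map(grid5, y, "b")).r
            worst = max(worst, abs(r - brute_force_pearson(list(x), list(y))))
        assert worst < 1e-12

    def test_p_matches_scipy(self, grid5):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=5), rng.normal(size=5)
        res = masp.map_correlation(vec_map(grid5, x, "a"), vec_map(grid5, y, "b"))
        ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_raw == pytest.approx(ref.pvalue, rel=1e-9)


class TestBonferroniThreshold:
    def test_study_scale_reproduces_r_0_3(self):
        """208 locations, ~5000 comparisons, alpha 0.05 -> threshold 0.3."""
        thr = masp.bonferroni_r_threshold(n_obs=208, n_tests=5018, alpha=0.05)
        assert round(thr, 1) == 0.3

    @pytest.mark.parametrize(
        "n_obs,n_tests,expected",
        [(4, 1, 0.950), (20, 1, 0.444)],
    )
    def test_hand_values_from_t_critical(self, n_obs, n_tests, expected):
        thr = masp.bonferroni_r_threshold(n_obs, n_tests, 0.05)
        assert round(thr, 3) == expected

    def test_monotone_in_n_tests_and_n_obs(self):
        thrs = [masp.bonferroni_r_threshold(50, t) for t in (1, 10, 100, 5000)]
        assert thrs == sorted(thrs)
        byobs = [masp.bonferroni_r_threshold(n, 100) for n in (10, 50, 200, 1000)]
        assert byobs == sorted(byobs, reverse=True)
        assert masp.bonferroni_r_threshold(100000, 1) < 0.01  # -> 0 as n grows

    def test_input_validation(self):
        with pytest.raises(ValueError):
            masp.bonferroni_r_threshold(3, 1)
        with pytest.raises(ValueError):
            masp.bonferroni_r_threshold(10, 0)
        with pytest.raises(ValueError):
            masp.bonferroni_r_threshold(10, 1, alpha=1.5)


class TestCorrelateAll:
    def test_planted_copy_ranks_first(self, slice_grid):
        rng = np.random.default_rng(9)
        n = slice_grid.n_wells
        base = rng.normal(size=n)
        vals = np.column_stack([base, base, rng.normal(size=n)])
        q = quant(vals, samples=[slice_grid.specimen_at(w) for w in slice_grid.sorted_wells()],
                  features=["target", "copy", "noise"])
        results, median_r = masp.correlate_all(q, slice_grid, "target")
        assert len(results) == 2
        assert results[0].protein_b == "copy"
        assert results[0].r == pytest.approx(1.0)
        assert results[0].significant

    def test_planted_correlate_ranks_first_from_generator(self, slice_grid):
        truth = masp.SyntheticTruth(
            region_of_well=masp.assign_regions(slice_grid, 1),
            effect_of_protein={},
            heterodimer_pairs=[("P01", "P02", 1.0)],
            noise_sd_log2=0.3, missing_rate=0.0, seed=4,
        )
        mat, _, _ = masp.generate_dataset(truth, slice_grid, n_proteins=20, n_qc=0)
        results, median_r = masp.correlate_all(mat, slice_grid, "P01")
        assert results[0].protein_b == "P02"
        assert abs(median_r) < 0.2  # unrelated proteins are near zero

    def test_absent_target_raises(self, slice_grid, small_dataset):
        mat, _, _ = small_dataset
        with pytest.raises(KeyError):
            masp.correlate_all(mat, slice_grid, "nope")


class TestClusterMaps:
    def test_two_pattern_groups_recovered(self, slice_grid):
        rng = np.random.default_rng(21)
        A, B = rng.normal(size=208), rng.normal(size=208)
        maps = [vec_map(slice_grid, A + 0.1 * rng.normal(size=208), f"a{i}") for i in range(3)]
        maps += [vec_map(slice_grid, B + 0.1 * rng.normal(size=208), f"b{i}") for i in range(3)]
        res = masp.cluster_maps(maps, k="auto", seed=0)
        assert res.k == 2
        labels = [res.labels[m.protein_id] for m in maps]
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], labels) == 1.0

    def test_identical_maps_k1(self, grid5):
        m1 = vec_map(grid5, [1.0, 2.0, 3.0, 4.0, 5.0], "a")
        m2 = vec_map(grid5, [1.0, 2.0, 3.0, 4.0, 5.0], "b")
        res = masp.cluster_maps([m1, m2], k=1)
        assert res.k == 1 and set(res.labels.values()) == {0}

    def test_k_beyond_n_maps_rejected(self, grid5):
        maps = [vec_map(grid5, np.arange(5.0) + i, f"m{i}") for i in range(2)]
        with pytest.raises(ValueError, match="out of range"):
            masp.cluster_maps(maps, k=3)

    def test_all_constant_maps_rejected(self, grid5):
        maps = [vec_map(grid5, np.full(5, 1.0), "a"), vec_map(grid5, np.full(5, 2.0), "b")]
        with pytest.raises(ValueError, match="constant"):
            masp.cluster_maps(maps, k=2)

    def test_invariant_to_order_and_affine_rescaling(self, slice_grid):
        rng = np.random.default_rng(31)
        A, B = rng.normal(size=208), rng.normal(size=208)
        base = [A, A, B, B]
        maps = [vec_map(slice_grid, v, f"m{i}") for i, v in enumerate(base)]
        scaled = [vec_map(slice_grid, 3.0 * v + 7.0, f"m{i}") for i, v in enumerate(base)]
        r1 = masp.cluster_maps(maps, k=2, seed=0)
        r2 = masp.cluster_maps(list(reversed(maps)), k=2, seed=0)
        r3 = masp.cluster_maps(scaled, k=2, seed=0)
        ids = [m.protein_id for m in maps]
        l1 = [r1.labels[i] for i in ids]
        for other in (r2, r3):
            lo = [other.labels[i] for i in ids]
            assert adjusted_rand_score(l1, lo) == 1.0


class TestRegionalPatterns:
    def test_checkerboard_morans_i_is_minus_one(self):
        g = masp.generate_grid(2, 2, "full", target_wells=4)
        W = mapstats.rook_adjacency(g)
        assert masp.morans_i(np.array([1.0, 0.0, 0.0, 1.0]), W) == pytest.approx(-1.0)

    def test_brute_force_moran_oracle(self):
        """I from the explicit double sum over directed rook pairs."""
        g = masp.generate_grid(3, 3, "full", target_wells=9)
        rng = np.random.default_rng(3)
        x = rng.normal(size=9)
        wells = g.sorted_wells()
        z = x - x.mean()
        pairs = [
            (i, j)
            for i, (r, c) in enumerate(wells)
            for j, (r2, c2) in enumerate(wells)
            if abs(r - r2) + abs(c - c2) == 1
        ]
        manual = (len(x) / len(pairs)) * sum(z[i] * z[j] for i, j in pairs) / np.sum(z**2)
        assert masp.morans_i(x, mapstats.rook_adjacency(g)) == pytest.approx(manual, abs=1e-12)

    def test_constant_protein_skipped(self, grid2x2, caplog):
        vals = np.column_stack([np.ones(4), [1.0, 0.0, 0.0, 1.0]])
        q = quant(vals, samples=["A", "B", "C", "D"], features=["const", "checker"])
        with caplog.at_level("WARNING"):
            res = masp.detect_regional_patterns(q, grid2x2, B=99, seed=0, min_obs=4)
        assert [r.protein_id for r in res] == ["checker"]
        assert "skipped" in caplog.text

    def test_p_range_and_determinism(self, slice_grid, small_dataset):
        mat, _, _ = small_dataset
        sub = masp.QuantMatrix(mat.values.iloc[:, :25], mat.scale_tag)
        r1 = masp.detect_regional_patterns(sub, slice_grid, B=199, seed=11)
        r2 = masp.detect_regional_patterns(sub, slice_grid, B=199, seed=11)
        assert [x.p_perm for x in r1] == [x.p_perm for x in r2]
        for x in r1:
            assert 1 / 200 <= x.p_perm <= 1.0

    def test_bh_preserves_p_ordering(self, slice_grid, small_dataset):
        mat, _, _ = small_dataset
        sub = masp.QuantMatrix(mat.values.iloc[:, :40], mat.scale_tag)
        res = masp.detect_regional_patterns(sub, slice_grid, B=199, seed=1)
        res_sorted = sorted(res, key=lambda r: r.p_perm)
        qs = [r.q_value for r in res_sorted]
        assert qs == sorted(qs)
        assert all(r.q_value >= r.p_perm - 1e-12 for r in res)

    def test_planted_regions_have_high_moran(self, slice_grid, small_dataset):
        mat, _, truth = small_dataset
        res = masp.detect_regional_patterns(mat, slice_grid, B=199, seed=2)
        stat = {r.protein_id: r.statistic for r in res}
        planted = np.median([stat[p] for p in truth.regional_proteins if p in stat])
        flat = np.median([s for p, s in stat.items() if p not in set(truth.regional_proteins)])
        assert planted > 0.3 > flat
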