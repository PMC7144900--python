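import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from tadpole.conclust import coniss, cut
from tadpole.concordance import DomainSet, moc
from tadpole.errors import ParameterError, UndefinedMetricError
from tadpole.hic_io import BinMap, detect_bad_columns, drop_masked
from tadpole.hierarchy import (
    broken_stick_max_level,
    broken_stick_pieces,
    calinski_harabasz,
    map_partition,
    optimize,
)
from tadpole.partition import Partition
from tadpole.synthetic import SyntheticSpec, generate_matrix


class TestBrokenStick:
    def test_pieces_n3_analytic(self):
        b = broken_stick_pieces(3)
        np.testing.assert_allclose(b, [11 / 18, 5 / 18, 2 / 18], atol=1e-15)
        assert b.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 5, 17])
    def test_pieces_sum_to_one_and_decrease(self, n):
        b = broken_stick_pieces(n)
        assert b.sum() == pytest.approx(1.0)
        assert np.all(np.diff(b) < 0)

    def test_insignificant_first_split_gives_zero(self, rng):
        # equally spaced points: every split explains a near-equal share,
        # below the largest broken-stick piece
        pts = np.arange(40, dtype=float).reshape(-1, 1)
        dend = coniss(squareform(pdist(pts)))
        obs_first = dend.increments[-1] / dend.total_dispersion
        if obs_first <= broken_stick_pieces(40)[1]:
            assert broken_stick_max_level(dend) == 0

    def test_two_block_matrix_recovers_boundary(self):
        spec = SyntheticSpec(n_bins=40, levels=((20,),), block_contrast=4.0, seed=3)
        cm, truth = generate_matrix(spec)
        filt, bm = drop_masked(detect_bad_columns(cm))
        h = optimize(filt, bin_map=bm, n_pc_max=5)
        assert h.has_hierarchy and h.max_level >= 1
        level1 = h.levels[0]
        planted = truth[0].boundaries[0]
        assert abs(level1.boundaries[0] - planted) <= 1

    def test_needs_three_leaves(self):
        dend = coniss(np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ParameterError):
            broken_stick_max_level(dend)


class TestCalinskiHarabasz:
    def test_separation_limit(self):
        pts = np.array([0.0, 0.01, 10.0, 10.01])
        labels = [0, 0, 1, 1]
        assert calinski_harabasz(pts, labels) > 1e6

    def test_random_labels_on_blob_near_one(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(60, 1))
        vals = []
        for _ in range(1000):
            labels = rng.permutation(np.repeat([0, 1, 2], 20))
            vals.append(calinski_harabasz(pts, labels))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_worked_six_point_instance(self):
        pts = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        grand = pts.mean()
        b = 3 * (1.0 - grand) ** 2 + 3 * (11.0 - grand) ** 2
        w = sum((v - 1.0) ** 2 for v in [0, 1, 2]) + sum(
            (v - 11.0) ** 2 for v in [10, 11, 12]
        )
        want = (b / (2 - 1)) / (w / (6 - 2))
        assert calinski_harabasz(pts, labels) == pytest.approx(want, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import calinski_harabasz_score

        pts = rng.normal(size=(30, 3))
        labels = rng.integers(0, 4, size=30)
        if len(np.unique(labels)) >= 2:
            assert calinski_harabasz(pts, labels) == pytest.approx(
                calinski_harabasz_score(pts, labels), rel=1e-10
            )

    def test_degenerate_k(self):
        pts = np.arange(5, dtype=float)
        with pytest.raises(UndefinedMetricError):
            calinski_harabasz(pts, np.zeros(5))
        with pytest.raises(UndefinedMetricError):
            calinski_harabasz(pts, np.arange(5))


class TestMapPartition:
    def test_identity(self):
        p = Partition(domains=[(0, 2), (2, 4)])
        out = map_partition(p, BinMap.identity(4))
        assert out.domains == p.domains

    def test_masked_bin_absorbed_left(self):
        # original mask [F,F,T,F]; boundary after filtered bin 1
        bm = BinMap(kept_to_original=np.array([0, 1, 3]), n_original=4)
        p = Partition(domains=[(0, 2), (2, 3)])
        out = map_partition(p, bm)
        assert out.domains == [(0, 3), (3, 4)]

    def test_leading_masked_attach_first(self):
        bm = BinMap(kept_to_original=np.array([2, 3, 4]), n_original=5)
        p = Partition(domains=[(0, 1), (1, 3)])
        out = map_partition(p, bm)
        assert out.domains == [(0, 3), (3, 5)]

    def test_tiling_preserved(self, rng):
        n_orig = 30
        mask = np.zeros(n_orig, bool)
        mask[rng.choice(n_orig, 6, replace=False)] = True
        kept = np.flatnonzero(~mask)
        bm = BinMap(kept_to_original=kept, n_original=n_orig)
        cuts = np.sort(rng.choice(np.arange(1, kept.size), 4, replace=False))
        p = Partition.from_boundaries(kept.size, cuts)
        out = map_partition(p, bm)
        assert out.start == 0 and out.end == n_orig
        assert np.all(np.diff(out.boundaries) > 0)


class TestOptimize:
    def test_three_level_nested_recovery(self):
        # benchmark-style min_tads keeps shallow-only dendrograms out of the
        # mean-CH comparison so the deep hierarchy can win
        spec = SyntheticSpec(
            n_bins=64,
            levels=((32,), (16, 32, 48), (8, 16, 24, 32, 40, 48, 56)),
            block_contrast=(1.1, 1.8, 2.5),
            distance_decay_exponent=1.0,
            base_intensity=50,
            seed=5,
        )
        cm, truth = generate_matrix(spec)
        filt, bm = drop_masked(detect_bad_columns(cm))
        h = optimize(filt, bin_map=bm, n_pc_max=12, min_tads=8)
        assert h.has_hierarchy
        got_boundary_sets = [set(p.boundaries.tolist()) for p in h.levels]
        for planted in truth:
            want = set(planted.boundaries.tolist())
            matched = any(
                len(got) == len(want)
                and all(min(abs(b - w) for b in got) <= 1 for w in want)
                for got in got_boundary_sets
            )
            assert matched, f"planted level {sorted(want)} not recovered"

    def test_null_flagged_unstable(self):
        spec = SyntheticSpec(
            n_bins=60, levels=(), block_contrast=1.0,
            distance_decay_exponent=0.0, seed=0,
        )
        cm, _ = generate_matrix(spec)
        filt, bm = drop_masked(detect_bad_columns(cm))
        h = optimize(filt, bin_map=bm, n_pc_max=8)
        assert (not h.has_hierarchy) or (not h.stable)

    def test_shuffled_matrix_not_stable(self, planted_two_level):
        """Row/col permutation destroys adjacency -> flagged unstable."""
        cm, _ = planted_two_level
        rng = np.random.default_rng(13)
        perm = rng.permutation(cm.n_bins)
        shuffled = type(cm)(
            chrom=cm.chrom,
            start_bp=cm.start_bp,
            resolution=cm.resolution,
            values=cm.values[np.ix_(perm, perm)],
        )
        filt, bm = drop_masked(detect_bad_columns(shuffled))
        h = optimize(filt, bin_map=bm, n_pc_max=8, stability_permutations=49, rng=1)
        assert (not h.has_hierarchy) or (not h.stable)

    def test_deterministic(self, planted_two_level):
        cm, _ = planted_two_level
        filt, bm = drop_masked(detect_bad_columns(cm))
        h1 = optimize(filt, bin_map=bm, n_pc_max=6)
        h2 = optimize(filt, bin_map=bm, n_pc_max=6)
        assert h1.n_pc_opt == h2.n_pc_opt
        assert h1.optimal_level == h2.optimal_level
        np.testing.assert_array_equal(h1.ch_matrix, h2.ch_matrix)
        assert [p.domains for p in h1.levels] == [p.domains for p in h2.levels]

    def test_n_tads_is_level_plus_one(self, planted_two_level):
        cm, _ = planted_two_level
        filt, bm = drop_masked(detect_bad_columns(cm))
        h = optimize(filt, bin_map=bm, n_pc_max=6)
        assert h.n_tads_opt == h.optimal_level + 1

    def test_optimal_cell_is_row_max(self, planted_two_level):
        cm, _ = planted_two_level
        filt, bm = drop_masked(detect_bad_columns(cm))
        h = optimize(filt, bin_map=bm, n_pc_max=6)
        row = h.ch_matrix[h.n_pc_opt - 1]
        finite = row[np.isfinite(row)]
        assert h.levels[h.optimal_level - 1].ch_index == pytest.approx(finite.max())

    def test_min_tads_restricts_optimum(self):
        spec = SyntheticSpec(
            n_bins=64,
            levels=((32,), (8, 16, 24, 32, 40, 48, 56)),
            block_contrast=3.0,
            seed=9,
        )
        cm, _ = generate_matrix(spec)
        filt, bm = drop_masked(detect_bad_columns(cm))
        h = optimize(filt, bin_map=bm, n_pc_max=8, min_tads=5)
        if h.has_hierarchy:
            assert h.n_tads_opt >= 5

    def test_nesting_invariant(self, planted_two_level):
        cm, _ = planted_two_level
        filt, bm = drop_masked(detect_bad_columns(cm))
        h = optimize(filt, bin_map=bm, n_pc_max=6)
        prev = set()
        for p in h.levels:
            bounds = set(p.boundaries.tolist())
            assert prev <= bounds
            prev = bounds

    def test_recovery_moc_over_seeds(self):
        """Mean MoC of the optimal partition vs planted truth over 20 seeds."""
        scores = []
        for seed in range(20):
            spec = SyntheticSpec(
                n_bins=60, levels=((30,), (15, 30, 45)),
                block_contrast=3.0, seed=seed,
            )
            cm, truth = generate_matrix(spec)
            filt, bm = drop_masked(detect_bad_columns(cm))
            h = optimize(filt, bin_map=bm, n_pc_max=8, stability_permutations=0)
            if not h.has_hierarchy:
                scores.append(0.0)
                continue
            opt = DomainSet.from_partition(h.optimal_partition)
            best = max(moc(opt, DomainSet.from_partition(t)) for t in truth)
            scores.append(best)
        assert np.mean(scores) >= 0.9
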