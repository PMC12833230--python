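"""Core statistics: FC maps, group t-tests, FDR, probability thresholding."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fcnm.fcnm_core import (
    AcupointNetwork,
    BinaryNetworkMap,
    DegenerateSeedError,
    GroupResult,
    PipelineConfig,
    ProbabilityMap,
    binarize_positive,
    fdr_select,
    group_onesample,
    probability_map,
    run_fcnm,
    seed_mean_timeseries,
    subject_fc_map,
    threshold_probability,
)
from fcnm.grid_io import ReferenceGrid, VolumeSeries
from fcnm.seeds import SeedMask


def tiny_grid(shape=(4, 4, 4)):
    return ReferenceGrid(shape, np.eye(4), np.ones(shape, bool))


def series_from(grid, assignments, T, fill=None, rng=None):
    """Build a VolumeSeries with specific voxel time courses."""
    if fill is not None:
        data = np.full(grid.shape + (T,), float(fill))
    else:
        data = (rng or np.random.default_rng(0)).standard_normal(grid.shape + (T,))
    for vox, ts in assignments.items():
        data[vox] = ts
    return VolumeSeries(grid, data, subject_id="sub")


class TestSeedMeanTimeseries:
    def test_single_voxel_seed_returns_its_series(self):
        grid = tiny_grid()
        ts = np.arange(5.0)
        s = series_from(grid, {(1, 1, 1): ts}, T=5, fill=0.0)
        seed = SeedMask(grid, frozenset({(1, 1, 1)}))
        assert np.array_equal(seed_mean_timeseries(s, seed), ts)

    def test_antisymmetric_pair_cancels(self):
        grid = tiny_grid()
        ts = np.array([1.0, -2.0, 3.0, 0.5])
        s = series_from(grid, {(0, 0, 0): ts, (0, 0, 1): -ts}, T=4, fill=0.0)
        seed = SeedMask(grid, frozenset({(0, 0, 0), (0, 0, 1)}))
        assert np.allclose(seed_mean_timeseries(s, seed), 0.0)

    def test_constant_levels_average(self):
        grid = tiny_grid()
        s = series_from(
            grid,
            {(0, 0, 0): np.full(4, 1.0), (0, 0, 1): np.full(4, 2.0),
             (0, 0, 2): np.full(4, 3.0)},
            T=4, fill=0.0,
        )
        seed = SeedMask(grid, frozenset({(0, 0, 0), (0, 0, 1), (0, 0, 2)}))
        assert np.allclose(seed_mean_timeseries(s, seed), 2.0)


class TestSubjectFCMap:
    def test_perfect_correlation_hits_clip(self):
        grid = tiny_grid()
        ts = np.array([1.0, 2.0, 3.0, 4.0])
        s = series_from(grid, {(1, 1, 1): ts, (2, 2, 2): ts}, T=4)
        seed = SeedMask(grid, frozenset({(1, 1, 1)}))
        fc = subject_fc_map(s, seed)
        assert fc.data[2, 2, 2] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_hand_computed_pair(self):
        grid = tiny_grid()
        s = series_from(
            grid,
            {(0, 0, 0): np.array([1.0, 2, 3, 4]), (3, 3, 3): np.array([1.0, 2, 3, 5])},
            T=4,
        )
        seed = SeedMask(grid, frozenset({(0, 0, 0)}))
        fc = subject_fc_map(s, seed)
        r = 6.5 / np.sqrt(5 * 8.75)  # hand Pearson
        assert fc.data[3, 3, 3] == pytest.approx(np.arctanh(r), abs=1e-10)
        assert fc.data[3, 3, 3] == pytest.approx(2.371, abs=1e-3)

    def test_zero_variance_voxel_flagged_zero(self):
        grid = tiny_grid()
        s = series_from(grid, {(2, 2, 2): np.zeros(4)}, T=4)
        seed = SeedMask(grid, frozenset({(0, 0, 0)}))
        fc = subject_fc_map(s, seed)
        assert fc.data[2, 2, 2] == 0.0
        assert fc.zero_variance[2, 2, 2]

    def test_constant_seed_series_raises(self):
        grid = tiny_grid()
        s = series_from(grid, {(1, 1, 1): np.full(4, 3.0)}, T=4)
        seed = SeedMask(grid, frozenset({(1, 1, 1)}))
        with pytest.raises(DegenerateSeedError):
            subject_fc_map(s, seed)

    def test_oracle_equivalence_loop_pearson(self):
        """Vectorized map equals per-voxel scipy.stats.pearsonr + atanh."""
        shape = (6, 6, 6)
        grid = ReferenceGrid(shape, np.eye(4), np.ones(shape, bool))
        rng = np.random.default_rng(11)
        s = VolumeSeries(grid, rng.standard_normal(shape + (20,)), "sub")
        seed = SeedMask(grid, frozenset({(0, 0, 0), (1, 2, 3)}))
        fc = subject_fc_map(s, seed)
        mean_ts = s.data[[0, 1], [0, 2], [0, 3]].mean(axis=0)
        for vox in [(0, 0, 0), (2, 3, 4), (5, 5, 5)]:
            r = stats.pearsonr(s.data[vox], mean_ts).statistic
            expected = np.arctanh(np.clip(r, -(1 - 1e-7), 1 - 1e-7))
            assert fc.data[vox] == pytest.approx(expected, abs=1e-10)


class TestGroupOnesample:
    def _maps(self, values):
        grid = tiny_grid((2, 2, 2))
        from fcnm.fcnm_core import SubjectFCMap

        out = []
        for i, v in enumerate(values):
            data = np.zeros(grid.shape)
            data[0, 0, 0] = v
            out.append(SubjectFCMap(grid, data, f"s{i}", "seed"))
        return out

    def test_closed_form_t_and_p(self):
        res = group_onesample(self._maps([1.0, 2.0, 3.0]))
        assert res.df == 2
        assert res.t_map.data[0, 0, 0] == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-12)
        assert res.p_map.data[0, 0, 0] == pytest.approx(
            2 * stats.t.sf(np.sqrt(12), 2), abs=1e-12
        )
        assert res.p_map.data[0, 0, 0] == pytest.approx(0.0743, abs=2e-4)

    def test_all_zero_voxel(self):
        res = group_onesample(self._maps([0.0, 0.0, 0.0]))
        assert res.t_map.data[0, 0, 0] == 0.0
        assert res.p_map.data[0, 0, 0] == 1.0

    def test_constant_nonzero_voxel_degenerate(self):
        res = group_onesample(self._maps([0.5, 0.5, 0.5]))
        assert res.p_map.data[0, 0, 0] == 0.0
        assert res.degenerate[0, 0, 0]

    def test_requires_three_maps(self):
        with pytest.raises(ValueError):
            group_onesample(self._maps([1.0, 2.0]))


def brute_force_bh(p, q):
    """Independent BH definition: k = max{i : p_(i) <= i*q/m}, reject p <= p_(k)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.sort(p)
    ks = [i + 1 for i in range(m) if order[i] <= (i + 1) * q / m]
    if not ks:
        return np.zeros(m, bool)
    return p <= order[max(ks) - 1]


class TestFdrSelect:
    def test_worked_example(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.09]
        assert fdr_select(p, 0.05).tolist() == [True, True, False, False, False]

    def test_all_ones_reject_none(self):
        assert not fdr_select(np.ones(10), 0.05).any()

    def test_single_p_at_threshold(self):
        assert fdr_select([0.009], 0.01).all()

    @given(st.integers(0, 300))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 200))
        p = rng.uniform(size=m)
        if m > 3 and rng.random() < 0.5:
            p[: m // 2] = rng.choice(p, size=m // 2)  # inject ties
        q = float(rng.uniform(0.01, 0.2))
        assert np.array_equal(fdr_select(p, q), brute_force_bh(p, q))


class TestBinarizeAndProbability:
    def _group(self, t_vals, p_vals, grid):
        from fcnm.grid_io import ScalarMap

        return GroupResult(
            t_map=ScalarMap(grid, t_vals, "t"),
            p_map=ScalarMap(grid, p_vals, "p"),
            df=9, n_subjects=10,
        )

    def test_negative_t_excluded_even_if_significant(self):
        grid = tiny_grid((2, 2, 2))
        t = np.zeros(grid.shape)
        p = np.ones(grid.shape)
        t[0, 0, 0], p[0, 0, 0] = -5.0, 1e-9
        t[1, 1, 1], p[1, 1, 1] = 5.0, 1e-9
        b = binarize_positive(self._group(t, p, grid), q=0.01)
        assert not b.mask[0, 0, 0]
        assert b.mask[1, 1, 1]

    def test_all_null_gives_empty_map(self):
        grid = tiny_grid((2, 2, 2))
        b = binarize_positive(
            self._group(np.zeros(grid.shape), np.ones(grid.shape), grid), q=0.01
        )
        assert b.n_voxels == 0

    def test_probability_counts(self):
        grid = tiny_grid((2, 2, 2))
        maps = []
        for i in range(4):
            m = np.zeros(grid.shape, bool)
            if i < 3:
                m[0, 0, 0] = True
            m[1, 1, 1] = True
            maps.append(BinaryNetworkMap(grid, m))
        pm = probability_map(maps)
        assert pm.data[0, 0, 0] == pytest.approx(0.75)
        assert pm.data[1, 1, 1] == pytest.approx(1.0)
        assert pm.data[0, 1, 0] == 0.0
        assert pm.n_maps == 4

    def test_threshold_inclusive_at_60(self):
        grid = tiny_grid((2, 2, 2))
        data = np.zeros(grid.shape)
        data[0, 0, 0] = 0.75
        data[0, 0, 1] = 0.50
        net = threshold_probability(ProbabilityMap(grid, data, 4), 0.60)
        assert net.mask[0, 0, 0] and not net.mask[0, 0, 1]

    @pytest.mark.parametrize("n,expected_min_count", [(14, 9), (4, 3)])
    def test_minimum_surviving_count_at_60pct(self, n, expected_min_count):
        counts = np.arange(n + 1)
        surviving = counts[counts / n >= 0.6]
        assert surviving.min() == expected_min_count
        # and the implementation agrees voxel-wise
        grid = tiny_grid((2, 2, 2))
        data = np.zeros(grid.shape)
        data[0, 0, 0] = (expected_min_count - 1) / n
        data[0, 0, 1] = expected_min_count / n
        net = threshold_probability(ProbabilityMap(grid, data, n), 0.60)
        assert not net.mask[0, 0, 0] and net.mask[0, 0, 1]

    @given(st.integers(0, 50))
    def test_threshold_nesting(self, seed):
        rng = np.random.default_rng(seed)
        grid = tiny_grid((3, 3, 3))
        n = int(rng.integers(2, 15))
        data = rng.integers(0, n + 1, size=grid.shape) / n
        pm = ProbabilityMap(grid, data, n)
        t1, t2 = sorted(rng.uniform(0.05, 1.0, size=2))
        hi = threshold_probability(pm, t2).mask
        lo = threshold_probability(pm, t1).mask
        assert not (hi & ~lo).any()


class TestRunFcnm:
    def test_recovers_planted_network(self, small_scene, small_connectome):
        from fcnm import synthetic_data as sd

        foci = sd.gen_foci(small_scene, n_units={"ST36": 6}, rng_seed=3)
        runs = run_fcnm(foci, small_connectome, PipelineConfig(), small_scene.grid)
        net = runs["ST36"].network
        truth = small_scene.true_network_masks["ST36"]
        inter = (net.mask & truth).sum()
        d = 2 * inter / (net.n_voxels + truth.sum())
        assert net.n_voxels > 0
        assert d > 0.8

    def test_two_acupoints_give_disjoint_networks(self, small_scene, small_connectome):
        from fcnm import synthetic_data as sd

        foci = sd.gen_foci(small_scene, n_units={"ST36": 4, "GB34": 4}, rng_seed=4)
        runs = run_fcnm(foci, small_connectome, PipelineConfig(), small_scene.grid)
        assert set(runs) == {"GB34", "ST36"}
        overlap = runs["ST36"].network.mask & runs["GB34"].network.mask
        assert not overlap.any()

    def test_provenance_counts(self, small_scene, small_connectome):
        from fcnm import synthetic_data as sd

        foci = sd.gen_foci(small_scene, n_units={"ST36": 3}, rng_seed=5)
        runs = run_fcnm(foci, small_connectome, PipelineConfig(), small_scene.grid)
        prov = runs["ST36"].provenance
        assert prov["n_units"] == 3
        assert prov["n_subjects"] == len(small_connectome)
        assert prov["network_voxels"] == runs["ST36"].network.n_voxels
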