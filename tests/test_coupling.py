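"""Cross-correlogram construction, extreme-region detection, diagonal."""

import numpy as np
import pytest

import tailbalance as tb
from tailbalance import coupling, errors
from tailbalance.gait import StepCycleSet


def make_set(epochs):
    epochs = np.asarray(epochs, float)
    h = (epochs.shape[1] - 1) // 2
    return StepCycleSet(epochs, h, np.arange(epochs.shape[0]))


def random_epochs(n, bins, seed):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, bins))


class TestBuildCorrelogram:
    def test_self_correlation_diagonal_is_one(self):
        ep = random_epochs(10, 21, 0)
        C = coupling.build_correlogram(make_set(ep), make_set(ep))
        np.testing.assert_allclose(np.diagonal(C.matrix), 1.0, atol=1e-9)

    def test_sign_flip_diagonal_is_minus_one(self):
        ep = random_epochs(10, 21, 1)
        C = coupling.build_correlogram(make_set(ep), make_set(-ep))
        np.testing.assert_allclose(np.diagonal(C.matrix), -1.0, atol=1e-9)

    def test_independent_signals_stay_near_null(self):
        # oracle: the permutation null of a Pearson correlation across n
        # epochs has s.d. about 1/sqrt(n); the matrix mean must sit within
        # a 3/sqrt(n) envelope of zero
        n = 40
        C = coupling.build_correlogram(make_set(random_epochs(n, 15, 2)),
                                       make_set(random_epochs(n, 15, 3)))
        assert abs(np.nanmean(C.matrix)) < 3 / np.sqrt(n)
        # explicit permutation oracle at a single bin pair
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=n), rng.normal(size=n)
        perms = []
        for _ in range(500):
            perms.append(np.corrcoef(a, rng.permutation(b))[0, 1])
        lo, hi = np.percentile(perms, [0.5, 99.5])
        observed = np.corrcoef(a, b)[0, 1]
        assert lo < observed < hi

    def test_zero_variance_bin_marked_undefined(self):
        ep = random_epochs(8, 11, 5)
        flat = ep.copy()
        flat[:, 4] = 7.0
        C = coupling.build_correlogram(make_set(flat), make_set(ep))
        assert np.isnan(C.matrix[4, :]).all()
        assert np.isfinite(C.matrix[0, 0])

    def test_too_few_epochs_rejected(self):
        ep = random_epochs(2, 11, 6)
        with pytest.raises(errors.ParameterError):
            coupling.build_correlogram(make_set(ep), make_set(ep))

    def test_affine_rescaling_invariance(self):
        tail = random_epochs(12, 15, 7)
        body = random_epochs(12, 15, 8)
        C1 = coupling.build_correlogram(make_set(tail), make_set(body))
        C2 = coupling.build_correlogram(make_set(3.5 * tail - 2.0),
                                        make_set(-0.25 * body + 11.0))
        np.testing.assert_allclose(np.abs(C1.matrix), np.abs(C2.matrix),
                                   atol=1e-9)

    def test_within_trial_variant_bounded_and_signed(self):
        # the within-trial reading keeps values in [-1, 1] and agrees with
        # the across-trials reading on the sign of a strong anti-coupling
        rng = np.random.default_rng(13)
        common = rng.normal(size=(12, 15))
        C = coupling.build_correlogram(make_set(common), make_set(-common),
                                       mode="within_trial_lag")
        assert np.nanmax(np.abs(C.matrix)) <= 1.0
        assert float(np.nanmean(np.diagonal(C.matrix))) < 0
        with pytest.raises(errors.ConfigError):
            coupling.build_correlogram(make_set(common), make_set(common),
                                       mode="banana")

    def test_transposing_roles_transposes_matrix(self):
        tail = random_epochs(9, 13, 9)
        body = random_epochs(9, 13, 10)
        C = coupling.build_correlogram(make_set(tail), make_set(body))
        Ct = coupling.build_correlogram(make_set(body), make_set(tail))
        np.testing.assert_allclose(Ct.matrix, C.matrix.T, atol=1e-12)


def planted_matrix(block_value, size=10, block=slice(2, 5)):
    mat = np.zeros((size, size))
    mat[block, block] = block_value
    return coupling.CrossCorrelogram(mat, n_trials=10,
                                     bin_times=np.arange(size) / 300.0)


class TestExtremeRegions:
    def test_planted_hot_block_recovered_exactly(self):
        C = planted_matrix(0.9)
        hot, _ = coupling.find_extreme_regions(C, pct=5.0)
        assert hot.size == 9
        assert hot.cells == frozenset((i, j) for i in range(2, 5)
                                      for j in range(2, 5))

    def test_planted_cold_block_recovered_exactly(self):
        C = planted_matrix(-0.9)
        _, cold = coupling.find_extreme_regions(C, pct=5.0)
        assert cold.size == 9
        assert cold.cells == frozenset((i, j) for i in range(2, 5)
                                       for j in range(2, 5))

    def test_largest_of_two_disjoint_blocks_wins(self):
        mat = np.zeros((12, 12))
        mat[0:2, 0:2] = 0.9          # 4 cells
        mat[6:9, 6:8] = 0.9          # 6 cells
        C = coupling.CrossCorrelogram(mat, 5, np.arange(12) / 300.0)
        hot, _ = coupling.find_extreme_regions(C, pct=5.0)
        assert hot.size == 6
        assert (6, 6) in hot.cells and (0, 0) not in hot.cells

    def test_constant_shift_leaves_regions_unchanged(self):
        mat = np.zeros((10, 10))
        mat[2:5, 2:5] = 0.5
        mat[7:9, 7:9] = -0.5
        C1 = coupling.CrossCorrelogram(mat, 5, np.arange(10) / 300.0)
        # shift all cells by a constant within correlation bounds
        C2 = coupling.CrossCorrelogram(mat * 0.5 + 0.2, 5,
                                       np.arange(10) / 300.0)
        hot1, cold1 = coupling.find_extreme_regions(C1, 10.0)
        hot2, cold2 = coupling.find_extreme_regions(C2, 10.0)
        assert hot1.cells == hot2.cells
        assert cold1.cells == cold2.cells

    def test_bad_percentile_rejected(self):
        C = planted_matrix(0.9)
        with pytest.raises(errors.ParameterError):
            coupling.find_extreme_regions(C, pct=50.0)


class TestDiagonal:
    def test_identity_like(self):
        ep = random_epochs(10, 11, 11)
        C = coupling.build_correlogram(make_set(ep), make_set(ep))
        _, diag = coupling.correlogram_diagonal(C)
        np.testing.assert_allclose(diag, 1.0, atol=1e-9)

    def test_anticorrelated(self):
        ep = random_epochs(10, 11, 12)
        C = coupling.build_correlogram(make_set(ep), make_set(-ep))
        _, diag = coupling.correlogram_diagonal(C)
        np.testing.assert_allclose(diag, -1.0, atol=1e-9)

    def test_planted_block_indexing(self):
        C = planted_matrix(0.7)
        times, diag = coupling.correlogram_diagonal(C)
        assert len(times) == len(diag) == 10
        np.testing.assert_array_equal(diag[2:5], 0.7)
        assert (diag[:2] == 0).all() and (diag[5:] == 0).all()


class TestAntiPhaseCohorts:
    def test_negative_diagonal_near_swing_peak(self):
        # tail oscillating anti-phase to the hips must show up as negative
        # zero-lag momentum coupling around the step event
        negatives = 0
        for seed in range(10):
            cfg = tb.SimConfig(ridge_width=4.0, seed=seed)
            res = tb.analyze_trial(*tb.simulate_trial(cfg)[:4])
            te, be = res.tail_momentum_epochs, res.body_momentum_epochs
            C = coupling.build_correlogram(
                StepCycleSet(te, 75, np.arange(len(te))),
                StepCycleSet(be, 75, np.arange(len(be))))
            times, diag = coupling.correlogram_diagonal(C)
            near = np.abs(times) <= 0.05
            if np.nanmean(diag[near]) < 0:
                negatives += 1
        assert negatives >= 9
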