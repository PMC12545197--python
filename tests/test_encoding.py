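"""Banded ridge solver, scoring, LOSO evaluation, weight swapping and
block-permutation inference."""

import numpy as np
import pytest
from scipy import linalg, stats

from convenc import encoding as enc
from convenc import simulate as sim
from convenc.features import DesignMatrix, assemble_design, fir_expand


def _design(X, runs=None, sessions=None, bands=None):
    T, P = X.shape
    if bands is None:
        bands = np.array(["production"] * P)
    return DesignMatrix(
        values=X,
        band=bands,
        feature=np.concatenate([np.arange(np.sum(bands == b)) for b in dict.fromkeys(bands)]),
        delay=np.zeros(P, int),
        run_index=runs if runs is not None else np.zeros(T, int),
        session_index=sessions if sessions is not None else np.zeros(T, int),
    )


class TestBandedRidgeSolver:
    def test_equal_alphas_match_standard_ridge(self, rng):
        X = rng.standard_normal((80, 12))
        Y = rng.standard_normal((80, 3))
        alpha = 10.0
        bands = {"a": np.arange(6), "b": np.arange(6, 12)}
        model = enc.BandedRidgeCV(bands=bands, alphas=np.array([alpha])).fit(X, Y)
        closed = linalg.solve(X.T @ X + alpha * np.eye(12), X.T @ Y)
        assert np.max(np.abs(model.coef_ - closed)) < 1e-6

    def test_orthonormal_design_closed_form(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((100, 10)))
        y = rng.standard_normal((100, 1))
        alpha = 3.7
        model = enc.BandedRidgeCV(bands={"a": np.arange(10)}, alphas=np.array([alpha])).fit(Q, y)
        assert np.max(np.abs(model.coef_ - Q.T @ y / (1 + alpha))) < 1e-8

    def test_noise_band_gets_stronger_penalty(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X1 = rng.standard_normal((600, 8))
            X2 = rng.standard_normal((600, 8))  # pure distractor
            w = rng.standard_normal((8, 1))
            y = X1 @ w + 0.5 * rng.standard_normal((600, 1))
            model = enc.BandedRidgeCV(bands={"signal": np.arange(8), "noise": np.arange(8, 16)}).fit(
                np.hstack([X1, X2]), y
            )
            hits += model.alpha_[1, 0] >= model.alpha_[0, 0]
        assert hits >= 18

    def test_ridge_limit_is_least_squares(self, rng):
        X = rng.standard_normal((200, 8))
        y = X @ rng.standard_normal((8, 1)) + 0.1 * rng.standard_normal((200, 1))
        model = enc.BandedRidgeCV(bands={"a": np.arange(8)}, alphas=np.array([1e-10])).fit(X, y)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.max(np.abs(model.coef_ - ols)) < 1e-4

    def test_dual_and_primal_agree(self, rng):
        X = rng.standard_normal((60, 20))
        Y = rng.standard_normal((60, 4))
        primal = linalg.solve(X.T @ X + np.eye(20), X.T @ Y)
        dual = X.T @ linalg.solve(X @ X.T + np.eye(60), Y)
        assert np.max(np.abs(primal - dual)) < 1e-6
        assert np.max(np.abs(enc._solve_unit_ridge(X, Y) - primal)) < 1e-6

    def test_wide_design_uses_dual_path(self, rng):
        X = rng.standard_normal((40, 300))
        y = rng.standard_normal((40, 2))
        model = enc.BandedRidgeCV(
            bands={"a": np.arange(150), "b": np.arange(150, 300)}, alphas=np.array([1.0, 10.0])
        ).fit(X, y)
        assert model.coef_.shape == (300, 2)

    def test_all_zero_design_warns(self):
        with pytest.warns(UserWarning):
            model = enc.BandedRidgeCV(bands={"a": np.arange(3)}).fit(np.zeros((30, 3)), np.ones((30, 2)))
        assert not model.coef_.any()
        assert np.all(model.alpha_ == enc.ALPHA_GRID.max())

    def test_bands_must_partition_columns(self, rng):
        with pytest.raises(ValueError):
            enc.BandedRidgeCV(bands={"a": np.arange(2)}).fit(rng.standard_normal((10, 4)), np.ones(10))


class TestScoring:
    def test_perfect_prediction_scores_one(self, rng):
        X = rng.standard_normal((50, 4))
        w = rng.standard_normal((4, 2))
        assert np.allclose(enc.predict_and_score(w, X, X @ w), 1.0)

    def test_zero_weights_score_zero(self, rng):
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal((50, 2))
        assert np.array_equal(enc.predict_and_score(np.zeros((4, 2)), X, y), [0.0, 0.0])

    def test_matches_hand_formula(self, rng):
        y = rng.standard_normal(10)
        p = rng.standard_normal(10)
        expected = stats.pearsonr(y, p).statistic
        assert enc.pearson_scores(y, p)[0] == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            enc.predict_and_score(np.ones((4, 1)), rng.standard_normal((5, 4)), np.ones(6))


class TestLOSO:
    def _small_problem(self, rng, n_sessions=3, n_tr=90):
        T = n_sessions * n_tr
        X = rng.standard_normal((T, 6))
        w = rng.standard_normal((6, 2))
        y = X @ w
        sessions = np.repeat(np.arange(n_sessions), n_tr)
        return _design(X, runs=sessions, sessions=sessions), y

    def test_each_session_tested_once(self, rng):
        design, y = self._small_problem(rng)
        res = enc.run_loso(design, y)
        assert res.fold_r.shape[0] == 3

    def test_identical_sessions_give_identical_fold_r(self, rng):
        X = rng.standard_normal((60, 4))
        w = rng.standard_normal((4, 1))
        Xr = np.tile(X, (3, 1))
        sessions = np.repeat(np.arange(3), 60)
        design = _design(Xr, runs=sessions, sessions=sessions)
        res = enc.run_loso(design, Xr @ w)
        assert np.allclose(res.fold_r, res.fold_r[0], atol=1e-9)

    def test_tiny_session_excluded_with_warning(self, rng):
        design, y = self._small_problem(rng)
        design.session_index[:10] = 7  # a 10-TR pseudo-session
        design.session_index[10:90] = 0
        with pytest.warns(UserWarning):
            res = enc.run_loso(design, y)
        assert res.fold_r.shape[0] == 3  # sessions 0, 1, 2 only

    def test_recovers_oracle_accuracy(self, small_store, small_truth):
        truth = small_truth
        sd = sim.oracle_noise_sd(small_store, truth, target_r=0.5)
        noisy = sim.GroundTruth(
            labels=truth.labels,
            w_production=truth.w_production,
            w_comprehension=truth.w_comprehension,
            rho=truth.rho,
            ar_coef=truth.ar_coef,
            noise_sd=sd,
            seed=truth.seed,
            shared_dims=truth.shared_dims,
        )
        bold = sim.simulate_bold(small_store, noisy, seed=21)
        design = fir_expand(assemble_design(small_store, "separate", 0, 1))
        res = enc.run_loso(design, bold.values)
        active = truth.labels != "null"
        assert abs(res.mean_r[active].mean() - 0.5) < 0.1


class TestWeightSwap:
    def test_swap_is_involution(self, rng):
        P = 12
        bands = {"production": np.arange(6), "comprehension": np.arange(6, 12)}
        res = enc.EncodingResult(
            weights=rng.standard_normal((P, 5)),
            alphas=np.ones((2, 5)),
            bands=("production", "comprehension"),
            band_columns=bands,
            fold_weights=rng.standard_normal((3, P, 5)),
        )
        back = enc.swap_band_weights(enc.swap_band_weights(res))
        assert np.array_equal(back.weights, res.weights)
        assert np.array_equal(back.fold_weights, res.fold_weights)

    def test_swap_moves_blocks(self, rng):
        bands = {"production": np.arange(3), "comprehension": np.arange(3, 6)}
        res = enc.EncodingResult(
            weights=rng.standard_normal((6, 2)),
            alphas=np.ones((2, 2)),
            bands=("production", "comprehension"),
            band_columns=bands,
        )
        sw = enc.swap_band_weights(res)
        assert np.array_equal(sw.weights[:3], res.weights[3:])
        assert np.array_equal(sw.weights[3:], res.weights[:3])

    def test_single_band_model_rejected(self, rng):
        res = enc.EncodingResult(
            weights=rng.standard_normal((4, 1)),
            alphas=np.ones((1, 1)),
            bands=("unified",),
            band_columns={"unified": np.arange(4)},
        )
        with pytest.raises(ValueError):
            enc.swap_band_weights(res)


class TestBlockPermutation:
    def test_extreme_observation_gets_minimal_p(self, rng):
        y = rng.standard_normal(200)
        p = enc.block_permutation_p(y, y, n_perm=1000, seed=0)
        assert p[0] == pytest.approx(1.0 / 1001.0)

    def test_single_block_degenerates_to_one(self, rng):
        y = rng.standard_normal(40)
        with pytest.warns(UserWarning):
            p = enc.block_permutation_p(y, y + 0.1 * rng.standard_normal(40), block_tr=40, n_perm=50, seed=0)
        assert p[0] == 1.0

    def test_invariant_to_affine_rescaling_of_predictions(self, rng):
        y = rng.standard_normal(100)
        pred = rng.standard_normal(100)
        p1 = enc.block_permutation_p(y, pred, n_perm=100, seed=3)
        p2 = enc.block_permutation_p(y, 5.0 * pred + 2.0, n_perm=100, seed=3)
        assert np.array_equal(p1, p2)

    def test_invalid_n_perm_rejected(self, rng):
        with pytest.raises(ValueError):
            enc.block_permutation_p(rng.standard_normal(100), rng.standard_normal(100), n_perm=0)


class TestFisherAndFDR:
    def test_two_half_p_values_combine(self):
        # chi2 statistic -2*(ln 0.5 + ln 0.5) = 2.7726 on 4 df
        p = enc.fisher_combine(np.array([[0.5], [0.5]]))
        assert p[0] == pytest.approx(0.5966, abs=1e-3)

    def test_all_ones_stay_one(self):
        assert enc.fisher_combine(np.ones((3, 2)))[0] == pytest.approx(1.0)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            p = enc.fisher_combine(np.array([[0.0], [0.5]]))
        assert 0 < p[0] < 1

    def test_bh_matches_step_up_oracle(self):
        pvals = np.linspace(0.001, 0.01, 10)

        def brute_force_bh(p):
            n = len(p)
            order = np.argsort(p)
            q = np.empty(n)
            prev = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * n / rank)
                q[i] = prev
            return q

        assert np.allclose(enc.bh_fdr(pvals), brute_force_bh(pvals))
        rng = np.random.default_rng(1)
        p = rng.uniform(size=57)
        assert np.allclose(enc.bh_fdr(p), brute_force_bh(p))

    def test_q_not_below_p(self, rng):
        p = rng.uniform(size=40)
        assert np.all(enc.bh_fdr(p) >= p - 1e-12)
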