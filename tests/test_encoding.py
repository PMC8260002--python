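"""Preprocessing, delay embedding, ridge fitting and accuracy scoring."""

import numpy as np
import pytest
import scipy.stats

from semrdm.encoding import (
    VoxelEncoder,
    delay_embed,
    detrend_standardize,
    fit_encoding_model,
    r_threshold,
    region_summary,
    score_model,
    significant_fraction,
)
from semrdm.types import AccuracyProfile


class TestDetrend:
    def test_median_filter_residual_by_hand(self):
        """Window-3 reflect-padded medians of (1,2,100,2,1) are (1,2,2,2,1)."""
        raw = np.array([[1.0], [2.0], [100.0], [2.0], [1.0]])
        resid = np.array([0.0, 0.0, 98.0, 0.0, 0.0])
        expected = (resid - resid.mean()) / resid.std(ddof=1)
        out = detrend_standardize(raw, window_seconds=3)
        np.testing.assert_allclose(out.values[:, 0], expected, atol=1e-12)

    def test_output_is_standardized(self):
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((400, 7)) + np.linspace(0, 5, 400)[:, None]
        out = detrend_standardize(raw, window_seconds=120)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_constant_voxel_errors_with_index(self):
        raw = np.ones((300, 2))
        raw[:, 0] = np.random.default_rng(1).standard_normal(300)
        with pytest.raises(ValueError, match="voxel 1"):
            detrend_standardize(raw, window_seconds=9)

    def test_even_window_coerced_to_odd(self):
        raw = np.random.default_rng(2).standard_normal((200, 1))
        out = detrend_standardize(raw, window_seconds=120)  # 121 samples internally
        assert out.values.shape == (200, 1)


class TestDelayEmbed:
    def test_index_arithmetic_by_hand(self):
        x = np.arange(1.0, 9.0)[:, None]
        X = delay_embed(x, delays=(3, 4, 5, 6))
        np.testing.assert_array_equal(X[6], [4.0, 3.0, 2.0, 1.0])  # row t=7, 1-based
        np.testing.assert_array_equal(X[2], [0.0, 0.0, 0.0, 0.0])  # row t=3
        assert X.shape == (8, 4)

    def test_block_layout(self):
        F = np.random.default_rng(0).standard_normal((50, 6))
        X = delay_embed(F, delays=(3, 4, 5, 6))
        assert X.shape == (50, 24)
        np.testing.assert_array_equal(X[10, 0:6], F[7])    # delay-3 block
        np.testing.assert_array_equal(X[10, 18:24], F[4])  # delay-6 block

    def test_single_delay_one_step_shift(self):
        X = delay_embed(np.array([[5.0], [6.0]]), delays=(1,))
        np.testing.assert_array_equal(X, [[0.0], [5.0]])

    def test_invalid_delays_error(self):
        F = np.zeros((10, 2))
        with pytest.raises(ValueError):
            delay_embed(F, delays=(0,))
        with pytest.raises(ValueError):
            delay_embed(F, delays=(10,))


def _ridge_oracle(X, R, lam):
    """Closed-form penalized normal equations."""
    K = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(K), X.T @ R)


class TestRidgeFit:
    def test_matches_closed_form_oracle_small(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((120, 7))
        R = rng.standard_normal((120, 4))
        model = fit_encoding_model(
            X, R, lambda_grid=[2.5], delays=(1,), n_resamples=2, seed=0
        )
        np.testing.assert_allclose(model.weights, _ridge_oracle(X, R, 2.5), atol=1e-8)

    def test_two_feature_toy_selects_oracle_lambda(self):
        """Selected lambda maximizes held-out r as computed by explicit solves."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 2))
        w = np.array([[1.0], [-2.0]])
        R = X @ w + 0.1 * rng.standard_normal((200, 1))
        grid = [0.1, 10.0]
        model = fit_encoding_model(
            X, R, lambda_grid=grid, delays=(1,), n_resamples=5, seed=1
        )
        # independent oracle: replicate the resampling with explicit solves
        rng2 = np.random.default_rng(1)
        scores = np.zeros(2)
        for _ in range(5):
            perm = rng2.permutation(200)
            fit_idx, val_idx = perm[:160], perm[160:]
            for gi, lam in enumerate(sorted(grid)):
                west = _ridge_oracle(X[fit_idx], R[fit_idx], lam)
                pred = X[val_idx] @ west
                scores[gi] += np.corrcoef(pred[:, 0], R[val_idx, 0])[0, 1]
        assert model.lambda_ == sorted(grid)[int(np.argmax(scores))]
        np.testing.assert_allclose(
            model.weights, _ridge_oracle(X, R, model.lambda_), atol=1e-8
        )

    def test_lambda_tie_goes_to_smaller(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 3))
        R = X @ rng.standard_normal((3, 2))
        # noiseless: every tiny lambda scores ~1; near-ties resolve downward
        model = fit_encoding_model(
            X, R, lambda_grid=[1e-9, 1e-8], delays=(1,), n_resamples=3, seed=2
        )
        assert model.lambda_ == 1e-9

    def test_default_resampling_schedule(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((80, 2))
        R = rng.standard_normal((80, 1))
        model = fit_encoding_model(X, R, lambda_grid=[1.0], delays=(1,))
        assert model.fit_meta["n_resamples"] == 10
        assert model.fit_meta["train_fraction"] == 0.8


class TestScoring:
    def _profile_from_r(self, r_values, n_test=1200, seed=0):
        """Build test data whose per-voxel correlations are exactly r_values."""
        rng = np.random.default_rng(seed)
        n = n_test
        pred = rng.standard_normal(n)
        pred = (pred - pred.mean()) / pred.std()
        R = np.empty((n, len(r_values)))
        for j, r in enumerate(r_values):
            raw = rng.standard_normal(n)
            raw -= raw.mean()
            raw -= pred * (pred @ raw) / (pred @ pred)  # orthogonalize
            raw /= raw.std()
            R[:, j] = r * pred + np.sqrt(1 - r**2) * raw
        X = pred[:, None]
        from semrdm.types import EncodingModel

        model = EncodingModel(weights=np.ones((1, len(r_values))), delays=(1,),
                              lambda_=0.0)
        return model, X, R

    def test_identity_and_sign_flip(self):
        model, X, R = self._profile_from_r([1.0 - 1e-12] * 3, n_test=50)
        profile = score_model(model, X, R)
        np.testing.assert_allclose(profile.per_voxel_r, 1.0, atol=1e-6)
        assert profile.significant_mask.all()
        profile_neg = score_model(model, X, -R)
        np.testing.assert_allclose(profile_neg.per_voxel_r, -1.0, atol=1e-6)

    def test_mixed_population_fraction_half(self):
        """50 voxels at r=0.2 (p ~ 1e-12 at n=1200) and 50 at r=0."""
        model, X, R = self._profile_from_r([0.2] * 50 + [0.0] * 50, n_test=1200)
        profile = score_model(model, X, R)
        assert profile.significant_mask[:50].all()
        assert not profile.significant_mask[50:].any()
        assert significant_fraction(profile) == 0.5

    def test_pure_noise_fraction_within_chance(self):
        rng = np.random.default_rng(11)
        n, nv = 500, 800
        X = rng.standard_normal((n, 3))
        R = rng.standard_normal((n, nv))
        from semrdm.types import EncodingModel

        model = EncodingModel(weights=rng.standard_normal((3, nv)), delays=(1,),
                              lambda_=1.0)
        frac = significant_fraction(score_model(model, X, R))
        se = np.sqrt(0.05 * 0.95 / nv)
        assert frac <= 0.05 + 3 * se


class TestRThreshold:
    def test_bonferroni_threshold_rounds_to_011(self):
        assert round(r_threshold(1200, 0.0001, sided="two"), 2) == 0.11

    def test_matches_numeric_inversion(self):
        """Oracle: root-find the r whose t-transform p equals alpha."""
        from scipy.optimize import brentq

        def p_of_r(r, n):
            t = r * np.sqrt((n - 2) / (1 - r**2))
            return 2 * scipy.stats.t.sf(t, df=n - 2)

        r_oracle = brentq(lambda r: p_of_r(r, 1200) - 0.05, 1e-9, 0.999, xtol=1e-12)
        assert abs(r_threshold(1200, 0.05) - r_oracle) < 1e-6

    def test_limits_and_validation(self):
        assert r_threshold(1200, 0.9999) < 1e-3
        with pytest.raises(ValueError):
            r_threshold(1200, 0.0)


class TestRegionSummary:
    def test_single_region_equals_global_mean(self):
        profile = AccuracyProfile(
            per_voxel_r=[0.1, 0.3, 0.2], n_test=100,
            p_values=[0.01, 0.01, 0.5], significant_mask=[True, True, False],
            region_labels=["r0", "r0", "r0"],
        )
        df = region_summary(profile)
        assert df.loc["r0", "mean_r"] == pytest.approx(0.2)

    def test_two_region_means(self):
        profile = AccuracyProfile(
            per_voxel_r=[0.1, 0.3, 0.2], n_test=100,
            p_values=[0.5, 0.5, 0.5], significant_mask=[False, False, False],
            region_labels=["a", "a", "b"],
        )
        df = region_summary(profile)
        assert df.loc["a", "mean_r"] == pytest.approx(0.2)
        assert df.loc["b", "mean_r"] == pytest.approx(0.2)


class TestRecoveryProperties:
    def test_noiseless_recovery_and_perfect_test_r(self):
        from semrdm.synthetic import (
            DEFAULT_DELAY_GAINS,
            make_brain_truth,
            make_embedding_truth,
            make_scene_stream,
            simulate_responses,
        )
        from semrdm.encoding import delay_embed_split

        emb, _ = make_embedding_truth(24, 8, 6, 0.5, seed=1)
        _, series = make_scene_stream(emb, 500, seed=2, n_test=120)
        weights, _ = make_brain_truth(8, 15, 3, 1.0, seed=3)
        resp = simulate_responses(series, weights, noise_sd=0.0, seed=4)
        Xtr, Xte = delay_embed_split(series)
        model = fit_encoding_model(
            Xtr, resp.train_values(), lambda_grid=[1e-8, 1e2], seed=5
        )
        truth_delayed = np.vstack([g * weights for g in DEFAULT_DELAY_GAINS])
        np.testing.assert_allclose(model.weights, truth_delayed, atol=1e-5)
        profile = score_model(model, Xte, resp.test_values())
        np.testing.assert_allclose(profile.per_voxel_r, 1.0, atol=1e-6)

    def test_weight_recovery_improves_with_less_noise(self):
        from semrdm.synthetic import (
            make_brain_truth,
            make_embedding_truth,
            make_scene_stream,
            simulate_responses,
        )
        from semrdm.encoding import delay_embed_split
        from semrdm.rdm import collapse_delays

        emb, _ = make_embedding_truth(30, 10, 6, 0.5, seed=1)
        _, series = make_scene_stream(emb, 700, seed=2, n_test=100)
        weights, _ = make_brain_truth(10, 40, 4, 1.0, seed=3)
        recovery = []
        for noise in (1.0, 0.5, 0.1):
            resp = simulate_responses(series, weights, noise_sd=noise, seed=4)
            Xtr, _ = delay_embed_split(series)
            model = fit_encoding_model(Xtr, resp.train_values(), seed=5)
            est = collapse_delays(model).ravel()
            recovery.append(np.corrcoef(est, weights.ravel())[0, 1])
        assert recovery[0] <= recovery[1] <= recovery[2]
        assert recovery[2] > 0.95


class TestVoxelEncoderEstimator:
    def test_sklearn_contract_and_equivalence(self):
        from semrdm.synthetic import (
            make_brain_truth,
            make_embedding_truth,
            make_scene_stream,
            simulate_responses,
        )

        emb, _ = make_embedding_truth(24, 8, 6, 0.5, seed=1)
        _, series = make_scene_stream(emb, 300, seed=2, n_test=80)
        weights, _ = make_brain_truth(8, 10, 2, 1.0, seed=3)
        resp = simulate_responses(series, weights, noise_sd=0.5, seed=4)
        enc = VoxelEncoder(lambda_grid=[1.0, 100.0], random_state=7)
        assert enc.get_params()["n_resamples"] == 10
        enc.fit(series.train_values(), resp.train_values())
        assert enc.weights_.shape == (32, 10)
        assert enc.lambda_ in (1.0, 100.0)
        pred = enc.predict(series.test_values())
        assert pred.shape == (80, 10)
        assert enc.score(series.test_values(), resp.test_values()) > 0.3
        # estimator path equals the functional path
        from semrdm.encoding import delay_embed

        model = fit_encoding_model(
            delay_embed(series.train_values()), resp.train_values(),
            lambda_grid=[1.0, 100.0], seed=7,
        )
        np.testing.assert_allclose(enc.weights_, model.weights, atol=1e-12)
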