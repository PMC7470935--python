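"""Ridge machinery: dual/primal equivalence, leave-one-out identities,
lagged designs, feature standardization, and decoder behaviour."""

import numpy as np
import pytest

from megdecode import errors
from megdecode.decoders import (
    FeatureScaler,
    LagWindow,
    RidgeSystem,
    TimeWindow,
    build_lagged_design,
    fit_convolution_decoder,
    fit_regression_decoder,
    kernel_ridge_solve,
    loo_select_lambda,
    predict,
    standardize_features,
)
from megdecode.neural import EvokedResponse

TIMES = np.arange(-300, 2001, 10)


def make_response(values, item_id="r", channel_ids=None):
    return EvokedResponse(item_id, values, TIMES, channel_ids or [])


def primal_ridge(R, S, lam):
    """Independent oracle: explicit primal normal equations."""
    d = R.shape[1]
    return np.linalg.solve(R.T @ R + lam * np.eye(d), R.T @ S)


class TestWindows:
    def test_lag_enumeration_inclusive(self):
        np.testing.assert_array_equal(LagWindow(100, 180).lags,
                                      [100, 110, 120, 130, 140, 150, 160,
                                       170, 180])
        np.testing.assert_array_equal(LagWindow(-80, 0).lags,
                                      np.arange(-80, 1, 10))

    def test_invalid_windows(self):
        with pytest.raises(ValueError):
            LagWindow(200, 100)
        with pytest.raises(ValueError):
            TimeWindow(500, 200)
        with pytest.raises(ValueError):
            TimeWindow(0, 1200)


class TestFeatureStandardization:
    def test_static_two_items(self):
        std, _ = standardize_features([np.array([2.0]), np.array([4.0])])
        np.testing.assert_allclose(np.ravel(std), [-1.0, 1.0])

    def test_categorical_passthrough_bit_identical(self, rng):
        tracks = [rng.integers(0, 2, (5, 30)).astype(float)
                  for _ in range(3)]
        std, _ = standardize_features(tracks, "time_varying",
                                      categorical=True)
        for a, b in zip(std, tracks):
            np.testing.assert_array_equal(a, b)

    def test_band_pooling_matches_hand_arithmetic(self):
        """2 items x 3 frames, one band: pooled mean/SD over all 6 values."""
        f1 = np.array([[1.0, 2.0, 3.0]])
        f2 = np.array([[5.0, 6.0, 7.0]])
        pooled = np.array([1, 2, 3, 5, 6, 7], dtype=float)
        std, _ = standardize_features([f1, f2], "time_varying")
        np.testing.assert_allclose(
            std[0][0], (f1[0] - pooled.mean()) / pooled.std())

    def test_zero_variance_feature_zeroed(self):
        std, _ = standardize_features([np.array([3.0, 1.0]),
                                       np.array([3.0, 2.0])])
        assert std[0][0] == 0.0 and std[1][0] == 0.0


class TestLaggedDesign:
    def test_shape_counting(self, rng):
        responses = [make_response(rng.standard_normal((3, TIMES.size)))
                     for _ in range(2)]
        design = build_lagged_design(responses, [5, 5], LagWindow(100, 180))
        assert design.matrix.shape == (10, 27)

    def test_zero_lag_is_identity(self, rng):
        r = make_response(rng.standard_normal((4, TIMES.size)))
        design = build_lagged_design([r], [8], LagWindow(0, 0))
        onset = np.flatnonzero(TIMES == 0)[0]
        np.testing.assert_array_equal(
            design.matrix, r.values[:, onset:onset + 8].T)

    def test_entry_indexing_on_hand_built_toy(self, rng):
        responses = [make_response(rng.standard_normal((3, TIMES.size)))
                     for _ in range(2)]
        design = build_lagged_design(responses, [5, 5],
                                     LagWindow(100, 180))
        # row of item 1, frame 3; column of channel 2, lag 120
        row = 5 + 3
        col = 2 * 9 + 2          # channel-major, lags step 10 from 100
        t_idx = np.flatnonzero(TIMES == 30 + 120)[0]
        assert design.matrix[row, col] == responses[1].values[2, t_idx]

    def test_out_of_epoch_raises(self, rng):
        r = make_response(rng.standard_normal((2, TIMES.size)))
        with pytest.raises(errors.OutOfEpochError):
            build_lagged_design([r], [200], LagWindow(100, 180))


class TestKernelRidge:
    def test_zero_targets_give_zero_solution(self, rng):
        R = rng.standard_normal((6, 4))
        alpha, w = kernel_ridge_solve(R, np.zeros(6), 1.0)
        np.testing.assert_allclose(alpha, 0.0)
        np.testing.assert_allclose(w, 0.0)

    def test_dual_equals_primal_on_6x4(self, rng):
        R = rng.standard_normal((6, 4))
        S = rng.standard_normal(6)
        _, w_dual = kernel_ridge_solve(R, S, 0.1)
        np.testing.assert_allclose(w_dual, primal_ridge(R, S, 0.1),
                                   rtol=1e-8, atol=1e-10)

    def test_shrinkage_monotone_in_lambda(self, rng):
        R = rng.standard_normal((8, 5))
        S = rng.standard_normal(8)
        norms = [np.linalg.norm(kernel_ridge_solve(R, S, lam)[1])
                 for lam in (0.1, 1.0, 10.0, 100.0, 1e4)]
        assert np.all(np.diff(norms) < 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            kernel_ridge_solve(np.array([[np.nan]]), np.array([1.0]), 1.0)


class TestLeaveOneOutSelection:
    def test_single_element_grid(self, rng):
        R, S = rng.standard_normal((5, 3)), rng.standard_normal(5)
        assert loo_select_lambda(R, S, [7.5]) == 7.5

    def test_closed_form_matches_explicit_refits(self, rng):
        """Oracle: n explicit refits, each leaving one row out."""
        R = rng.standard_normal((8, 3))
        S = rng.standard_normal(8)
        grid = [0.01, 1.0, 100.0]
        sse_closed = RidgeSystem(R).loo_sse(grid, S)
        for gi, lam in enumerate(grid):
            sse = 0.0
            for i in range(8):
                keep = [k for k in range(8) if k != i]
                w = primal_ridge(R[keep], S[keep], lam)
                sse += (S[i] - R[i] @ w) ** 2
            assert sse_closed[gi, 0] == pytest.approx(sse, rel=1e-8)

    def test_grouped_loo_matches_explicit_block_refits(self, rng):
        """Leaving out whole items (row blocks) matches refits without
        those blocks."""
        R = rng.standard_normal((12, 4))
        S = rng.standard_normal((12, 2))
        groups = [np.arange(0, 4), np.arange(4, 9), np.arange(9, 12)]
        grid = [0.5, 50.0]
        sse_closed = RidgeSystem(R).loo_sse(grid, S, groups)
        for gi, lam in enumerate(grid):
            sse = np.zeros(2)
            for g in groups:
                keep = np.setdiff1d(np.arange(12), g)
                w = primal_ridge(R[keep], S[keep], lam)
                sse += ((S[g] - R[g] @ w) ** 2).sum(axis=0)
            np.testing.assert_allclose(sse_closed[gi], sse, rtol=1e-8)

    def test_pure_noise_selects_maximal_lambda(self):
        grid = [0.01, 1.0, 100.0]
        hits = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            lam = loo_select_lambda(r.standard_normal((30, 20)),
                                    r.standard_normal(30), grid)
            hits += lam == 100.0
        assert hits >= 45

    def test_tie_breaks_to_smallest(self):
        R = np.zeros((4, 2))
        S = np.ones(4)
        # all-zero design: identical LOO error for every lambda
        assert loo_select_lambda(R, S, [10.0, 0.1, 1000.0]) == 0.1


def simulate_trf_responses(rng, n_items, n_channels, n_bands, T, lags_ms,
                           noise_sd=0.0):
    """Forward model for decoder tests: known TRF, causal lagged mixing."""
    onset = np.flatnonzero(TIMES == 0)[0]
    h = rng.standard_normal((n_channels, n_bands, len(lags_ms)))
    feats, resps = [], []
    for i in range(n_items):
        s = rng.standard_normal((n_bands, T))
        r = np.zeros((n_channels, TIMES.size))
        for li, lag in enumerate(lags_ms):
            j0 = onset + lag // 10
            r[:, j0:j0 + T] += h[:, :, li] @ s
        r += noise_sd * rng.standard_normal(r.shape)
        feats.append(s)
        resps.append(make_response(r, item_id=f"i{i}"))
    return resps, feats


class TestConvolutionDecoder:
    def test_noiseless_recovery_at_matched_lags(self, rng):
        # single-lag forward model: the inverse map is exactly linear in
        # the lagged window, so in-sample reconstruction is near perfect
        resps, feats = simulate_trf_responses(rng, 8, 4, 3, 40, [100])
        dec = fit_convolution_decoder(resps, feats, LagWindow(100, 120),
                                      grid=[1e-6])
        rs = []
        for e, s in zip(resps, feats):
            p = predict(dec, e, 40)
            rs.append(np.corrcoef(p.ravel(), s.ravel())[0, 1])
        assert np.mean(rs) >= 0.99

    def test_zero_feature_gets_zero_weights(self, rng):
        resps, feats = simulate_trf_responses(rng, 6, 3, 2, 30, [100])
        feats = [np.vstack([f, np.zeros((1, 30))]) for f in feats]
        dec = fit_convolution_decoder(resps, feats, LagWindow(100, 120),
                                      grid=[1.0])
        np.testing.assert_allclose(dec.weights[:, -1], 0.0, atol=1e-12)

    def test_permuted_labels_destroy_heldout_reconstruction(self):
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            resps, feats = simulate_trf_responses(rng, 8, 3, 2, 30, [100],
                                                  noise_sd=1.0)
            perm = (np.arange(7) + 1 + rng.integers(0, 6)) % 7  # derangement
            dec = fit_convolution_decoder(
                [resps[p] for p in perm], [feats[k] for k in range(7)],
                LagWindow(100, 120), grid=[1.0])
            p = predict(dec, resps[7], 30)
            rs.append(np.corrcoef(p.ravel(), feats[7].ravel())[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_single_lag_equals_per_frame_regression_on_t1_toy(self, rng):
        """With one frame per item and one lag, the convolution decoder's
        design equals the static per-frame design, so predictions match a
        regression on the single lagged copy."""
        resps, feats = simulate_trf_responses(rng, 9, 3, 2, 1, [100])
        lw = LagWindow(100, 100)
        dec = fit_convolution_decoder(resps, feats, lw, grid=[1.0])
        design = build_lagged_design(resps, [1] * 9, lw)
        w_oracle = primal_ridge(design.matrix,
                                np.vstack([f.T for f in feats]), 1.0)
        test = resps[0]
        np.testing.assert_allclose(predict(dec, test, 1).ravel(),
                                   (build_lagged_design([test], [1], lw)
                                    .matrix @ w_oracle).ravel(),
                                   rtol=1e-8, atol=1e-10)

    def test_channel_permutation_invariance(self, rng):
        resps, feats = simulate_trf_responses(rng, 6, 4, 2, 20, [100, 110])
        dec = fit_convolution_decoder(resps, feats, LagWindow(100, 110),
                                      grid=[1.0])
        perm = [2, 0, 3, 1]
        resps_p = []
        for e in resps:
            p = make_response(e.values[perm], item_id=e.item_id,
                              channel_ids=[e.channel_ids[k] for k in perm])
            resps_p.append(p)
        dec_p = fit_convolution_decoder(resps_p, feats,
                                        LagWindow(100, 110), grid=[1.0])
        np.testing.assert_allclose(predict(dec, resps[0], 20),
                                   predict(dec_p, resps_p[0], 20),
                                   rtol=1e-8, atol=1e-10)

    def test_features_decoded_independently(self, rng):
        resps, feats = simulate_trf_responses(rng, 6, 3, 3, 25, [100])
        lw = LagWindow(100, 120)
        full = fit_convolution_decoder(resps, feats, lw, grid=[1.0, 10.0])
        dropped = fit_convolution_decoder(
            resps, [f[:2] for f in feats], lw, grid=[1.0, 10.0])
        np.testing.assert_allclose(full.weights[:, :2],
                                   dropped.weights, rtol=1e-10)


class TestRegressionDecoder:
    def test_linear_identifiability_noiseless(self, rng):
        """Static features exactly linear in the windowed response are
        recovered exactly for a held-out item (small-dimensional design)."""
        tw = TimeWindow(0, 50)      # 3 channels x 5 samples = 15 columns
        w_true = rng.standard_normal((15, 4))
        resps, feats = [], []
        for i in range(20):
            r = rng.standard_normal((3, TIMES.size))
            resps.append(make_response(r, item_id=f"i{i}"))
            mask = (TIMES >= 0) & (TIMES < 50)
            feats.append(r[:, mask].ravel() @ w_true)
        dec = fit_regression_decoder(resps[:19], feats[:19], tw,
                                     grid=[1e-8])
        np.testing.assert_allclose(predict(dec, resps[19]), feats[19],
                                   rtol=1e-5, atol=1e-6)

    def test_design_column_counting(self, rng):
        resps = [make_response(rng.standard_normal((56, TIMES.size)),
                               item_id=f"i{k}") for k in range(4)]
        feats = [rng.standard_normal(3) for _ in range(4)]
        dec = fit_regression_decoder(resps, feats, TimeWindow(0, 1000),
                                     grid=[1.0])
        assert dec.weights.shape == (56 * 100, 3)

    def test_needs_three_items(self, rng):
        resps = [make_response(rng.standard_normal((2, TIMES.size)))
                 for _ in range(2)]
        with pytest.raises(ValueError):
            fit_regression_decoder(resps, [np.ones(2)] * 2,
                                   TimeWindow(0, 100))


class TestPredict:
    def test_zero_response_zero_reconstruction(self, rng):
        resps, feats = simulate_trf_responses(rng, 5, 3, 2, 20, [100])
        dec = fit_convolution_decoder(resps, feats, LagWindow(100, 110),
                                      grid=[1.0])
        zero = make_response(np.zeros((3, TIMES.size)))
        np.testing.assert_allclose(predict(dec, zero, 20), 0.0)

    def test_training_item_close_to_in_sample_fit(self, rng):
        resps, feats = simulate_trf_responses(rng, 8, 3, 2, 30,
                                              [100, 110], noise_sd=0.1)
        lw = LagWindow(100, 110)
        dec = fit_convolution_decoder(resps, feats, lw, grid=[0.01])
        design = build_lagged_design(resps, [30] * 8, lw)
        in_sample = design.matrix @ dec.weights
        stacked_pred = np.vstack(
            [predict(dec, e, 30).T for e in resps])
        np.testing.assert_allclose(stacked_pred, in_sample, rtol=1e-8,
                                   atol=1e-10)

    def test_prediction_linear_in_weights(self, rng):
        resps, feats = simulate_trf_responses(rng, 5, 3, 2, 20, [100])
        dec = fit_convolution_decoder(resps, feats, LagWindow(100, 110),
                                      grid=[1.0])
        base = predict(dec, resps[0], 20)
        dec.coef = 2.0 * dec.coef
        np.testing.assert_allclose(predict(dec, resps[0], 20), 2 * base,
                                   rtol=1e-12)

    def test_channel_mismatch_raises(self, rng):
        resps, feats = simulate_trf_responses(rng, 5, 3, 2, 20, [100])
        dec = fit_convolution_decoder(resps, feats, LagWindow(100, 110),
                                      grid=[1.0])
        other = make_response(np.zeros((3, TIMES.size)),
                              channel_ids=["x", "y", "z"])
        with pytest.raises(ValueError):
            predict(dec, other, 20)


class TestDualPrimalProperty:
    @pytest.mark.parametrize("lam", [1e-3, 1.0, 1e3])
    def test_random_suite(self, lam, rng):
        for _ in range(10):
            n, d = rng.integers(3, 20), rng.integers(2, 30)
            R = rng.standard_normal((int(n), int(d)))
            S = rng.standard_normal(int(n))
            _, w = kernel_ridge_solve(R, S, lam)
            w_p = primal_ridge(R, S, lam)
            np.testing.assert_allclose(w, w_p, rtol=1e-8, atol=1e-9)
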