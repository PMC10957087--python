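"""Lagged design construction, ridge solver, TRF and decoder estimation."""

import numpy as np
import pytest
from scipy import stats
from scipy.sparse.linalg import lsqr

from speechtrack import lagged_ridge as lrdg
from speechtrack.synthetic_data import one_over_f_noise, simulate_envelope_pair


def spec_from_lags(lags, rate=1000.0):
    return lrdg.LagSpec(min(lags) * 1000.0 / rate, max(lags) * 1000.0 / rate,
                        rate)


class TestLagMatrix:
    def test_impulse_lag_sign_convention(self):
        x = np.zeros(10)
        x[5] = 1.0
        spec = spec_from_lags([-2, 2])  # contiguous lags -2..2
        assert np.array_equal(spec.lag_samples, [-2, -1, 0, 1, 2])
        X = lrdg.build_lag_matrix(x, spec)
        assert X.shape == (10, 5)
        assert np.flatnonzero(X[:, 0]) == [3]   # lag -2: appears earlier
        assert np.flatnonzero(X[:, 2]) == [5]   # lag 0 reproduces the impulse
        assert np.flatnonzero(X[:, 4]) == [7]   # lag +2: appears later

    def test_two_inputs_three_lags_shape_and_order(self, rng):
        x = rng.standard_normal((2, 10))
        X = lrdg.build_lag_matrix(x, spec_from_lags([0, 1, 2]))
        assert X.shape == (10, 6)
        # input-major order: columns 0-2 from input 0, 3-5 from input 1
        assert np.array_equal(X[:, 0], x[0])
        assert np.array_equal(X[:, 3], x[1])

    def test_degenerate_and_invalid_lag_windows(self):
        # a zero-width window still yields the single lag 0
        X = lrdg.build_lag_matrix(np.ones(5), lrdg.LagSpec(0.0, 0.0, 64.0))
        assert X.shape == (5, 1)
        with pytest.raises(ValueError):
            lrdg.LagSpec(10.0, -10.0, 64.0)
        with pytest.raises(ValueError, match="finite"):
            lrdg.build_lag_matrix(np.array([np.nan, 1.0]),
                                  lrdg.LagSpec(0.0, 0.0, 64.0))


class TestFitRidge:
    def test_zero_penalty_equals_ols(self, rng):
        X = rng.standard_normal((50, 6))
        y = rng.standard_normal(50)
        w = lrdg.fit_ridge(X, y, 0.0)
        w_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(w, w_ols, atol=1e-8)

    def test_infinite_shrinkage_limit(self, rng):
        X = rng.standard_normal((50, 6))
        y = rng.standard_normal(50)
        w = lrdg.fit_ridge(X, y, 1e12)
        assert np.linalg.norm(w) < 1e-6

    def test_duplicate_columns_share_weight(self, rng):
        x = rng.standard_normal((40, 1))
        X = np.hstack([x, x, rng.standard_normal((40, 1))])
        w = lrdg.fit_ridge(X, rng.standard_normal(40), 0.5)
        assert np.isclose(w[0], w[1], rtol=1e-10)

    def test_matches_damped_least_squares_oracle(self, rng):
        """Closed form agrees with an independent iterative solver."""
        for _ in range(10):
            X = rng.standard_normal((60, 8))
            y = rng.standard_normal(60)
            lam = float(rng.uniform(0.1, 10.0))
            w = lrdg.fit_ridge(X, y, lam)
            w_ref = lsqr(X, y, damp=np.sqrt(lam), atol=1e-14, btol=1e-14,
                         iter_lim=10_000)[0]
            assert np.linalg.norm(w - w_ref) / np.linalg.norm(w_ref) < 1e-6

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            lrdg.fit_ridge(rng.standard_normal((5, 2)), np.zeros(5), -1.0)

    def test_gradient_optimality(self, rng):
        X = rng.standard_normal((80, 10))
        Y = rng.standard_normal((80, 3))
        lam = 2.0
        w = lrdg.fit_ridge(X, Y, lam)
        grad = X.T @ (X @ w - Y) + lam * w
        assert np.linalg.norm(grad) < 1e-6 * np.linalg.norm(X.T @ Y)


class TestEstimateTrf:
    def test_pure_delay_recovered_at_correct_lag(self, rng):
        rate = 128.0
        delay = 3
        envs, eegs = [], []
        for _ in range(3):
            env = rng.standard_normal(832)
            eeg = np.zeros((1, 832))
            eeg[0, delay:] = env[:-delay]
            envs.append(env)
            eegs.append(eeg)
        trf, fold_r = lrdg.estimate_trf(envs, eegs, rate, lam=1e-3,
                                        t_min_ms=-200, t_max_ms=200)
        peak_ms = trf.lags_ms[np.argmax(trf.weights[0])]
        assert abs(peak_ms - delay * 1000 / rate) <= 1000 / rate
        assert fold_r.mean() > 0.99

    def test_noise_eeg_gives_chance_prediction(self, rng):
        envs = [rng.standard_normal(416) for _ in range(20)]
        eegs = [rng.standard_normal((2, 416)) for _ in range(20)]
        _, fold_r = lrdg.estimate_trf(envs, eegs, 64.0, lam=10.0)
        t = stats.ttest_1samp(fold_r.mean(axis=1), 0.0, alternative="greater")
        assert t.pvalue > 0.05

    def test_known_gamma_kernels_recovered(self, rng):
        rate, n = 128.0, 832
        t = np.arange(64) / rate
        k1 = stats.gamma.pdf(t, 3, scale=0.03)
        k2 = stats.gamma.pdf(t, 5, scale=0.04) * -0.8
        envs, eegs = [], []
        gen = np.random.default_rng(7)
        for _ in range(6):
            env, _ = simulate_envelope_pair(n / rate, rate, gen)
            sig = np.vstack([np.convolve(env, k, mode="full")[:n]
                             for k in (k1, k2)])
            noise = one_over_f_noise(sig.shape, rate, gen)  # EEG-band noise
            noise *= np.sqrt(np.mean(sig**2) / 10)  # SNR 10
            envs.append(env)
            eegs.append(sig + noise)
        trf, _ = lrdg.estimate_trf(envs, eegs, rate, lam=1e3)
        w, _ = trf.nonnegative()
        for ch, k in enumerate((k1, k2)):
            r = np.corrcoef(w[ch, :64], k)[0, 1]
            assert r > 0.9

    def test_positive_kernel_yields_positive_peak(self, rng):
        rate, n = 64.0, 416
        k = stats.gamma.pdf(np.arange(32) / rate, 3, scale=0.05)
        envs, eegs = [], []
        for _ in range(4):
            env = rng.standard_normal(n)
            eegs.append(np.convolve(env, k, mode="full")[None, :n])
            envs.append(env)
        trf, _ = lrdg.estimate_trf(envs, eegs, rate, lam=1.0)
        w, _ = trf.nonnegative()
        assert w[0, np.argmax(np.abs(w[0]))] > 0

    def test_single_trial_rejected(self, rng):
        with pytest.raises(ValueError, match=">=2 trials"):
            lrdg.estimate_trf([rng.standard_normal(416)],
                              [rng.standard_normal((1, 416))], 64.0)

    def test_heldout_accuracy_monotone_in_snr(self):
        rate, n = 64.0, 416
        gen = np.random.default_rng(11)
        k = stats.gamma.pdf(np.arange(32) / rate, 3, scale=0.05)
        envs = [gen.standard_normal(n) for _ in range(6)]
        clean = [np.convolve(e, k, mode="full")[None, :n] for e in envs]
        noises = [gen.standard_normal(c.shape) for c in clean]
        means = []
        for snr in (10.0, 1.0, 0.1):
            eegs = [c + nz * np.sqrt(np.mean(c**2) / snr)
                    for c, nz in zip(clean, noises)]
            _, fold_r = lrdg.estimate_trf(envs, eegs, rate, lam=10.0)
            means.append(fold_r.mean())
        assert means[0] > means[1] > means[2]


class TestReconstruction:
    def test_invertible_mixing_reconstructs_heldout_envelope(self, rng):
        rate, n = 64.0, 416
        A = np.array([[1.0, 0.4], [-0.3, 1.2]])  # invertible mixing
        envs, eegs = [], []
        for _ in range(4):
            env = rng.standard_normal(n)
            other = rng.standard_normal(n)
            eegs.append(A @ np.vstack([env, other]))
            envs.append(env)
        recons, r = lrdg.reconstruct_envelope(eegs, envs, rate, lam=1e-4)
        assert r.min() > 0.99
        assert recons[0].shape == (n,)

    def test_unrelated_eeg_reconstruction_centred_on_zero(self, rng):
        envs = [rng.standard_normal(416) for _ in range(16)]
        eegs = [rng.standard_normal((3, 416)) for _ in range(16)]
        _, r = lrdg.reconstruct_envelope(eegs, envs, 64.0, lam=10.0)
        t = stats.ttest_1samp(r, 0.0)
        assert t.pvalue > 0.01

    def test_eeg_scaling_invariance(self, rng):
        envs = [rng.standard_normal(416) for _ in range(3)]
        eegs = [rng.standard_normal((2, 416)) for _ in range(3)]
        _, r1 = lrdg.reconstruct_envelope(eegs, envs, 64.0, lam=5.0)
        _, r2 = lrdg.reconstruct_envelope([10.0 * e for e in eegs], envs,
                                          64.0, lam=5.0)
        assert np.allclose(r1, r2, atol=1e-8)

    def test_channel_mismatch_rejected(self, rng):
        eegs = [rng.standard_normal((2, 416)), rng.standard_normal((3, 416))]
        envs = [rng.standard_normal(416)] * 2
        with pytest.raises(ValueError, match="channel count"):
            lrdg.reconstruct_envelope(eegs, envs, 64.0)
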