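"""CCA, filter-bank CCA and TRCA: oracles, invariances, classification."""

import numpy as np
import pytest
from scipy import optimize

from ssvep_depth_lab.decoding import (
    FilterBankSpec,
    TrcaClassifier,
    TrcaModel,
    _argmax_lowest,
    cca_classify,
    cca_correlation,
    fbcca_classify,
    make_references,
    trca_filter,
    trca_train,
)
from ssvep_depth_lab.preprocess import EpochSet


def _cca_oracle(X, Y, n_starts=8, seed=0):
    """Directly maximize |corr(wx'X, wy'Y)| by numerical optimization."""
    X = X - X.mean(axis=1, keepdims=True)
    Y = Y - Y.mean(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)

    def neg_corr(w):
        wx, wy = w[: X.shape[0]], w[X.shape[0] :]
        x, y = wx @ X, wy @ Y
        denom = np.linalg.norm(x) * np.linalg.norm(y)
        if denom < 1e-30:
            return 0.0
        return -abs(float(x @ y / denom))

    best = 0.0
    for _ in range(n_starts):
        w0 = rng.standard_normal(X.shape[0] + Y.shape[0])
        res = optimize.minimize(neg_corr, w0, method="Nelder-Mead",
                                options={"maxiter": 20000, "xatol": 1e-10,
                                         "fatol": 1e-12})
        best = max(best, -res.fun)
    return best


class TestReferences:
    def test_construction(self):
        refs = make_references([11.25], 2, 250.0, 1000)  # 4 s: whole cycles
        Y = refs[11.25]
        assert Y.shape == (4, 1000)
        freqs = np.fft.rfftfreq(1000, 1 / 250.0)
        for row, expect in zip(Y, (11.25, 11.25, 22.5, 22.5)):
            peak = freqs[np.argmax(np.abs(np.fft.rfft(row)))]
            assert peak == pytest.approx(expect, abs=0.2)
        # whole number of cycles -> zero mean
        assert np.allclose(Y.mean(axis=1), 0.0, atol=1e-12)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            make_references([18.0], 3, 100.0, 500)


class TestCca:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((3, 300))
        rho, _, _ = cca_correlation(Y, Y)
        assert rho == pytest.approx(1.0, abs=1e-6)

    def test_single_row_reduces_to_pearson_magnitude(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(400)
        y = 0.3 * x + rng.standard_normal(400)
        rho, _, _ = cca_correlation(x[None], y[None])
        assert rho == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), abs=1e-9)

    def test_matches_direct_optimization_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((3, 200))
        Y = rng.standard_normal((4, 200))
        rho, _, _ = cca_correlation(X, Y)
        assert rho == pytest.approx(_cca_oracle(X, Y), abs=1e-4)

    def test_invariance_to_channel_mixing(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((5, 500))
        Y = rng.standard_normal((4, 500))
        A = rng.standard_normal((5, 5)) + 3 * np.eye(5)
        rho1, _, _ = cca_correlation(X, Y)
        rho2, _, _ = cca_correlation(A @ X, Y)
        assert abs(rho1 - rho2) < 1e-8

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cca_correlation(np.zeros((5, 6)), np.zeros((4, 6)))


class TestCcaClassify:
    def test_planted_signal_recovered(self, planted_epoch):
        refs = make_references([7.5, 11.25, 18.0], 2, 250.0, 1250)
        res = cca_classify(planted_epoch, refs)
        assert res.predicted_frequency == 11.25
        assert res.correlations[11.25] > 0.99
        assert all(0 <= r <= 1 for r in res.correlations.values())

    def test_length_mismatch_rejected(self, planted_epoch):
        refs = make_references([7.5], 2, 250.0, 1000)
        with pytest.raises(ValueError):
            cca_classify(planted_epoch, refs)

    def test_exact_tie_goes_to_lowest_frequency(self):
        assert _argmax_lowest((18.0, 7.5, 11.25), {18.0: 0.5, 7.5: 0.5, 11.25: 0.2}) == 7.5


class TestFbcca:
    def test_subband_weights(self):
        # w(n) = n^(-1.25) + 0.25, independently evaluated
        w = FilterBankSpec().weights
        assert w == pytest.approx([1.25, 0.6704482, 0.5032786, 0.4267767], abs=1e-6)
        assert (np.diff(w) < 0).all() and (w > 0).all()

    def test_planted_signal_recovered(self, planted_epoch):
        refs = make_references([7.5, 11.25, 18.0], 2, 250.0, 1250)
        res = fbcca_classify(planted_epoch, refs)
        assert res.predicted_frequency == 11.25
        assert res.features[11.25] == max(res.features.values())
        assert all(v >= 0 for v in res.features.values())

    def test_single_fullband_reduces_to_cca(self, small_session, strong_session):
        """A single band weights all classes equally, so the decision is
        exactly CCA's on the band-filtered trial — and on clearly
        decodable trials it coincides with plain CCA."""
        from scipy import signal as sps

        _, stim, refs = small_session
        bank = FilterBankSpec(bands=((0.1, 40.0),))
        sos = sps.butter(bank.order, [0.1, 40.0], btype="bandpass",
                         fs=refs.sample_rate, output="sos")
        for trial in stim:
            fb = fbcca_classify(trial, refs, bank)
            cca_filtered = cca_classify(sps.sosfiltfilt(sos, trial, axis=-1), refs)
            assert fb.predicted_frequency == cca_filtered.predicted_frequency
        _, strong, refs_s = strong_session
        for trial in strong:
            assert (
                fbcca_classify(trial, refs_s, bank).predicted_frequency
                == cca_classify(trial, refs_s).predicted_frequency
            )

    def test_invalid_band_rejected(self, planted_epoch):
        refs = make_references([7.5], 2, 250.0, 1250)
        with pytest.raises(ValueError):
            fbcca_classify(planted_epoch, refs, FilterBankSpec(bands=((10.0, 200.0),)))


class TestTrca:
    def _toy_trials(self, K=6, T=400, seed=5, shared_gain=1.0):
        """2-channel trials: channel 0 carries a shared waveform, channel 1 noise."""
        rng = np.random.default_rng(seed)
        shared = rng.standard_normal(T)
        trials = np.empty((K, 2, T))
        for k in range(K):
            trials[k, 0] = shared_gain * shared + 0.3 * rng.standard_normal(T)
            trials[k, 1] = rng.standard_normal(T)
        return trials

    def test_identical_trials_perfect_consistency(self):
        rng = np.random.default_rng(0)
        one = rng.standard_normal((3, 300))
        trials = np.stack([one] * 5)
        model = trca_train(trials)
        w = model.filters[:, 0]
        proj = [w @ (t - t.mean(axis=1, keepdims=True)) for t in trials]
        assert np.corrcoef(proj[0], proj[1])[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_signal_channel_dominates_and_matches_grid_oracle(self):
        trials = self._toy_trials()
        model = trca_train(trials)
        w = model.filters[:, 0]
        assert abs(w[0]) > abs(w[1])
        # brute-force oracle over filter angle for the Rayleigh quotient
        best = -np.inf
        for theta in np.linspace(0, np.pi, 3601, endpoint=False):
            v = np.array([np.cos(theta), np.sin(theta)])
            q = (v @ model.s_t @ v) / (v @ model.s_n @ v)
            best = max(best, q)
        q_top = (w @ model.s_t @ w) / (w @ model.s_n @ w)
        assert q_top == pytest.approx(best, rel=1e-6)

    def test_generalized_eigen_residual(self):
        trials = self._toy_trials(K=8, T=500, seed=9)
        model = trca_train(trials)
        for lam, w in zip(model.eigenvalues, model.filters.T):
            lhs = model.s_t @ w
            residual = np.linalg.norm(lhs - lam * model.s_n @ w)
            assert residual / np.linalg.norm(lhs) < 1e-8

    def test_no_random_filter_beats_top_eigenvector(self):
        trials = self._toy_trials(K=8, T=500, seed=13)
        model = trca_train(trials)
        w = model.filters[:, 0]
        q_top = (w @ model.s_t @ w) / (w @ model.s_n @ w)
        rng = np.random.default_rng(99)
        draws = rng.standard_normal((1000, 2))
        quotients = np.einsum("ic,cd,id->i", draws, model.s_t, draws) / np.einsum(
            "ic,cd,id->i", draws, model.s_n, draws
        )
        assert quotients.max() <= q_top * (1 + 1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            trca_train(np.zeros((1, 3, 100)))
        with pytest.raises(ValueError):
            trca_train(np.zeros((3, 100, 50)))

    def test_identity_passthrough_filter(self):
        data = np.random.default_rng(2).normal(size=(4, 1, 200))
        eps = EpochSet(data=data, sample_rate=250.0, window=(0.0, 0.8),
                       labels=[{}] * 4, channel_names=("Oz",))
        model = TrcaModel(filters=np.array([[1.0]]), eigenvalues=np.array([1.0]),
                          s_t=np.eye(1), s_n=np.eye(1))
        out = trca_filter(eps, model, 1)
        assert np.array_equal(out.data, data)

    def test_zero_epochs_project_to_zero(self):
        data = np.zeros((2, 3, 100))
        eps = EpochSet(data=data, sample_rate=250.0, window=(0.0, 0.4),
                       labels=[{}] * 2, channel_names=("a", "b", "c"))
        model = trca_train(np.random.default_rng(1).normal(size=(4, 3, 200)))
        assert np.allclose(trca_filter(eps, model, 2).data, 0.0)

    def test_component_count_guard(self):
        model = trca_train(np.random.default_rng(1).normal(size=(4, 3, 200)))
        eps = EpochSet(data=np.zeros((1, 3, 100)), sample_rate=250.0,
                       window=(0.0, 0.4), labels=[{}], channel_names=("a", "b", "c"))
        with pytest.raises(ValueError):
            trca_filter(eps, model, 4)


def test_trca_classifier_separates_planted_classes():
    """Template matching on TRCA-filtered trials recovers noiseless classes."""
    fs, n = 250.0, 1250
    t = np.arange(n) / fs
    rng = np.random.default_rng(3)
    gains = np.array([1.0, 0.8, 0.6])
    trials, labels = [], []
    for f in (7.5, 11.25, 18.0):
        for _ in range(4):
            wave = np.sin(2 * np.pi * f * t) + 0.1 * rng.standard_normal(n)
            trials.append(np.outer(gains, wave))
            labels.append(f)
    trials, labels = np.array(trials), np.array(labels)
    clf = TrcaClassifier().fit(trials, labels)
    assert (clf.predict(trials) == labels).all()
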