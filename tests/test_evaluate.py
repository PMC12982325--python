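"""SNR estimation, spectra, CV splitting, accuracy and statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from ssvep_depth_lab.evaluate import (
    CvScheme,
    accuracy,
    amplitude_spectrum,
    bonferroni_alpha,
    linear_fit,
    make_cv_splits,
    snr_db,
    snr_from_powers,
    wilcoxon_signed_rank,
)


def _psd_oracle(x, fs, resolution=0.05):
    """Independently coded zero-padded rectangular periodogram."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    nfft = int(round(fs / resolution))
    t = np.arange(n)
    freqs = np.arange(nfft // 2 + 1) * resolution
    psd = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        z = np.sum(x * np.exp(-2j * np.pi * f / fs * t))
        psd[i] = abs(z) ** 2 / (fs * n)
    psd[1:-1] *= 2.0
    return freqs, psd


def _snr_oracle(x, fs, f0):
    freqs, psd = _psd_oracle(x, fs)
    p_f0 = psd[int(round(f0 / 0.05))]
    p_2f0 = psd[int(round(2 * f0 / 0.05))]
    noise = [
        psd[i]
        for i, f in enumerate(freqs)
        if f > 0
        and (abs(f - f0) <= 1.0 + 1e-9 or abs(f - 2 * f0) <= 1.0 + 1e-9)
        and abs(f - f0) > 0.1 + 1e-9
        and abs(f - 2 * f0) > 0.1 + 1e-9
    ]
    return 10 * math.log10((p_f0 + p_2f0) / np.mean(noise))


class TestSnr:
    def test_power_ratio_identities(self):
        assert snr_from_powers(0.6, 0.4, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert snr_from_powers(8.0, 2.0, 1.0) == pytest.approx(10.0, abs=1e-12)
        with pytest.raises(ValueError):
            snr_from_powers(1.0, 1.0, 0.0)

    def test_matches_independent_periodogram_oracle(self):
        fs, n = 250.0, 1250
        rng = np.random.default_rng(17)
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 11.25 * t) + 0.8 * rng.standard_normal(n)
        rep = snr_db(x[None, None], fs, 11.25)
        assert rep.snr_per_channel[0, 0] == pytest.approx(
            _snr_oracle(x, fs, 11.25), abs=1e-6
        )

    def test_report_internal_consistency(self):
        fs, n = 250.0, 1250
        rng = np.random.default_rng(5)
        data = rng.standard_normal((3, 9, n))
        rep = snr_db(data, fs, 18.0)
        recomputed = 10 * np.log10((rep.p_f0 + rep.p_2f0) / rep.p_noise)
        assert np.allclose(rep.snr_per_channel, recomputed, atol=1e-9)
        assert (rep.p_noise > 0).all()

    def test_scale_invariance(self):
        fs, n = 250.0, 1250
        rng = np.random.default_rng(6)
        x = rng.standard_normal((2, 4, n))
        a = snr_db(x, fs, 7.5).snr_per_channel
        b = snr_db(137.5 * x, fs, 7.5).snr_per_channel
        assert np.allclose(a, b, atol=1e-9)

    def test_harmonic_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            snr_db(np.zeros((1, 1, 1250)), 250.0, 70.0)

    def test_empty_noise_band_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            snr_db(np.ones((1, 1, 1250)), 250.0, 11.25,
                   noise_halfwidth=0.05, exclusion_halfwidth=0.1)


class TestAmplitudeSpectrum:
    def test_zero_signal(self):
        freqs, amp = amplitude_spectrum(np.zeros((2, 3, 1000)), 250.0)
        assert np.allclose(amp, 0.0)

    def test_unit_sinusoid_peaks_at_one(self):
        fs, n = 250.0, 1000  # 0.25 Hz bins: 11.25 is bin-aligned
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 11.25 * t)
        freqs, amp = amplitude_spectrum(x[None, None], fs)
        i = np.argmax(amp)
        assert freqs[i] == pytest.approx(11.25)
        assert amp[i] == pytest.approx(1.0, abs=1e-9)

    def test_fundamental_above_harmonic(self):
        fs, n = 250.0, 1000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 7.5 * t) + 0.5 * np.sin(2 * np.pi * 15.0 * t)
        freqs, amp = amplitude_spectrum(x[None, None], fs)
        a_f0 = amp[np.argmin(abs(freqs - 7.5))]
        a_2f0 = amp[np.argmin(abs(freqs - 15.0))]
        assert a_f0 > a_2f0 > np.median(amp)


class TestCvSplits:
    def _strata(self):
        return [(d, f) for d in (0.4, 1.0, 1.8) for f in (7.5, 11.25, 18.0)
                for _ in range(10)]

    def test_canonical_63_27_split(self):
        splits = make_cv_splits(self._strata(), CvScheme(seed=4))
        assert len(splits) == 10
        for train, test in splits:
            assert len(train) == 63 and len(test) == 27
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.union1d(train, test)) == 90

    def test_each_stratum_contributes_7_train_3_test(self):
        strata = self._strata()
        for train, test in make_cv_splits(strata, CvScheme(seed=1)):
            for s in set(strata):
                idx = [i for i, lab in enumerate(strata) if lab == s]
                assert sum(i in set(train) for i in idx) == 7
                assert sum(i in set(test) for i in idx) == 3

    def test_small_stratum_rejected(self):
        strata = ["a"] * 9 + ["b"]
        with pytest.raises(ValueError, match="stratum"):
            make_cv_splits(strata, CvScheme())

    def test_seed_reproducibility(self):
        s1 = make_cv_splits(self._strata(), CvScheme(seed=7))
        s2 = make_cv_splits(self._strata(), CvScheme(seed=7))
        for (a1, b1), (a2, b2) in zip(s1, s2):
            assert np.array_equal(a1, a2) and np.array_equal(b1, b2)


class TestAccuracy:
    def _table(self, n_correct, n_total):
        true = [7.5] * n_total
        pred = [7.5] * n_correct + [18.0] * (n_total - n_correct)
        return pd.DataFrame({"true_frequency": true, "predicted_frequency": pred,
                             "method": "cca", "environment": "MR", "depth": 0.4})

    def test_percent_arithmetic(self):
        assert accuracy(self._table(27, 27))["accuracy_pct"].iloc[0] == 100.0
        assert accuracy(self._table(9, 27))["accuracy_pct"].iloc[0] == pytest.approx(
            100 / 3, abs=0.05
        )

    def test_matches_hand_count(self):
        df = pd.DataFrame(
            {
                "true_frequency": [7.5, 7.5, 11.25, 11.25, 18.0, 18.0],
                "predicted_frequency": [7.5, 18.0, 11.25, 11.25, 18.0, 7.5],
                "method": ["cca"] * 6,
                "environment": ["MR"] * 3 + ["VR"] * 3,
                "depth": [0.4] * 6,
            }
        )
        out = accuracy(df).set_index("environment")
        assert out.loc["MR", "n_correct"] == 2 and out.loc["MR", "n_total"] == 3
        assert out.loc["VR", "accuracy_pct"] == pytest.approx(200 / 3, abs=0.01)

    def test_empty_cells_absent_not_zero(self):
        out = accuracy(self._table(3, 3))
        assert set(out["depth"]) == {0.4}


class TestWilcoxon:
    def test_reported_double_vision_statistics(self):
        """5 raters VR > MR (one larger step), 5 tied -> Z = -2.121, p = 0.034."""
        mr = [2, 2, 2, 2, 2, 1, 1, 1, 1, 3]
        vr = [2, 2, 2, 2, 2, 2, 2, 2, 2, 5]
        res = wilcoxon_signed_rank(mr, vr)
        assert round(res.z, 3) == -2.121
        assert round(res.p, 3) == 0.034
        assert res.n_positive == 5 and res.n_negative == 0 and res.n_ties == 5

    def test_identical_vectors_null(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.z == 0.0 and res.p == 1.0 and res.all_zero

    def test_five_equal_positive_differences(self):
        # T- = 0, mu = 7.5, var = 13.75 - (125 - 5)/48 = 11.25
        res = wilcoxon_signed_rank([0] * 5, [1] * 5)
        assert res.z == pytest.approx(-7.5 / math.sqrt(11.25), abs=1e-9)
        assert res.z == pytest.approx(-2.236, abs=5e-4)

    def test_sign_convention(self):
        # scores_b below scores_a -> positive Z
        res = wilcoxon_signed_rank([3, 4, 5, 6, 7], [1, 2, 3, 4, 5])
        assert res.z > 0

    def test_agrees_with_scipy_approx(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = rng.integers(1, 6, size=12).astype(float)
            b = a + rng.integers(-2, 3, size=12)
            if np.all(a == b):
                continue
            mine = wilcoxon_signed_rank(a, b)
            ref = st.wilcoxon(a, b, correction=False, method="approx",
                              zero_method="wilcox")
            assert abs(mine.z) == pytest.approx(abs(ref.zstatistic), abs=1e-9)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_p_ordering_matches_exact_permutation(self):
        """Normal-approximation p preserves the exact-test ranking (n <= 10)."""
        rng = np.random.default_rng(23)
        approx_ps, exact_ps = [], []
        while len(approx_ps) < 6:
            a = rng.integers(1, 6, size=9).astype(float)
            b = a + rng.integers(-2, 3, size=9)
            d = b - a
            if np.count_nonzero(d) < 4:
                continue
            approx_ps.append(wilcoxon_signed_rank(a, b).p)
            exact_ps.append(
                st.wilcoxon(d[d != 0], method="exact").pvalue
            )
        assert (
            np.argsort(np.argsort(approx_ps)).tolist()
            == np.argsort(np.argsort(exact_ps)).tolist()
        )


class TestBonferroniAndFits:
    def test_bonferroni_levels(self):
        assert bonferroni_alpha(0.05, 10) == 0.005
        assert bonferroni_alpha(0.05, 1) == 0.05
        assert bonferroni_alpha(0.05, 20) == 0.0025
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)

    def test_exact_lines(self):
        x = np.arange(10.0)
        out = linear_fit(x, 2 * x)
        assert (out.slope, out.intercept, out.r) == (2.0, 0.0, 1.0)
        out = linear_fit(x, -x + 5)
        assert out.slope == pytest.approx(-1.0) and out.r == pytest.approx(-1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(31)
        x = rng.standard_normal(50)
        y = 1.7 * x - 0.4 + 0.3 * rng.standard_normal(50)
        out = linear_fit(x, y)
        A = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        assert out.slope == pytest.approx(slope, abs=1e-10)
        assert out.intercept == pytest.approx(intercept, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        out = linear_fit([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])
        assert out.constant_y and out.r == 0.0
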