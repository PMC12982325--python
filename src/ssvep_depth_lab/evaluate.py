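"""Quantitative evaluation: SNR, spectra, accuracy, and statistics.

The SSVEP signal-to-noise ratio of a trial is defined in decibels as

    SNR = 10 log10( (P_f0 + P_2f0) / P_noise )

where ``P_f0`` and ``P_2f0`` are periodogram powers at the target
frequency and its second harmonic and ``P_noise`` is the mean power over
adjacent bins (within +-1 Hz of each peak, excluding +-0.1 Hz around the
peaks).  Classification accuracy is ``N_correct / N_total x 100%`` under
repeated stratified 70/30 train/test splits.  Questionnaire contrasts use
the tie-corrected Wilcoxon signed-rank normal approximation with
Bonferroni-corrected significance levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = [
    "SnrReport",
    "CvScheme",
    "StatTestResult",
    "LinearFitResult",
    "snr_db",
    "amplitude_spectrum",
    "make_cv_splits",
    "accuracy",
    "wilcoxon_signed_rank",
    "bonferroni_alpha",
    "linear_fit",
]

#: PSD bin spacing (Hz) used for SNR peak/noise estimation.  0.05 Hz
#: divides every fundamental (7.5, 11.25, 18) and second harmonic
#: exactly, so peaks land on bins.
SNR_RESOLUTION = 0.05


@dataclass
class SnrReport:
    """Per-trial SNR decomposition.

    ``snr_per_channel`` (trials x channels) satisfies the defining ratio
    against the per-channel power components; ``snr_per_trial`` is the
    channel-averaged dB value used for condition summaries.
    """

    snr_per_channel: np.ndarray
    p_f0: np.ndarray
    p_2f0: np.ndarray
    p_noise: np.ndarray
    psd_resolution: float
    f0: float

    @property
    def snr_per_trial(self) -> np.ndarray:
        return self.snr_per_channel.mean(axis=1)

    def mean(self) -> float:
        return float(self.snr_per_trial.mean())


def snr_from_powers(p_f0: float, p_2f0: float, p_noise: float) -> float:
    """The defining dB ratio for pre-computed power components."""
    if p_noise <= 0:
        raise ValueError("noise power must be positive")
    return 10.0 * math.log10((p_f0 + p_2f0) / p_noise)


def _psd(data: np.ndarray, fs: float, resolution: float) -> tuple[np.ndarray, np.ndarray]:
    """Rectangular-window periodogram on a zero-padded ``resolution`` grid."""
    n = data.shape[-1]
    nfft = int(round(fs / resolution))
    if nfft < n:
        raise ValueError("requested resolution coarser than the native grid")
    x = data - data.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(x, n=nfft, axis=-1)
    psd = (np.abs(spec) ** 2) / (fs * n)
    psd[..., 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, psd


def snr_db(
    epochs_stim: np.ndarray,
    sample_rate: float,
    f0: float,
    noise_halfwidth: float = 1.0,
    exclusion_halfwidth: float = 0.1,
    resolution: float = SNR_RESOLUTION,
) -> SnrReport:
    """SSVEP SNR of stimulus-window trials at target frequency ``f0``.

    ``epochs_stim`` is trials x channels x samples (a single trial may be
    passed as channels x samples).  Powers are read from the exact
    periodogram bins at ``f0`` and ``2 f0``; the noise floor is the mean
    over bins within ``noise_halfwidth`` Hz of either peak, excluding
    bins within ``exclusion_halfwidth`` Hz of the peaks.  SNR is computed
    per channel and summarized by averaging the dB values over channels.
    """
    data = np.asarray(epochs_stim, dtype=float)
    if data.ndim == 1:
        data = data[None]
    if data.ndim == 2:
        data = data[None]
    nyq = sample_rate / 2.0
    if 2 * f0 >= nyq:
        raise ValueError(f"second harmonic {2 * f0} Hz at or above Nyquist {nyq}")
    freqs, psd = _psd(data, sample_rate, resolution)

    def _bin(f: float) -> int:
        i = int(round(f / resolution))
        if abs(freqs[i] - f) > 1e-6:
            raise ValueError(f"frequency {f} Hz not on the {resolution} Hz grid")
        return i

    i0, i1 = _bin(f0), _bin(2 * f0)
    near_peak = (np.abs(freqs - f0) <= exclusion_halfwidth + 1e-9) | (
        np.abs(freqs - 2 * f0) <= exclusion_halfwidth + 1e-9
    )
    in_band = (np.abs(freqs - f0) <= noise_halfwidth + 1e-9) | (
        np.abs(freqs - 2 * f0) <= noise_halfwidth + 1e-9
    )
    noise_bins = in_band & ~near_peak & (freqs > 0)
    if not noise_bins.any():
        raise ValueError("noise neighborhood is empty; widen noise_halfwidth")
    p_f0 = psd[..., i0]
    p_2f0 = psd[..., i1]
    p_noise = psd[..., noise_bins].mean(axis=-1)
    snr = 10.0 * np.log10((p_f0 + p_2f0) / p_noise)
    return SnrReport(
        snr_per_channel=snr,
        p_f0=p_f0,
        p_2f0=p_2f0,
        p_noise=p_noise,
        psd_resolution=resolution,
        f0=f0,
    )


def amplitude_spectrum(
    epochs_stim: np.ndarray,
    sample_rate: float,
    f_resolution: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged single-sided amplitude spectrum of equal-length trials.

    Returns ``(freqs, amplitude)`` where amplitude is 2|X(f)|/N (so a
    bin-aligned unit sinusoid peaks at 1), averaged across trials and
    channels.  ``f_resolution`` finer than the native grid zero-pads.
    """
    data = np.asarray(epochs_stim, dtype=float)
    if data.ndim == 2:
        data = data[None]
    n = data.shape[-1]
    nfft = n if f_resolution is None else int(round(sample_rate / f_resolution))
    if nfft < n:
        raise ValueError("f_resolution coarser than the native grid")
    x = data - data.mean(axis=-1, keepdims=True)
    amp = 2.0 * np.abs(np.fft.rfft(x, n=nfft, axis=-1)) / n
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sample_rate)
    return freqs, amp.mean(axis=(0, 1))


@dataclass(frozen=True)
class CvScheme:
    """Repeated stratified train/test splitting.

    10 seeded repetitions of random 70/30 splits, stratified over the
    (depth x frequency) cells, reproducing 63 train / 27 test trials on
    the canonical 90-trial session.
    """

    n_repetitions: int = 10
    train_fraction: float = 0.7
    seed: int = 0


def make_cv_splits(
    strata: list, scheme: CvScheme = CvScheme()
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified train/test index splits.

    ``strata`` holds one hashable stratum key per trial (e.g. the
    (depth, frequency) tuple).  Each repetition draws, per stratum, a
    random ``train_fraction`` subset (rounded) for training and the rest
    for testing.
    """
    strata = list(strata)
    if len(strata) < 10:
        raise ValueError("need at least 10 trials")
    rng = np.random.default_rng(scheme.seed)
    by_stratum: dict = {}
    for i, s in enumerate(strata):
        by_stratum.setdefault(s, []).append(i)
    for s, idx in by_stratum.items():
        if len(idx) < 2:
            raise ValueError(f"stratum {s!r} has fewer than 2 trials")
    splits = []
    for _ in range(scheme.n_repetitions):
        train, test = [], []
        for idx in by_stratum.values():
            perm = rng.permutation(idx)
            n_train = int(round(scheme.train_fraction * len(idx)))
            train.extend(perm[:n_train])
            test.extend(perm[n_train:])
        splits.append((np.sort(np.array(train)), np.sort(np.array(test))))
    return splits


def accuracy(
    decisions: pd.DataFrame,
    by: tuple[str, ...] = ("method", "environment", "depth"),
) -> pd.DataFrame:
    """Per-cell percent-correct from a decision table.

    ``decisions`` needs ``true_frequency`` and ``predicted_frequency``
    columns plus the grouping columns in ``by`` (and optionally
    ``repetition`` for a mean +- sd across repetitions).  Empty cells are
    simply absent (undefined), never reported as 0%.
    """
    required = {"true_frequency", "predicted_frequency"}
    if not required <= set(decisions.columns):
        raise ValueError(f"decision table needs columns {sorted(required)}")
    df = decisions.copy()
    df["correct"] = df["true_frequency"] == df["predicted_frequency"]
    by = tuple(c for c in by if c in df.columns)
    rows = []
    for key, cell in df.groupby(list(by)) if by else [((), df)]:
        key = key if isinstance(key, tuple) else (key,)
        n_total = len(cell)
        n_correct = int(cell["correct"].sum())
        rec = dict(zip(by, key))
        rec.update(
            n_correct=n_correct,
            n_total=n_total,
            accuracy_pct=100.0 * n_correct / n_total,
        )
        if "repetition" in cell.columns and cell["repetition"].nunique() > 1:
            per_rep = cell.groupby("repetition")["correct"].mean() * 100.0
            rec["accuracy_sd"] = float(per_rep.std(ddof=1))
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class StatTestResult:
    """Wilcoxon signed-rank contrast between paired condition scores."""

    label: str
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    n_negative: int
    n_positive: int
    n_ties: int
    z: float
    p: float
    significance_level: float = 0.05
    all_zero: bool = False

    @property
    def significant(self) -> bool:
        return self.p < self.significance_level


def wilcoxon_signed_rank(
    scores_a,
    scores_b,
    label: str = "",
    significance_level: float = 0.05,
) -> StatTestResult:
    """Paired Wilcoxon signed-rank test, SPSS-style normal approximation.

    Zero differences are dropped; tied absolute differences share
    mid-ranks; the variance carries the tie correction and no continuity
    correction is applied.  Z is computed from the negative-rank sum
    ``T- = sum of ranks where b < a``, so scores_b systematically above
    scores_a (e.g. VR above MR) yields a negative Z.  The p-value is
    two-sided.  If every difference is zero, ``Z = 0, p = 1`` with the
    ``all_zero`` flag set.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = b - a
    n_ties = int((d == 0).sum())
    nz = d[d != 0]
    q_a = np.percentile(a, [25, 75])
    q_b = np.percentile(b, [25, 75])
    base = dict(
        label=label,
        median_a=float(np.median(a)),
        iqr_a=(float(q_a[0]), float(q_a[1])),
        median_b=float(np.median(b)),
        iqr_b=(float(q_b[0]), float(q_b[1])),
        n_ties=n_ties,
        significance_level=significance_level,
    )
    if nz.size == 0:
        return StatTestResult(
            n_negative=0, n_positive=0, z=0.0, p=1.0, all_zero=True, **base
        )
    ranks = st.rankdata(np.abs(nz))
    t_neg = float(ranks[nz < 0].sum())
    n = nz.size
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(nz), return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    z = (t_neg - mu) / math.sqrt(var) if var > 0 else 0.0
    p = 2.0 * st.norm.sf(abs(z))
    return StatTestResult(
        n_negative=int((nz < 0).sum()),
        n_positive=int((nz > 0).sum()),
        z=float(z),
        p=float(min(p, 1.0)),
        **base,
    )


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison significance level ``family_alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    return family_alpha / m


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    r: float
    n: int
    constant_y: bool = False


def linear_fit(x, y) -> LinearFitResult:
    """Least-squares line and Pearson r (e.g. decoder feature vs SNR)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need paired x, y with n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0])
        return LinearFitResult(slope, intercept, 0.0, x.size, constant_y=True)
    res = st.linregress(x, y)
    return LinearFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=int(x.size),
    )
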