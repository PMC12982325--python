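"""SSVEP frequency decoding: CCA, filter-bank CCA and TRCA.

Canonical correlation analysis (CCA) matches the multi-channel EEG of one
trial against sine/cosine reference templates at each candidate flicker
frequency and its harmonics; the frequency with the largest canonical
correlation wins.  Filter-bank CCA (FBCCA) first splits the trial into
Butterworth sub-bands, computes CCA per band and fuses the correlations
with a weighted sum of squares, w(n) = n^(-1.25) + 0.25.  Task-related
component analysis (TRCA) learns, per stimulus class, the spatial filter
maximizing inter-trial consistency via the generalized eigenproblem
S_t w = lambda S_n w; projecting epochs onto the leading filter enhances
the stimulus-locked component before SNR estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from .preprocess import EpochSet

__all__ = [
    "ReferenceSet",
    "FilterBankSpec",
    "CcaResult",
    "FbccaResult",
    "TrcaModel",
    "make_references",
    "cca_correlation",
    "cca_classify",
    "fbcca_classify",
    "trca_train",
    "trca_filter",
    "TrcaClassifier",
]


@dataclass(frozen=True)
class ReferenceSet:
    """Sine/cosine reference templates per candidate frequency.

    For frequency ``f`` the template matrix has ``2 * n_harmonics`` rows:
    unit-amplitude sin and cos at ``h * f`` for ``h = 1..n_harmonics``.
    """

    frequencies: tuple[float, ...]
    n_harmonics: int
    sample_rate: float
    n_samples: int
    templates: dict[float, np.ndarray] = field(repr=False, default_factory=dict)

    def __getitem__(self, f: float) -> np.ndarray:
        return self.templates[f]


def make_references(
    frequencies,
    n_harmonics: int = 2,
    sample_rate: float = 250.0,
    n_samples: int = 1250,
) -> ReferenceSet:
    """Build the sinusoid reference bank; every harmonic must sit below Nyquist."""
    frequencies = tuple(float(f) for f in frequencies)
    nyq = sample_rate / 2.0
    for f in frequencies:
        top = n_harmonics * f
        if top >= nyq:
            raise ValueError(
                f"harmonic {n_harmonics} of {f} Hz is {top} Hz, at or above "
                f"Nyquist {nyq} Hz"
            )
    t = np.arange(n_samples) / sample_rate
    templates = {}
    for f in frequencies:
        rows = []
        for h in range(1, n_harmonics + 1):
            rows.append(np.sin(2 * np.pi * h * f * t))
            rows.append(np.cos(2 * np.pi * h * f * t))
        templates[f] = np.array(rows)
    return ReferenceSet(
        frequencies=frequencies,
        n_harmonics=n_harmonics,
        sample_rate=sample_rate,
        n_samples=n_samples,
        templates=templates,
    )


@dataclass(frozen=True)
class FilterBankSpec:
    """Sub-band decomposition and fusion weights for FBCCA."""

    bands: tuple[tuple[float, float], ...] = (
        (0.1, 10.0),
        (10.0, 20.0),
        (20.0, 30.0),
        (30.0, 40.0),
    )
    order: int = 4

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def weights(self) -> np.ndarray:
        """w(n) = n^(-1.25) + 0.25 — strictly positive and decreasing."""
        n = np.arange(1, self.n_bands + 1, dtype=float)
        return n ** (-1.25) + 0.25


@dataclass
class CcaResult:
    correlations: dict[float, float]
    weights_x: dict[float, np.ndarray]
    weights_y: dict[float, np.ndarray]
    predicted_frequency: float


@dataclass
class FbccaResult:
    subband_correlations: dict[float, np.ndarray]
    features: dict[float, float]
    predicted_frequency: float


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=-1, keepdims=True)


def cca_correlation(
    X: np.ndarray, Y: np.ndarray, ridge: float = 1e-9
) -> tuple[float, np.ndarray, np.ndarray]:
    """Largest canonical correlation between two row-variable signals.

    Solves the whitened cross-covariance SVD: with auto-covariances
    ``Cxx``, ``Cyy`` and cross-covariance ``Cxy`` of the centered rows,
    the leading singular value of ``Cxx^-1/2 Cxy Cyy^-1/2`` is the
    maximal correlation over linear row combinations; a small ridge on
    the auto-covariances guards rank deficiency (with a warning).

    Returns ``(rho, w_x, w_y)`` with ``rho`` clipped to [0, 1].
    """
    X = _center(np.atleast_2d(np.asarray(X, dtype=float)))
    Y = _center(np.atleast_2d(np.asarray(Y, dtype=float)))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have the same number of samples")
    n = X.shape[1]
    if n < X.shape[0] + Y.shape[0]:
        raise ValueError("need at least channels + references samples")
    Cxx = X @ X.T / n
    Cyy = Y @ Y.T / n
    Cxy = X @ Y.T / n

    def _inv_sqrt(C: np.ndarray, name: str) -> np.ndarray:
        w, V = np.linalg.eigh(C)
        if w.min() <= w.max() * 1e-10:
            warnings.warn(
                f"{name} is rank-deficient; applying ridge regularization",
                stacklevel=3,
            )
        w = np.maximum(w, 0.0) + ridge * max(1.0, w.max())
        return V @ np.diag(w ** -0.5) @ V.T

    Kx = _inv_sqrt(Cxx, "Cxx")
    Ky = _inv_sqrt(Cyy, "Cyy")
    U, s, Vt = np.linalg.svd(Kx @ Cxy @ Ky)
    rho = float(min(max(s[0], 0.0), 1.0))
    w_x = Kx @ U[:, 0]
    w_y = Ky @ Vt[0]
    return rho, w_x, w_y


def _argmax_lowest(freqs, scores) -> float:
    """Argmax over candidate frequencies; exact ties go to the lowest."""
    scores = np.asarray([scores[f] for f in freqs])
    best = scores.max()
    return min(f for f, s in zip(freqs, scores) if s == best)


def cca_classify(epoch: np.ndarray, refs: ReferenceSet) -> CcaResult:
    """Standard (training-free) CCA frequency decision for one trial.

    ``epoch`` is channels x samples over the stimulus window, at the same
    rate and length as the reference templates.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[1] != refs.n_samples:
        raise ValueError(
            f"epoch has {epoch.shape[1]} samples but references expect "
            f"{refs.n_samples}"
        )
    correlations, wxs, wys = {}, {}, {}
    for f in refs.frequencies:
        rho, wx, wy = cca_correlation(epoch, refs[f])
        correlations[f], wxs[f], wys[f] = rho, wx, wy
    pred = _argmax_lowest(refs.frequencies, correlations)
    return CcaResult(
        correlations=correlations,
        weights_x=wxs,
        weights_y=wys,
        predicted_frequency=pred,
    )


def fbcca_classify(
    epoch: np.ndarray, refs: ReferenceSet, bank: FilterBankSpec | None = None
) -> FbccaResult:
    """Filter-bank CCA decision: per-sub-band CCA fused by sum w(n) rho_n^2."""
    if bank is None:
        bank = FilterBankSpec()
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[1] != refs.n_samples:
        raise ValueError("epoch/reference length mismatch")
    nyq = refs.sample_rate / 2.0
    weights = bank.weights
    subbands = []
    for low, high in bank.bands:
        if not 0 < low < high < nyq:
            raise ValueError(f"band ({low}, {high}) invalid for Nyquist {nyq}")
        sos = sps.butter(
            bank.order, [low, high], btype="bandpass", fs=refs.sample_rate,
            output="sos",
        )
        subbands.append(sps.sosfiltfilt(sos, epoch, axis=-1))
    sub_corr: dict[float, np.ndarray] = {}
    features: dict[float, float] = {}
    for f in refs.frequencies:
        rhos = np.array(
            [cca_correlation(xb, refs[f])[0] for xb in subbands]
        )
        sub_corr[f] = rhos
        features[f] = float(np.sum(weights * rhos**2))
    pred = _argmax_lowest(refs.frequencies, features)
    return FbccaResult(
        subband_correlations=sub_corr, features=features, predicted_frequency=pred
    )


@dataclass
class TrcaModel:
    """Per-class TRCA spatial filters, eigenvalue-sorted.

    ``filters`` columns w_i satisfy S_t w = lambda S_n w and are
    normalized so w^T S_n w = 1; ``eigenvalues`` are descending.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    s_t: np.ndarray
    s_n: np.ndarray
    channel_names: tuple[str, ...] | None = None


def trca_train(
    class_trials: np.ndarray,
    normalization: str = "covariance",
    ridge: float = 1e-9,
) -> TrcaModel:
    """Fit TRCA spatial filters from K >= 2 same-class trials (K x C x T).

    The inter-trial matrix is ``S_t = sum_{j != k} X_j X_k^T`` of the
    per-trial-centered signals (computed as the covariance of the summed
    trials minus the within-trial sum, which is algebraically identical);
    the normalization matrix ``S_n`` is the total covariance
    ``sum_k X_k X_k^T`` (``normalization='covariance'``) or the identity.
    """
    trials = np.asarray(class_trials, dtype=float)
    if trials.ndim != 3:
        raise ValueError("class_trials must be K x channels x samples")
    K, C, T = trials.shape
    if K < 2:
        raise ValueError("TRCA needs at least 2 trials per class")
    if T <= C:
        raise ValueError("need more samples than channels")
    if normalization not in ("covariance", "identity"):
        raise ValueError("normalization must be 'covariance' or 'identity'")
    X = trials - trials.mean(axis=-1, keepdims=True)
    total = X.sum(axis=0)
    s_within = np.einsum("kct,kdt->cd", X, X)
    s_t = total @ total.T - s_within
    s_t = 0.5 * (s_t + s_t.T)
    s_n = s_within if normalization == "covariance" else np.eye(C) * 1.0
    s_n = 0.5 * (s_n + s_n.T)
    scale = np.trace(s_n) / C
    if scale <= 0 or np.linalg.cond(s_n) > 1e10:
        warnings.warn("S_n is near-singular; applying ridge regularization")
        s_n = s_n + ridge * max(scale, 1.0) * np.eye(C)
    try:
        lam, W = sla.eigh(s_t, s_n)
    except np.linalg.LinAlgError:
        warnings.warn("generalized eigensolve failed; retrying with ridge")
        s_n = s_n + ridge * max(scale, 1.0) * np.eye(C)
        lam, W = sla.eigh(s_t, s_n)
    order = np.argsort(lam)[::-1]
    lam, W = lam[order], W[:, order]
    # eigh(b=s_n) already yields W^T S_n W = I; re-normalize defensively
    norms = np.sqrt(np.einsum("ci,cd,di->i", W, s_n, W))
    W = W / norms
    return TrcaModel(filters=W, eigenvalues=lam, s_t=s_t, s_n=s_n)


def trca_filter(
    epochs: EpochSet, model: TrcaModel, n_components: int = 1
) -> EpochSet:
    """Project epochs onto the leading TRCA components.

    Used upstream of SNR estimation: the projection enhances the
    stimulus-locked component shared across trials and suppresses noise.
    """
    if n_components > model.filters.shape[1]:
        raise ValueError(
            f"requested {n_components} components but model holds "
            f"{model.filters.shape[1]} filters"
        )
    if epochs.data.shape[1] != model.filters.shape[0]:
        raise ValueError("model channel count does not match epochs")
    W = model.filters[:, :n_components]
    data = np.einsum("ck,tcs->tks", W, epochs.data)
    names = tuple(f"trca{i + 1}" for i in range(n_components))
    return EpochSet(
        data=data,
        sample_rate=epochs.sample_rate,
        window=epochs.window,
        labels=list(epochs.labels),
        channel_names=names,
        kept_mask=epochs.kept_mask.copy(),
    )


class TrcaClassifier:
    """Template-matching classifier on TRCA-filtered signals.

    Goes beyond the SNR-enhancement role of TRCA: per class, the top
    spatial filter and the filtered mean training template are stored;
    a test trial is assigned to the class whose filtered template it
    correlates with most strongly (ties to the lowest frequency).
    """

    def __init__(self, normalization: str = "covariance") -> None:
        self.normalization = normalization
        self.models: dict[float, TrcaModel] = {}
        self.templates: dict[float, np.ndarray] = {}

    def fit(self, epochs_stim: np.ndarray, frequencies: np.ndarray) -> "TrcaClassifier":
        """Train from stimulus-window trials (N x C x T) and their labels."""
        frequencies = np.asarray(frequencies, dtype=float)
        for f in np.unique(frequencies):
            trials = epochs_stim[frequencies == f]
            model = trca_train(trials, normalization=self.normalization)
            w = model.filters[:, 0]
            self.models[float(f)] = model
            mean_trial = trials.mean(axis=0)
            self.templates[float(f)] = w @ _center(mean_trial)
        return self

    def predict_one(self, epoch: np.ndarray) -> float:
        scores = {}
        for f, model in self.models.items():
            w = model.filters[:, 0]
            x = w @ _center(np.asarray(epoch, dtype=float))
            y = self.templates[f]
            denom = np.linalg.norm(x) * np.linalg.norm(y)
            scores[f] = float(x @ y / denom) if denom > 0 else 0.0
        return _argmax_lowest(sorted(scores), scores)

    def predict(self, epochs_stim: np.ndarray) -> np.ndarray:
        return np.array([self.predict_one(e) for e in epochs_stim])
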