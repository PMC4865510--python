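"""Filtering, detrending, and infomax-ICA ocular artifact removal.

All filters are zero-phase (forward-backward) Butterworth filters applied
as second-order sections; zero phase matters because downstream features
depend on event timing (R-peaks, blinks).

The ICA is the logistic-infomax algorithm of Bell & Sejnowski with the
natural-gradient update

    W <- W + lr * (I + (1 - 2*g(U)) U^T / T) W,   U = W X,  g = logistic,

run on whitened data with an annealed learning rate.  Ocular components
are identified by correlation with the EOG reference channels and zeroed
before reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class FilterSpec:
    """A band-pass or high-pass Butterworth specification."""

    kind: str  # "bandpass" | "highpass"
    lo_hz: float
    hi_hz: float | None = None
    order: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "highpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 2:
            raise ValueError("filter order must be >= 2")
        if self.kind == "bandpass":
            if self.hi_hz is None or not (0 < self.lo_hz < self.hi_hz):
                raise ValueError("bandpass needs 0 < lo_hz < hi_hz")
        elif self.lo_hz <= 0:
            raise ValueError("highpass cutoff must be positive")


#: Filters used throughout the pipeline.
EEG_BANDPASS = FilterSpec("bandpass", 1.0, 50.0)
ECG_BANDPASS = FilterSpec("bandpass", 0.1, 30.0)
EOG_BANDPASS = FilterSpec("bandpass", 0.1, 10.0)
FNIRS_HIGHPASS = FilterSpec("highpass", 0.01)


def apply_filter(trace: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase filter along the last axis; length preserved."""
    trace = np.asarray(trace, dtype=float)
    nyq = fs / 2.0
    if spec.kind == "bandpass":
        if not (0 < spec.lo_hz < spec.hi_hz < nyq):
            raise ValueError(f"bandpass {spec.lo_hz}-{spec.hi_hz} Hz invalid for fs={fs}")
        sos = signal.butter(spec.order, [spec.lo_hz, spec.hi_hz], btype="bandpass", fs=fs,
                            output="sos")
    else:
        if not (0 < spec.lo_hz < nyq):
            raise ValueError(f"highpass {spec.lo_hz} Hz invalid for fs={fs}")
        sos = signal.butter(spec.order, spec.lo_hz, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, trace, axis=-1)


def detrend(trace: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend along the last axis."""
    trace = np.asarray(trace, dtype=float)
    if trace.shape[-1] < 2:
        raise ValueError("need at least 2 samples to detrend")
    return signal.detrend(trace, axis=-1, type="linear")


@dataclass
class IcaModel:
    """Fitted infomax ICA: ``sources = unmixing @ X``, ``X = mixing @ sources``."""

    unmixing: np.ndarray
    mixing: np.ndarray
    converged: bool
    n_iter: int

    def sources(self, X: np.ndarray) -> np.ndarray:
        return self.unmixing @ X


def _logistic(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-u))


def fit_infomax_ica(
    X: np.ndarray,
    max_iter: int = 2000,
    tol: float = 1e-5,
    seed: int | None = 0,
    lr: float = 0.1,
    extended: bool = False,
) -> IcaModel:
    """Fit logistic infomax ICA on ``X`` (channels x samples).

    The data are centred and PCA-whitened first; the square unmixing
    matrix returned maps raw (centred) channels to sources.  Full-batch
    natural-gradient steps with a constant learning rate are used (the
    natural gradient is well conditioned, so no schedule is needed);
    convergence is declared when the gradient's largest entry falls below
    ``tol``.  Non-convergence within ``max_iter`` is reported on the
    model rather than raised, since a partially converged unmixing is
    still usable for artifact screening.

    The plain logistic nonlinearity separates super-Gaussian sources
    (blinks, heartbeats); ``extended=True`` switches to the
    kurtosis-sign-adaptive update, which also handles sub-Gaussian
    sources such as strong oscillations.
    """
    X = np.asarray(X, dtype=float)
    n_ch, n_samp = X.shape
    if n_samp < 10 * n_ch:
        raise ValueError("need substantially more samples than channels")
    rng = np.random.default_rng(seed)
    Xc = X - X.mean(axis=1, keepdims=True)

    cov = Xc @ Xc.T / n_samp
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * evals[-1]:
        raise ValueError("data are rank-deficient after centring")
    whiten = (evecs / np.sqrt(evals)) @ evecs.T  # symmetric whitening
    Z = whiten @ Xc

    W = np.eye(n_ch) + 0.01 * rng.standard_normal((n_ch, n_ch))
    eye = np.eye(n_ch)
    converged = False
    n_iter = max_iter
    for it in range(max_iter):
        U = W @ Z
        if extended:
            Un = U / U.std(axis=1, keepdims=True)
            signs = np.sign((Un ** 4).mean(axis=1) - 3.0)
            signs[signs == 0] = 1.0
            grad = (eye - (signs[:, None] * np.tanh(U)) @ U.T / n_samp
                    - U @ U.T / n_samp)
        else:
            grad = eye + (1.0 - 2.0 * _logistic(U)) @ U.T / n_samp
        W_new = W + lr * (grad @ W)
        if not np.all(np.isfinite(W_new)):
            lr *= 0.5  # step too large for this data; restart more carefully
            W = eye + 0.01 * rng.standard_normal((n_ch, n_ch))
            continue
        W = W_new
        if np.abs(grad).max() < tol:
            converged = True
            n_iter = it + 1
            break

    unmixing = W @ whiten
    mixing = np.linalg.pinv(unmixing)
    return IcaModel(unmixing=unmixing, mixing=mixing, converged=converged, n_iter=n_iter)


def component_eog_correlation(ica: IcaModel, X: np.ndarray, eog: np.ndarray) -> np.ndarray:
    """Max absolute Pearson correlation of each IC with any EOG channel."""
    S = ica.sources(np.asarray(X, dtype=float) - np.asarray(X, dtype=float).mean(axis=1, keepdims=True))
    eog = np.atleast_2d(np.asarray(eog, dtype=float))
    r = np.zeros(S.shape[0])
    for k in range(S.shape[0]):
        s = S[k] - S[k].mean()
        sn = np.linalg.norm(s)
        if sn == 0:
            continue
        best = 0.0
        for e in eog:
            ec = e - e.mean()
            en = np.linalg.norm(ec)
            if en == 0:
                continue
            best = max(best, abs(float(s @ ec) / (sn * en)))
        r[k] = best
    return r


def remove_eog_components(
    X: np.ndarray,
    ica: IcaModel,
    eog: np.ndarray,
    r_threshold: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero ICs correlated with the EOG reference and reconstruct.

    Returns the cleaned data (same shape as ``X``) and the indices of the
    removed components.  Raises if the threshold would remove every
    component, which signals a degenerate decomposition or threshold.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    r = component_eog_correlation(ica, X, eog)
    bad = np.flatnonzero(r > r_threshold)
    if bad.size == r.size:
        raise ValueError("every component exceeds the EOG correlation threshold")
    S = ica.sources(X - mean)
    S[bad] = 0.0
    return ica.mixing @ S + mean, bad
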