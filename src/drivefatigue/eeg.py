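"""Trial segmentation, spectral estimation, and relative power levels.

A session is cut into consecutive 10-s trials (a 30-min drive yields 180).
For each trial and channel a Welch power spectral density is integrated
over the five canonical bands — delta 1-4, theta 4-8, alpha 8-13,
beta 13-30, gamma 30-50 Hz (half-open intervals, shared edges belong to
the upper band) — and each band power is divided by the summed power of
all five bands, giving the relative power level (RPL).  RPLs are
dimensionless and sum to one per trial, which removes session- and
subject-level gain variability.

The two discriminative scalar features are the spatial mean alpha RPL
over the right centro-parietal region and the mean beta RPL over the
fronto-central region; their ratio beta/alpha feeds the fatigue index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import DEFAULT_ALPHA_REGION, DEFAULT_BETA_REGION, EEG_CHANNELS, region_indices

#: Canonical band edges in Hz, half-open [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}
BAND_NAMES = tuple(BANDS)


@dataclass(frozen=True)
class TrialSet:
    """Equally spaced non-overlapping trial windows from t = 0."""

    trial_len_s: float
    n_trials: int

    @property
    def onsets_s(self) -> np.ndarray:
        return np.arange(self.n_trials) * self.trial_len_s


@dataclass(frozen=True)
class RegionSpec:
    """Channel label sets over which alpha and beta RPLs are averaged."""

    alpha_region: tuple[str, ...] = DEFAULT_ALPHA_REGION
    beta_region: tuple[str, ...] = DEFAULT_BETA_REGION

    def __post_init__(self) -> None:
        for region in (self.alpha_region, self.beta_region):
            if not region:
                raise ValueError("region channel list must be non-empty")
            region_indices(region)  # raises on unknown labels


def segment_trials(duration_s: float, trial_len_s: float = 10.0) -> TrialSet:
    """Maximal non-overlapping 10-s cover of [0, duration); remainder dropped."""
    if duration_s < trial_len_s:
        raise ValueError("session shorter than one trial")
    n = int(np.floor(duration_s / trial_len_s + 1e-9))
    return TrialSet(trial_len_s=trial_len_s, n_trials=n)


def compute_psd(trace: np.ndarray, fs: float, seg_s: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of one trial (time last); Hamming windows, 50% overlap.

    Returns ``(freqs, psd)`` with resolution 1/seg_s Hz (0.5 Hz default).
    """
    trace = np.asarray(trace, dtype=float)
    nperseg = int(round(seg_s * fs))
    if trace.shape[-1] < nperseg:
        raise ValueError("trial shorter than one Welch segment")
    freqs, psd = signal.welch(trace, fs=fs, window="hamming", nperseg=nperseg,
                              noverlap=nperseg // 2, axis=-1)
    return freqs, psd


def band_powers(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    """Integrate a PSD over the five canonical bands (last axis -> 5)."""
    freqs = np.asarray(freqs)
    df = float(freqs[1] - freqs[0])
    out = []
    for lo, hi in BANDS.values():
        sel = (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)
        out.append(psd[..., sel].sum(axis=-1) * df)
    return np.stack(out, axis=-1)


def compute_rpl(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    """Relative power level per band: band power over summed band power."""
    bp = band_powers(freqs, psd)
    total = bp.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero total band power")
    return bp / total


def trial_rpls(eeg: np.ndarray, fs: float, trials: TrialSet) -> np.ndarray:
    """RPL matrix of shape (n_trials, n_channels, 5) for a full session."""
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    n = int(round(trials.trial_len_s * fs))
    out = np.empty((trials.n_trials, eeg.shape[0], len(BANDS)))
    for k in range(trials.n_trials):
        seg = eeg[:, k * n:(k + 1) * n]
        freqs, psd = compute_psd(seg, fs)
        out[k] = compute_rpl(freqs, psd)
    return out


def region_features(
    rpl: np.ndarray,
    regions: RegionSpec = RegionSpec(),
    labels: tuple[str, ...] = EEG_CHANNELS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Region-averaged (alpha_cp, beta_fc, beta_over_alpha) per trial.

    ``rpl`` has shape (n_trials, n_channels, 5) as from :func:`trial_rpls`.
    """
    rpl = np.asarray(rpl, dtype=float)
    ia = region_indices(regions.alpha_region, labels)
    ib = region_indices(regions.beta_region, labels)
    alpha_idx = BAND_NAMES.index("alpha")
    beta_idx = BAND_NAMES.index("beta")
    alpha_cp = rpl[:, ia, alpha_idx].mean(axis=1)
    beta_fc = rpl[:, ib, beta_idx].mean(axis=1)
    if np.any(alpha_cp == 0):
        raise ValueError("zero alpha RPL in region; ratio undefined")
    return alpha_cp, beta_fc, beta_fc / alpha_cp
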