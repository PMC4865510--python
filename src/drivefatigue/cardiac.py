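"""R-peak, heart-rate, RR-interval, and blink-rate features.

ECG traces are band-pass filtered (0.1-30 Hz) and linearly detrended
upstream; R-peaks are then simple threshold crossings — local maxima above
mean + k*sd separated by a refractory period.  Heart rate is the R-peak
count per minute; the per-trial feature is the mean RR interval within
each 10-s trial.  The two chest leads are detected independently and
their per-minute rates averaged to reduce detection error and bias.

Blinks are sharp deflections of the vertical EOG; the blink rate per
minute is computed the same way but is kept out of the fatigue index
because it does not separate the two driving conditions reliably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .eeg import TrialSet


@dataclass(frozen=True)
class PeakTrain:
    """Strictly increasing event times from one detector run."""

    peak_times_s: np.ndarray
    source: str  # "ecg" | "eog"

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times_s, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("peak times must be strictly increasing")
        object.__setattr__(self, "peak_times_s", t)


@dataclass(frozen=True)
class HrSeries:
    """Heart rate per minute (NaN for empty minutes) and its mean."""

    hr_per_min: np.ndarray

    @property
    def mean_hr(self) -> float:
        return float(np.nanmean(self.hr_per_min))


def detect_r_peaks(ecg: np.ndarray, fs: float, k_sd: float = 2.5,
                   refractory_s: float = 0.3) -> PeakTrain:
    """Threshold detector: maxima above mean + k_sd*sd, refractory-spaced.

    The statistics-based threshold makes detection invariant to amplitude
    scaling of the trace.  Raises if nothing crosses the threshold.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.ndim != 1:
        raise ValueError("detect_r_peaks expects a single-channel trace")
    thresh = ecg.mean() + k_sd * ecg.std()
    idx, _ = signal.find_peaks(ecg, height=thresh, distance=max(1, int(round(refractory_s * fs))))
    if idx.size == 0:
        raise ValueError("no R-peaks found above threshold")
    return PeakTrain(peak_times_s=idx / fs, source="ecg")


def event_counts_per_minute(times_s: np.ndarray, duration_s: float) -> np.ndarray:
    """Event count in each half-open minute window [60k, 60(k+1))."""
    n_min = int(np.floor(duration_s / 60.0 + 1e-9))
    if n_min < 1:
        raise ValueError("need at least one full minute")
    edges = np.arange(n_min + 1) * 60.0
    counts, _ = np.histogram(np.asarray(times_s, dtype=float), bins=edges)
    return counts.astype(float)


def heart_rate(peaks: PeakTrain, duration_s: float) -> HrSeries:
    """Beats per minute from a peak train; empty minutes become NaN."""
    counts = event_counts_per_minute(peaks.peak_times_s, duration_s)
    counts[counts == 0] = np.nan
    return HrSeries(hr_per_min=counts)


def mean_heart_rate_two_leads(hr_left: HrSeries, hr_right: HrSeries) -> HrSeries:
    """Average the per-minute rates of the two chest leads."""
    if hr_left.hr_per_min.shape != hr_right.hr_per_min.shape:
        raise ValueError("lead HR series lengths differ")
    stacked = np.vstack([hr_left.hr_per_min, hr_right.hr_per_min])
    return HrSeries(hr_per_min=np.nanmean(stacked, axis=0))


def rr_features(peaks: PeakTrain, trials: TrialSet) -> np.ndarray:
    """Mean RR interval per 10-s trial (NaN where fewer than two peaks)."""
    t = peaks.peak_times_s
    out = np.full(trials.n_trials, np.nan)
    for k, onset in enumerate(trials.onsets_s):
        in_trial = t[(t >= onset) & (t < onset + trials.trial_len_s)]
        if in_trial.size >= 2:
            out[k] = float(np.diff(in_trial).mean())
    return out


def detect_blinks(eog_v: np.ndarray, fs: float, k_sd: float = 3.0,
                  refractory_s: float = 0.2) -> PeakTrain:
    """Blink detector on the (drift-removed) vertical EOG channel."""
    eog_v = np.asarray(eog_v, dtype=float)
    thresh = eog_v.mean() + k_sd * eog_v.std()
    idx, _ = signal.find_peaks(eog_v, height=thresh,
                               distance=max(1, int(round(refractory_s * fs))))
    return PeakTrain(peak_times_s=idx / fs, source="eog")


def blink_rate(eog_v: np.ndarray, fs: float, duration_s: float, k_sd: float = 3.0) -> np.ndarray:
    """Blinks per minute from the vertical EOG channel (zeros allowed)."""
    try:
        peaks = detect_blinks(eog_v, fs, k_sd=k_sd)
    except ValueError:
        return np.zeros(int(np.floor(duration_s / 60.0)))
    return event_counts_per_minute(peaks.peak_times_s, duration_s)
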