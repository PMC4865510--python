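"""Synthetic multimodal driving-session generator with known ground truth.

Emulates a 30-min simulated drive recorded with 64-channel EEG, two EOG
and two ECG electrodes at 512 Hz, plus an 8-channel two-wavelength
(735/850 nm) continuous-wave fNIRS probe on the forehead at 10 Hz.  The
two driving conditions differ in the directions reported for real
drivers:

* sleep-deprived: higher centro-parietal alpha relative power, lower
  fronto-central beta relative power, lower heart rate (~62 vs ~70 bpm),
  and a flat-to-slightly-negative HbO time course;
* well-rested: the opposite, with HbO rising gradually over the session.

Every stream is driven by one seeded generator; per-modality sub-streams
are derived deterministically, so identical parameters give bit-identical
output and ground-truth event lists (R-peak times, blink times, the true
hemodynamic series, per-band EEG amplitudes) are returned alongside the
raw traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import montage
from .eeg import BANDS
from .nirs import DEFAULT_MBLL, MbllParams, forward_intensity
from .preprocess import FilterSpec, apply_filter

#: Resting per-band amplitude scale (uV RMS) before condition gains.
BASE_BAND_AMPLITUDE_UV: dict[str, float] = {
    "delta": 20.0, "theta": 10.0, "alpha": 10.0, "beta": 6.0, "gamma": 3.0,
}

#: Seconds of flat hemodynamics at the head of the session, matching the
#: downstream 30-s baseline-intensity window so recovered concentration
#: changes are referenced exactly to zero.
HBO_BASELINE_HOLD_S = 30.0


@dataclass(frozen=True)
class SessionParams:
    """Everything that determines one synthetic driving session."""

    condition: str  # "well_rested" | "sleep_deprived"
    duration_s: float = 1800.0
    eeg_fs: float = 512.0
    fnirs_fs: float = 10.0
    hr_bpm: float = 70.0
    hr_slope_bpm_per_min: float = 0.0
    hr_jitter_s: float = 0.01
    alpha_gain_cp: float = 1.0
    beta_gain_fc: float = 1.0
    hbo_trend_mM_per_min: float = 0.0
    blink_rate_per_min: float = 12.0
    eeg_noise_uv: float = 2.0
    ecg_noise_rel: float = 0.05
    ecg_wander_mv: float = 0.1
    eog_noise_uv: float = 5.0
    eog_drift_uv: float = 50.0
    fnirs_noise_rel: float = 0.002
    fnirs_drift_amp: float = 0.02
    hbo_sin_amp_mM: float = 0.02
    hbo_noise_mM: float = 0.01
    eog_leak_uv: float = 20.0
    #: optional override of the resting per-band RMS amplitudes (uV);
    #: bands set to 0 are silenced (spectrum-controlled test sessions)
    band_amplitude_uv: tuple[float, float, float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("well_rested", "sleep_deprived"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.duration_s <= 60:
            raise ValueError("duration_s must exceed 60 s")
        if self.eeg_fs <= 0 or self.fnirs_fs <= 0:
            raise ValueError("sampling rates must be positive")
        if not (30 <= self.hr_bpm <= 200):
            raise ValueError("hr_bpm must lie in [30, 200]")
        if self.alpha_gain_cp <= 0 or self.beta_gain_fc <= 0:
            raise ValueError("band gains must be positive")
        if self.blink_rate_per_min < 0:
            raise ValueError("blink_rate_per_min must be non-negative")


#: Study-like condition presets: the effect *directions* are the contract;
#: magnitudes are chosen to be physiologically plausible (the published
#: study reports directions and heart rates, not band-gain magnitudes).
PRESETS: dict[str, SessionParams] = {
    "well_rested": SessionParams(
        condition="well_rested", hr_bpm=70.0, hr_slope_bpm_per_min=-0.1,
        alpha_gain_cp=1.0, beta_gain_fc=1.3, hbo_trend_mM_per_min=0.01,
        blink_rate_per_min=10.0),
    "sleep_deprived": SessionParams(
        condition="sleep_deprived", hr_bpm=62.0, hr_slope_bpm_per_min=0.0,
        alpha_gain_cp=1.3, beta_gain_fc=1.0, hbo_trend_mM_per_min=-0.001,
        blink_rate_per_min=14.0),
}


def preset(condition: str, seed: int = 0, **overrides) -> SessionParams:
    """A condition preset with a seed and optional field overrides."""
    return replace(PRESETS[condition], seed=seed, **overrides)


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    r_peak_times_s: np.ndarray
    blink_times_s: np.ndarray
    true_hbo: np.ndarray  # (8, T_f) mM/DPF
    true_hbr: np.ndarray  # (8, T_f) mM/DPF
    true_band_amplitudes: np.ndarray  # (64, 5) uV RMS


@dataclass
class SyntheticSession:
    """Raw multimodal traces plus the ground truth that produced them."""

    params: SessionParams
    eeg_uv: np.ndarray          # (64, T_e)
    eog_uv: np.ndarray          # (2, T_e)  rows: EOGh, EOGv
    ecg_mv: np.ndarray          # (2, T_e)
    fnirs_intensity: np.ndarray  # (8, 2, T_f) a.u., wavelengths (735, 850)
    truth: GroundTruth


def _rng(params: SessionParams, stream: int) -> np.random.Generator:
    # one deterministic sub-stream per modality, independent of the others
    return np.random.default_rng(np.random.SeedSequence((params.seed, stream)))


def _band_gain(params: SessionParams, channel: str, band: str) -> float:
    if band == "alpha" and channel in montage.DEFAULT_ALPHA_REGION:
        return params.alpha_gain_cp
    if band == "beta" and channel in montage.DEFAULT_BETA_REGION:
        return params.beta_gain_fc
    return 1.0


def band_amplitude_table(params: SessionParams) -> np.ndarray:
    """Ground-truth per-channel, per-band RMS amplitude (uV)."""
    base = (params.band_amplitude_uv if params.band_amplitude_uv is not None
            else tuple(BASE_BAND_AMPLITUDE_UV[b] for b in BANDS))
    table = np.empty((len(montage.EEG_CHANNELS), len(BANDS)))
    for i, ch in enumerate(montage.EEG_CHANNELS):
        for j, band in enumerate(BANDS):
            table[i, j] = base[j] * _band_gain(params, ch, band)
    return table


def generate_eeg(params: SessionParams, blink_times_s: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """64-channel EEG: five band-limited noise processes plus white noise.

    Band-limited noise is white noise through a 4th-order Butterworth
    band-pass, re-scaled to the target RMS of the channel/band from
    :func:`band_amplitude_table`.  If ``blink_times_s`` is given, the
    stereotyped blink waveform leaks into the frontal channels with
    amplitude ``eog_leak_uv`` so the ICA cleaning stage has a real ocular
    artifact to remove.  Returns ``(eeg_uv, band_amplitudes)``.
    """
    rng = _rng(params, 0)
    fs = params.eeg_fs
    n = int(round(params.duration_s * fs))
    amp = band_amplitude_table(params)
    eeg = rng.standard_normal((len(montage.EEG_CHANNELS), n)) * params.eeg_noise_uv
    for j, (band, (lo, hi)) in enumerate(BANDS.items()):
        spec = FilterSpec("bandpass", lo, min(hi, fs / 2 * 0.99), order=4)
        noise = apply_filter(rng.standard_normal((len(montage.EEG_CHANNELS), n)), fs, spec)
        noise /= noise.std(axis=1, keepdims=True)
        eeg += noise * amp[:, j:j + 1]
    if blink_times_s is not None and len(blink_times_s) and params.eog_leak_uv > 0:
        wave = _blink_series(blink_times_s, fs, n)
        for ch in montage.FRONTAL_CHANNELS:
            eeg[montage.channel_index(montage.EEG_CHANNELS, ch)] += params.eog_leak_uv * wave
    return eeg, amp


def generate_ecg(params: SessionParams) -> tuple[np.ndarray, np.ndarray]:
    """Two-lead ECG as a QRS template train; returns (trace_mv, r_peak_times).

    Beat-to-beat intervals follow the instantaneous rate
    ``hr_bpm + hr_slope_bpm_per_min * t_min`` with Gaussian timing jitter;
    the QRS template is a Mexican-hat wavelet of ~80 ms support whose
    dominant positive deflection is the R-peak.  Slow baseline wander and
    white noise are added per lead.
    """
    rng = _rng(params, 1)
    fs = params.eeg_fs
    n = int(round(params.duration_s * fs))
    t_end = params.duration_s
    times = []
    t = 30.0 / params.hr_bpm  # first beat half an interval in, so a
    # constant-rate train puts exactly hr_bpm beats in every minute
    while t < t_end:
        times.append(t)
        rate = params.hr_bpm + params.hr_slope_bpm_per_min * (t / 60.0)
        rate = float(np.clip(rate, 30.0, 200.0))
        gap = 60.0 / rate + (params.hr_jitter_s * rng.standard_normal() if params.hr_jitter_s else 0.0)
        t += max(gap, 0.25)
    peak_times = np.asarray(times)

    sigma = 0.015  # s; Mexican hat support ~ +/-40 ms
    half = int(round(0.04 * fs))
    tt = np.arange(-half, half + 1) / fs
    template = (1.0 - (tt / sigma) ** 2) * np.exp(-tt ** 2 / (2 * sigma ** 2))
    train = np.zeros(n)
    idx = np.round(peak_times * fs).astype(int)
    for i in idx:
        lo, hi = i - half, i + half + 1
        s0, s1 = max(lo, 0), min(hi, n)
        train[s0:s1] += template[s0 - lo: s1 - lo]

    t_axis = np.arange(n) / fs
    ecg = np.empty((2, n))
    for lead, gain in enumerate((1.0, 0.8)):
        wander = params.ecg_wander_mv * np.sin(2 * np.pi * 0.2 * t_axis + lead)
        noise = params.ecg_noise_rel * rng.standard_normal(n)
        ecg[lead] = gain * train + wander + noise
    return ecg, peak_times


def generate_blink_times(params: SessionParams) -> np.ndarray:
    """Poisson blink process at ``blink_rate_per_min`` over the session."""
    rng = _rng(params, 2)
    if params.blink_rate_per_min == 0:
        return np.empty(0)
    rate_per_s = params.blink_rate_per_min / 60.0
    # draw enough exponential gaps to cover the session
    n_draw = int(rate_per_s * params.duration_s * 2 + 50)
    gaps = rng.exponential(1.0 / rate_per_s, size=n_draw)
    times = np.cumsum(gaps)
    while times[-1] < params.duration_s:
        extra = rng.exponential(1.0 / rate_per_s, size=n_draw)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    return times[times < params.duration_s]


def _blink_series(blink_times_s: np.ndarray, fs: float, n: int) -> np.ndarray:
    """Unit-amplitude stereotyped blink waveform train (Gaussian bumps)."""
    sigma = 0.05  # s
    half = int(round(4 * sigma * fs))
    tt = np.arange(-half, half + 1) / fs
    bump = np.exp(-tt ** 2 / (2 * sigma ** 2))
    out = np.zeros(n)
    for i in np.round(np.asarray(blink_times_s) * fs).astype(int):
        lo, hi = i - half, i + half + 1
        s0, s1 = max(lo, 0), min(hi, n)
        out[s0:s1] += bump[s0 - lo: s1 - lo]
    return out


def generate_eog(params: SessionParams, blink_times_s: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Two-channel EOG (horizontal, vertical) with blinks on the vertical.

    Blinks are sharp 300 uV Gaussian deflections at Poisson times; slow
    sinusoidal baseline drift and white noise are added to both channels.
    """
    rng = _rng(params, 3)
    if blink_times_s is None:
        blink_times_s = generate_blink_times(params)
    fs = params.eeg_fs
    n = int(round(params.duration_s * fs))
    t_axis = np.arange(n) / fs
    wave = _blink_series(blink_times_s, fs, n)
    drift_v = params.eog_drift_uv * np.sin(2 * np.pi * 0.02 * t_axis)
    drift_h = params.eog_drift_uv * np.sin(2 * np.pi * 0.015 * t_axis + 1.0)
    eog = np.empty((2, n))
    eog[0] = 30.0 * wave + drift_h + params.eog_noise_uv * rng.standard_normal(n)
    eog[1] = 300.0 * wave + drift_v + params.eog_noise_uv * rng.standard_normal(n)
    return eog, np.asarray(blink_times_s)


def true_hemodynamics(params: SessionParams) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (dHbO, dHbR) per channel at the fNIRS rate, mM/DPF.

    Flat during the 30-s baseline hold, then a linear trend of
    ``hbo_trend_mM_per_min`` plus a slow 0.02 Hz physiological sinusoid
    and white noise; dHbR moves opposite to dHbO at 30% amplitude.
    """
    rng = _rng(params, 4)
    n = int(round(params.duration_s * params.fnirs_fs))
    t = np.arange(n) / params.fnirs_fs
    active = np.clip(t - HBO_BASELINE_HOLD_S, 0.0, None)
    ch_gain = 1.0 + 0.05 * rng.standard_normal(8)
    base = (params.hbo_trend_mM_per_min / 60.0) * active \
        + params.hbo_sin_amp_mM * np.sin(2 * np.pi * 0.02 * active) * (active > 0)
    dhbo = ch_gain[:, None] * base[None, :]
    if params.hbo_noise_mM:
        dhbo = dhbo + params.hbo_noise_mM * rng.standard_normal((8, n)) * (active > 0)
    dhbr = -0.3 * dhbo
    return dhbo, dhbr


def generate_fnirs_intensities(
    params: SessionParams, mbll: MbllParams = DEFAULT_MBLL,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-wavelength intensities from the forward Beer-Lambert model.

    The ground-truth hemodynamics are mapped to per-wavelength optical
    densities with the same extinction coefficients the inverse model
    uses, then to intensities around a nominal 1000 a.u. baseline with a
    slow multiplicative exponential drift (time constant 15 min) and
    multiplicative sensor noise.  Returns
    ``(intensity (8, 2, T_f), true_dhbo, true_dhbr)``.
    """
    rng = _rng(params, 5)
    dhbo, dhbr = true_hemodynamics(params)
    n = dhbo.shape[1]
    t = np.arange(n) / params.fnirs_fs
    baseline = 1000.0 * (1.0 + 0.1 * rng.random((8, 2)))
    # guard: a trend so large the attenuation underflows is a parameter error
    max_od = mbll.d_cm * mbll.dpf * (
        max(mbll.eps_hbo) * np.abs(dhbo).max() + max(mbll.eps_hbr) * np.abs(dhbr).max())
    if max_od > 6.0:
        raise ValueError("hemodynamic trend too large: light intensity would vanish")
    intensity = forward_intensity(dhbo, dhbr, baseline, mbll)
    if params.fnirs_drift_amp:
        amp = params.fnirs_drift_amp * rng.uniform(-1.0, 1.0, size=(8, 2))
        drift = np.exp(amp[..., None] * (1.0 - np.exp(-t / 900.0))[None, None, :])
        intensity = intensity * drift
    if params.fnirs_noise_rel:
        intensity = intensity * (
            1.0 + params.fnirs_noise_rel * rng.standard_normal((8, 2, n)))
    if np.any(intensity <= 0):
        raise ValueError("noise/drift produced non-positive intensity")
    return intensity, dhbo, dhbr


def generate_session(params: SessionParams) -> SyntheticSession:
    """Generate all four streams of one session with shared ground truth."""
    blink_times = generate_blink_times(params)
    eeg, amp = generate_eeg(params, blink_times_s=blink_times)
    ecg, r_peaks = generate_ecg(params)
    eog, _ = generate_eog(params, blink_times_s=blink_times)
    intensity, dhbo, dhbr = generate_fnirs_intensities(params)
    truth = GroundTruth(r_peak_times_s=r_peaks, blink_times_s=blink_times,
                        true_hbo=dhbo, true_hbr=dhbr, true_band_amplitudes=amp)
    return SyntheticSession(params=params, eeg_uv=eeg, eog_uv=eog, ecg_mv=ecg,
                            fnirs_intensity=intensity, truth=truth)
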