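"""Continuous-wave fNIRS processing via the modified Beer-Lambert law.

A two-wavelength (735/850 nm) continuous-wave system measures light
intensity attenuation across an emitter-detector pair.  Changes in optical
density at the two wavelengths are linear in the concentration changes of
oxy- and deoxy-hemoglobin (HbO, HbR), with wavelength-specific extinction
coefficients.  The differential path length factor (DPF) is unknown for a
CW system and is folded into the concentration unit, so all hemodynamic
outputs here carry the unit mM/DPF.

The closed-form inversion for a two-wavelength system is

    dHbO = (OD_l1 * eps_HbR_l2 - OD_l2 * eps_HbR_l1) / (d * DPF * det)
    dHbR = (OD_l2 * eps_HbO_l1 - OD_l1 * eps_HbO_l2) / (d * DPF * det)

with OD_l = log10(I_baseline / I_transient) and
det = eps_HbO_l1 * eps_HbR_l2 - eps_HbO_l2 * eps_HbR_l1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import FilterSpec, apply_filter


@dataclass(frozen=True)
class MbllParams:
    """Optical constants of the two-wavelength CW system.

    Extinction coefficients are in mM^-1 cm^-1 for (735 nm, 850 nm);
    ``d_cm`` is the emitter-detector separation; ``dpf`` is kept at 1 so
    concentrations are reported in mM/DPF.
    """

    wavelengths_nm: tuple[float, float] = (735.0, 850.0)
    eps_hbo: tuple[float, float] = (0.4646, 1.1596)
    eps_hbr: tuple[float, float] = (1.2959, 0.7861)
    d_cm: float = 3.0
    dpf: float = 1.0
    log_base: float = 10.0  # optical-density convention

    @property
    def determinant(self) -> float:
        return self.eps_hbo[0] * self.eps_hbr[1] - self.eps_hbo[1] * self.eps_hbr[0]

    def __post_init__(self) -> None:
        if abs(self.determinant) < 1e-12:
            raise ValueError("extinction coefficient matrix is singular")
        if self.d_cm <= 0 or self.dpf <= 0:
            raise ValueError("d_cm and dpf must be positive")


DEFAULT_MBLL = MbllParams()


def compute_baseline(intensity: np.ndarray, fs: float, window_s: float = 30.0) -> np.ndarray:
    """Mean intensity over the opening ``window_s`` seconds.

    ``intensity`` has time on the last axis; the baseline is the mean over
    [0, window_s) along that axis (one value per channel/wavelength).
    """
    intensity = np.asarray(intensity, dtype=float)
    n = int(round(window_s * fs))
    if intensity.shape[-1] < n:
        raise ValueError(f"need at least {window_s} s of data for the baseline")
    base = intensity[..., :n].mean(axis=-1)
    if np.any(base <= 0):
        raise ValueError("non-positive baseline intensity")
    return base


def mbll_convert(
    transient: np.ndarray,
    baseline: np.ndarray,
    params: MbllParams = DEFAULT_MBLL,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert two-wavelength intensities to (dHbO, dHbR) in mM/DPF.

    Parameters
    ----------
    transient : array, shape (..., 2, T)
        Intensity time courses, wavelength axis second-to-last ordered
        (735 nm, 850 nm).
    baseline : array, shape (..., 2)
        Baseline intensity per wavelength (see :func:`compute_baseline`).

    Returns
    -------
    dhbo, dhbr : arrays, shape (..., T)
    """
    transient = np.asarray(transient, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(transient <= 0) or np.any(baseline <= 0):
        raise ValueError("intensities must be strictly positive")
    # optical density change per wavelength
    od = np.log(baseline[..., None] / transient) / np.log(params.log_base)
    od1, od2 = od[..., 0, :], od[..., 1, :]
    scale = params.d_cm * params.dpf * params.determinant
    dhbo = (od1 * params.eps_hbr[1] - od2 * params.eps_hbr[0]) / scale
    dhbr = (od2 * params.eps_hbo[0] - od1 * params.eps_hbo[1]) / scale
    return dhbo, dhbr


def forward_intensity(
    dhbo: np.ndarray,
    dhbr: np.ndarray,
    baseline: np.ndarray,
    params: MbllParams = DEFAULT_MBLL,
) -> np.ndarray:
    """Forward Beer-Lambert attenuation model (inverse of :func:`mbll_convert`).

    Maps hemodynamic ground truth to per-wavelength intensities
    ``I(t) = I_b * base**(-d * DPF * (eps_hbo * dHbO + eps_hbr * dHbR))``.
    Returns an array of shape (..., 2, T).
    """
    dhbo = np.asarray(dhbo, dtype=float)
    dhbr = np.asarray(dhbr, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    eps_o = np.asarray(params.eps_hbo)
    eps_r = np.asarray(params.eps_hbr)
    od = params.d_cm * params.dpf * (
        eps_o[..., :, None] * dhbo[..., None, :] + eps_r[..., :, None] * dhbr[..., None, :]
    )
    intensity = baseline[..., None] * params.log_base ** (-od)
    if np.any(intensity <= 0):
        raise ValueError("forward model produced non-positive intensity")
    return intensity


def drift_highpass(series: np.ndarray, fs: float, cutoff_hz: float = 0.01,
                   order: int = 4) -> np.ndarray:
    """Remove slow baseline drift with a zero-phase high-pass filter."""
    return apply_filter(series, fs, FilterSpec("highpass", lo_hz=cutoff_hz, order=order))


def smooth_overlap(series: np.ndarray, fs: float, window_s: float = 10.0,
                   overlap: float = 0.5) -> np.ndarray:
    """Smooth with overlapping window means, interpolated back to the grid.

    Window means are computed at hops of ``window_s * (1 - overlap)`` and
    linearly interpolated (constant-extrapolated at the edges) back onto
    the original sample grid, preserving length.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    win = int(round(window_s * fs))
    hop = int(round(win * (1.0 - overlap)))
    if n < win or win < 1 or hop < 1:
        raise ValueError("series shorter than one smoothing window")
    starts = np.arange(0, n - win + 1, hop)
    centers = starts + (win - 1) / 2.0
    flat = series.reshape(-1, n)
    out = np.empty_like(flat)
    means = np.stack([flat[:, s:s + win].mean(axis=1) for s in starts], axis=1)
    grid = np.arange(n, dtype=float)
    for i in range(flat.shape[0]):
        out[i] = np.interp(grid, centers, means[i])
    return out.reshape(series.shape)


def trial_amplitudes(series: np.ndarray, fs: float, trials) -> np.ndarray:
    """Mean level of a hemodynamic series within each trial.

    ``series`` has time last; channel axes are averaged so one amplitude
    per trial is returned (the feature fed to the fatigue index and the
    classifier).  ``trials`` is a :class:`~drivefatigue.eeg.TrialSet`.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    flat = series.reshape(-1, n).mean(axis=0)
    out = np.empty(trials.n_trials)
    for k, onset in enumerate(trials.onsets_s):
        i0 = int(round(onset * fs))
        i1 = int(round((onset + trials.trial_len_s) * fs))
        if i1 > n:
            raise ValueError("trial extends beyond the series")
        out[k] = flat[i0:i1].mean()
    return out
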