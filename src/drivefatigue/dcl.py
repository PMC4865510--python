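"""The Driving Condition Level (DCL) fatigue index.

Three per-minute features — the beta/alpha RPL ratio from EEG, the mean
HbO change from fNIRS, and the heart rate from ECG — are min-max
normalized to [0, 1] and summed:

    DCL = norm(beta RPL / alpha RPL) + norm(HbO) + norm(HR),  0 <= DCL <= 3.

All three features are larger when the driver is alert, so a smaller DCL
indicates greater fatigue.  Before normalization, values outside
mean +/- 2*sd of the feature set are treated as outliers and shrunk to the
minimum/maximum of the remaining values.  The relative DCL compares the
two driving conditions of one subject:

    rDCL (%) = 100 - 100 * DCL_sleep_deprived / DCL_well_rested,

a higher rDCL meaning a larger fatigue-induced drop.  A weighted variant
DCL = a*norm(ratio) + b*norm(HbO) + c*norm(HR) is searched on the
{0, 0.1, ..., 1.0}^3 grid for the largest between-condition difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np


@dataclass(frozen=True)
class NormalizationBounds:
    """Min-max bounds after outlier shrinkage, plus the moments used."""

    min_x: float
    max_x: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.min_x < self.max_x:
            raise ValueError("degenerate bounds: min >= max")


@dataclass(frozen=True)
class DclRecord:
    """Per-minute DCL values and the session-level summary (their mean)."""

    dcl_per_min: np.ndarray
    condition: str = ""

    @property
    def dcl_session(self) -> float:
        return float(np.nanmean(self.dcl_per_min))


def shrink_outliers(values: np.ndarray, n_sd: float = 2.0) -> np.ndarray:
    """Shrink values outside mean +/- n_sd*sd to the inlier min/max."""
    values = np.asarray(values, dtype=float)
    mean, sd = values.mean(), values.std()
    lo, hi = mean - n_sd * sd, mean + n_sd * sd
    inlier = values[(values >= lo) & (values <= hi)]
    if inlier.size == 0:
        return values.copy()
    return np.clip(values, inlier.min(), inlier.max())


def fit_bounds(values: np.ndarray, n_sd: float = 2.0) -> NormalizationBounds:
    """Min-max bounds of the outlier-shrunk feature set."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise ValueError("need at least 3 finite values to fit bounds")
    shrunk = shrink_outliers(values, n_sd=n_sd)
    min_x, max_x = float(shrunk.min()), float(shrunk.max())
    if min_x == max_x:
        raise ValueError("all values identical: zero normalization range")
    return NormalizationBounds(min_x=min_x, max_x=max_x,
                               mean=float(values.mean()), sd=float(values.std()))


def normalize(x: np.ndarray | float, bounds: NormalizationBounds) -> np.ndarray | float:
    """Min-max scale to [0, 1], clipping beyond the fitted bounds."""
    scaled = (np.asarray(x, dtype=float) - bounds.min_x) / (bounds.max_x - bounds.min_x)
    out = np.clip(scaled, 0.0, 1.0)
    return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class DclComponents:
    """Per-minute normalized components, each already in [0, 1]."""

    norm_ratio: np.ndarray  # beta/alpha RPL
    norm_hbo: np.ndarray
    norm_hr: np.ndarray

    def __post_init__(self) -> None:
        a, b, c = (np.asarray(v, dtype=float) for v in
                   (self.norm_ratio, self.norm_hbo, self.norm_hr))
        if not (a.shape == b.shape == c.shape):
            raise ValueError("component series lengths differ")
        for v in (a, b, c):
            fin = v[np.isfinite(v)]
            if fin.size and (fin.min() < -1e-9 or fin.max() > 1 + 1e-9):
                raise ValueError("components must lie in [0, 1]")
        object.__setattr__(self, "norm_ratio", a)
        object.__setattr__(self, "norm_hbo", b)
        object.__setattr__(self, "norm_hr", c)


def compute_dcl(components: DclComponents,
                weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                condition: str = "") -> DclRecord:
    """Weighted sum of the normalized components, per minute."""
    a, b, c = weights
    per_min = (a * components.norm_ratio + b * components.norm_hbo
               + c * components.norm_hr)
    return DclRecord(dcl_per_min=per_min, condition=condition)


def compute_rdcl(dcl_well: float, dcl_sleep: float) -> float:
    """Relative DCL drop in percent: 100 - 100*DCL_sleep/DCL_well."""
    if dcl_well <= 0:
        raise ValueError("well-rested DCL must be positive")
    return 100.0 - 100.0 * dcl_sleep / dcl_well


def modality_contributions(components_well: DclComponents,
                           components_sleep: DclComponents) -> dict[str, float]:
    """Decompose the session DCL difference into per-modality terms.

    contribution_m = mean(norm_m, well) - mean(norm_m, sleep); the three
    contributions sum exactly to DCL_well - DCL_sleep (unit weights).
    """
    out = {}
    for name, key in (("eeg", "norm_ratio"), ("fnirs", "norm_hbo"), ("ecg", "norm_hr")):
        w = np.nanmean(getattr(components_well, key))
        s = np.nanmean(getattr(components_sleep, key))
        out[name] = float(w - s)
    return out


WEIGHT_GRID = tuple(round(0.1 * k, 1) for k in range(11))


def grid_search_weights(components_well: DclComponents,
                        components_sleep: DclComponents) -> tuple[tuple[float, float, float], float]:
    """Exhaustive 11^3 search for weights maximizing DCL_well - DCL_sleep.

    Ties break to the lexicographically smallest (a, b, c).  Returns the
    best weights and the difference they achieve.
    """
    best_w, best_diff = None, -np.inf
    for w in product(WEIGHT_GRID, repeat=3):
        diff = (compute_dcl(components_well, w).dcl_session
                - compute_dcl(components_sleep, w).dcl_session)
        if diff > best_diff + 1e-12:
            best_w, best_diff = w, diff
    return best_w, float(best_diff)
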