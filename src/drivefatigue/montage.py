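"""Electrode montage and region definitions.

The electrophysiology cap is a 64-channel 10-20 layout (Biosemi ordering)
plus horizontal/vertical EOG and two chest ECG electrodes, all sampled at
the same rate on one amplifier.
"""

from __future__ import annotations

# Biosemi 64-channel 10-20 labels, amplifier order.
EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

EOG_CHANNELS: tuple[str, ...] = ("EOGh", "EOGv")
ECG_CHANNELS: tuple[str, ...] = ("ECG1", "ECG2")

#: Right centro-parietal channels where the alpha rhythm separates the two
#: driving conditions (alpha relative power rises when sleep-deprived).
DEFAULT_ALPHA_REGION: tuple[str, ...] = ("CP2", "CP4", "CP6", "P2", "P4", "P6")

#: Fronto-central channels where beta relative power drops when sleep-deprived.
DEFAULT_BETA_REGION: tuple[str, ...] = ("Fz", "FCz", "FC1", "FC2", "Cz")

#: Prefrontal channels that receive a small share of the ocular blink
#: artifact in the simulator (closest to the eyes).
FRONTAL_CHANNELS: tuple[str, ...] = ("Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8")


def channel_index(labels: tuple[str, ...] | list[str], wanted: str) -> int:
    """Index of ``wanted`` in ``labels``; raises ``ValueError`` if absent."""
    try:
        return list(labels).index(wanted)
    except ValueError:
        raise ValueError(f"channel {wanted!r} not in montage") from None


def region_indices(region: tuple[str, ...] | list[str],
                   labels: tuple[str, ...] | list[str] = EEG_CHANNELS) -> list[int]:
    """Map a list of region labels onto row indices of an EEG array."""
    return [channel_index(labels, ch) for ch in region]
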