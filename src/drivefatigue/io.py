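"""On-disk formats and trigger-based stream alignment.

Electrophysiology (64 EEG + 2 EOG + 2 ECG channels, one sampling rate)
travels as EDF+ with ``session_start``/``session_end`` annotations; the
file is written by this module's own EDF+ encoder (16-bit, physical range
set per channel from the data to minimize quantization loss) and read
back through MNE.  fNIRS raw intensities travel as a tab-delimited table
with header ``time_s, ch{1..8}_735, ch{1..8}_850``; generator ground
truth goes to a sidecar JSON.

The two acquisition computers are synchronized by triggers: the EEG
recorder marks start/end, and the fNIRS recorder starts/stops on those
triggers.  :func:`align_streams` crops both streams to the common
triggered window with time zero at the start trigger.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import montage
from .simulate import GroundTruth, SessionParams, SyntheticSession

START_LABEL = "session_start"
END_LABEL = "session_end"

_ANNOT_SAMPLES_PER_RECORD = 60  # 120 bytes of TAL space per 1-s record


# ---------------------------------------------------------------------------
# EDF+ writing

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r}")
    return b.ljust(width)


def write_edf(
    path: str | Path,
    signals: np.ndarray,
    labels: list[str],
    fs: float,
    units: list[str],
    annotations: list[tuple[float, str]] | None = None,
    start: datetime.datetime | None = None,
) -> Path:
    """Write a continuous EDF+C file with one annotation channel.

    ``signals`` is (n_channels, n_samples); the duration must be a whole
    number of seconds and ``fs`` integral, giving 1-s data records.
    """
    path = Path(path)
    signals = np.asarray(signals, dtype=float)
    n_ch, n_samp = signals.shape
    if len(labels) != n_ch or len(units) != n_ch:
        raise ValueError("labels/units must match the channel count")
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integral sampling rate")
    spr = int(round(fs))
    if n_samp % spr != 0:
        raise ValueError("signal length must be a whole number of seconds")
    n_rec = n_samp // spr
    annotations = sorted(annotations or [])
    start = start or datetime.datetime(2000, 1, 1, 0, 0, 0)

    pmin = signals.min(axis=1)
    pmax = signals.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.round((signals - pmin[:, None]) * gain[:, None] + dmin).astype("<i2")

    ns = n_ch + 1  # + annotation channel
    header = bytearray()
    header += _pad("0", 8)
    header += _pad("X X X X", 80)
    header += _pad("Startdate X X X X", 80)
    header += _pad(start.strftime("%d.%m.%y"), 8)
    header += _pad(start.strftime("%H.%M.%S"), 8)
    header += _pad(str(256 * (ns + 1)), 8)
    header += _pad("EDF+C", 44)
    header += _pad(str(n_rec), 8)
    header += _pad("1", 8)
    header += _pad(str(ns), 4)

    def field_block(values: list[str], width: int) -> bytes:
        return b"".join(_pad(v, width) for v in values)

    all_labels = labels + ["EDF Annotations"]
    header += field_block(all_labels, 16)
    header += field_block([""] * ns, 80)                         # transducer
    header += field_block(units + [""], 8)                       # physical dim
    header += field_block([f"{v:.6g}"[:8] for v in pmin] + ["-1"], 8)
    header += field_block([f"{v:.6g}"[:8] for v in pmax] + ["1"], 8)
    header += field_block([str(dmin)] * n_ch + [str(dmin)], 8)
    header += field_block([str(dmax)] * n_ch + [str(dmax)], 8)
    header += field_block([""] * ns, 80)                         # prefiltering
    header += field_block([str(spr)] * n_ch + [str(_ANNOT_SAMPLES_PER_RECORD)], 8)
    header += field_block([""] * ns, 32)                         # reserved

    def _tal_num(t: float) -> str:
        return f"{t:g}" if t >= 0 else f"{t:+g}"

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for rec in range(n_rec):
            fh.write(digital[:, rec * spr:(rec + 1) * spr].tobytes())
            tal = f"+{rec:g}\x14\x14\x00".encode("ascii")
            for onset, text in annotations:
                in_rec = rec <= onset < rec + 1 or (rec == n_rec - 1 and onset == n_rec)
                if in_rec:
                    tal += f"+{_tal_num(onset)}\x14{text}\x14\x00".encode("ascii")
            room = 2 * _ANNOT_SAMPLES_PER_RECORD
            if len(tal) > room:
                raise ValueError("too many annotations in one data record")
            fh.write(tal.ljust(room, b"\x00"))
    return path


def write_session_edf(path: str | Path, session: SyntheticSession) -> Path:
    """Write the electrophysiology of a synthetic session as EDF+."""
    signals = np.vstack([session.eeg_uv, session.eog_uv, session.ecg_mv])
    labels = list(montage.EEG_CHANNELS) + list(montage.EOG_CHANNELS) + list(montage.ECG_CHANNELS)
    units = ["uV"] * 66 + ["mV"] * 2
    annotations = [(0.0, START_LABEL), (session.params.duration_s, END_LABEL)]
    return write_edf(path, signals, labels, session.params.eeg_fs, units, annotations)


# ---------------------------------------------------------------------------
# EDF reading (MNE for data/annotations; header re-parsed for physical units)

def _edf_units(path: Path) -> dict[str, str]:
    with open(path, "rb") as fh:
        head = fh.read(256)
        ns = int(head[252:256].decode().strip())
        block = fh.read(256 * ns)
    labels = [block[16 * i:16 * (i + 1)].decode("ascii").strip() for i in range(ns)]
    dims = [block[16 * ns + 80 * ns + 8 * i: 16 * ns + 80 * ns + 8 * (i + 1)]
            .decode("ascii").strip() for i in range(ns)]
    return dict(zip(labels, dims))


_UNIT_SCALE = {"uV": 1e6, "µV": 1e6, "mV": 1e3, "V": 1.0, "": 1.0}


def read_edf(path: str | Path, require_trigger: bool = True):
    """Read an EDF file: (signals, labels, fs, annotations).

    Signals come back in their original physical units (uV channels as
    uV, mV channels as mV).  Raises on a malformed header, on missing
    EOG/ECG channel labels, and — unless ``require_trigger`` is False —
    when no ``session_start`` annotation is present.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on bad headers
        raise ValueError(f"not a readable EDF file: {path}") from exc
    labels = list(raw.ch_names)
    fs = float(raw.info["sfreq"])
    units = _edf_units(path)
    data = raw.get_data()  # volts for voltage channels
    for i, lab in enumerate(labels):
        data[i] *= _UNIT_SCALE.get(units.get(lab, ""), 1.0)
    annotations = [(float(on), str(desc))
                   for on, desc in zip(raw.annotations.onset, raw.annotations.description)]
    eog = [l for l in labels if l.upper().startswith("EOG")]
    ecg = [l for l in labels if l.upper().startswith("ECG")]
    if len(eog) != 2 or len(ecg) != 2:
        raise ValueError("expected exactly 2 EOG and 2 ECG channels")
    if require_trigger and not any(d == START_LABEL for _, d in annotations):
        raise ValueError(f"no {START_LABEL!r} annotation in {path}")
    return data, labels, fs, annotations


def partition_labels(labels: list[str]) -> dict[str, list[str]]:
    """Split channel labels into eeg/eog/ecg groups by label convention."""
    eog = [l for l in labels if l.upper().startswith("EOG")]
    ecg = [l for l in labels if l.upper().startswith("ECG")]
    eeg = [l for l in labels if l not in eog and l not in ecg]
    return {"eeg": eeg, "eog": eog, "ecg": ecg}


# ---------------------------------------------------------------------------
# fNIRS table

def fnirs_columns() -> list[str]:
    return (["time_s"] + [f"ch{c}_735" for c in range(1, 9)]
            + [f"ch{c}_850" for c in range(1, 9)])


def write_fnirs_table(path: str | Path, intensity: np.ndarray, fs: float) -> Path:
    """Write an (8, 2, T) intensity tensor as the tab-delimited dialect."""
    path = Path(path)
    intensity = np.asarray(intensity)
    if intensity.shape[:2] != (8, 2):
        raise ValueError("expected an (8, 2, T) intensity tensor")
    t = np.arange(intensity.shape[2]) / fs
    cols = {"time_s": t}
    for w, wl in enumerate((735, 850)):
        for c in range(8):
            cols[f"ch{c + 1}_{wl}"] = intensity[c, w]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_fnirs_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read the fNIRS dialect back into ((8, 2, T) tensor, time vector)."""
    df = pd.read_csv(path, sep="\t")
    expected = fnirs_columns()
    if list(df.columns) != expected:
        raise ValueError(f"fNIRS table columns must be exactly {expected}")
    t = df["time_s"].to_numpy(float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("fNIRS time vector must be strictly increasing")
    tensor = np.empty((8, 2, t.size))
    for w, wl in enumerate((735, 850)):
        for c in range(8):
            tensor[c, w] = df[f"ch{c + 1}_{wl}"].to_numpy(float)
    return tensor, t


# ---------------------------------------------------------------------------
# ground truth sidecar

def write_ground_truth(path: str | Path, session: SyntheticSession,
                       include_hemo: bool = True) -> Path:
    path = Path(path)
    truth = session.truth
    payload = {
        "params": {k: (v if not isinstance(v, np.generic) else v.item())
                   for k, v in vars(session.params).items()},
        "r_peak_times_s": truth.r_peak_times_s.tolist(),
        "blink_times_s": truth.blink_times_s.tolist(),
        "true_band_amplitudes_uv": truth.true_band_amplitudes.tolist(),
    }
    if include_hemo:
        payload["true_hbo_mM"] = truth.true_hbo.tolist()
        payload["true_hbr_mM"] = truth.true_hbr.tolist()
    path.write_text(json.dumps(payload))
    return path


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# multimodal container and alignment

@dataclass
class MultimodalRecording:
    """Synchronized raw traces of one session, before feature extraction."""

    eeg: np.ndarray
    eog: np.ndarray
    ecg: np.ndarray
    eeg_fs: float
    fnirs_intensity: np.ndarray
    fnirs_fs: float
    condition: str = ""
    eeg_labels: list[str] = field(default_factory=lambda: list(montage.EEG_CHANNELS))
    bad_channels: tuple[str, ...] = ()
    start_trigger_s: float = 0.0       # electrophysiology clock
    end_trigger_s: float | None = None
    fnirs_start_s: float = 0.0         # fNIRS clock
    fnirs_end_s: float | None = None

    @property
    def duration_s(self) -> float:
        return self.eeg.shape[1] / self.eeg_fs

    def drop_bad_channels(self) -> "MultimodalRecording":
        if not self.bad_channels:
            return self
        keep = [i for i, l in enumerate(self.eeg_labels) if l not in self.bad_channels]
        if not keep:
            raise ValueError("bad-channel list removes every EEG channel")
        return replace(self, eeg=self.eeg[keep],
                       eeg_labels=[self.eeg_labels[i] for i in keep])


def align_streams(rec: MultimodalRecording, max_skew_s: float = 1.0,
                  min_overlap_s: float = 60.0) -> MultimodalRecording:
    """Crop both acquisition streams to the triggered window.

    Each stream is cut to its own [start, end] marker (time zero moves to
    the start trigger), the two durations must agree within
    ``max_skew_s``, and both are trimmed at the tail to the common
    duration.
    """
    if rec.end_trigger_s is None:
        raise ValueError("electrophysiology end trigger missing")
    e0 = int(round(rec.start_trigger_s * rec.eeg_fs))
    e1 = int(round(rec.end_trigger_s * rec.eeg_fs))
    f_end = rec.fnirs_end_s if rec.fnirs_end_s is not None else \
        rec.fnirs_intensity.shape[-1] / rec.fnirs_fs
    f0 = int(round(rec.fnirs_start_s * rec.fnirs_fs))
    f1 = int(round(f_end * rec.fnirs_fs))
    if e1 <= e0 or f1 <= f0:
        raise ValueError("trigger markers out of order")
    dur_e = (e1 - e0) / rec.eeg_fs
    dur_f = (f1 - f0) / rec.fnirs_fs
    if abs(dur_e - dur_f) > max_skew_s:
        raise ValueError(f"stream durations differ by {abs(dur_e - dur_f):.2f} s")
    common = min(dur_e, dur_f)
    if common < min_overlap_s:
        raise ValueError(f"triggered overlap is only {common:.1f} s")
    ne = int(round(common * rec.eeg_fs))
    nf = int(round(common * rec.fnirs_fs))
    return replace(
        rec,
        eeg=rec.eeg[:, e0:e0 + ne],
        eog=rec.eog[:, e0:e0 + ne],
        ecg=rec.ecg[:, e0:e0 + ne],
        fnirs_intensity=rec.fnirs_intensity[..., f0:f0 + nf],
        start_trigger_s=0.0, end_trigger_s=common,
        fnirs_start_s=0.0, fnirs_end_s=common,
    )


def load_recording(edf_path: str | Path, fnirs_path: str | Path,
                   condition: str = "", bad_channels: tuple[str, ...] = (),
                   ) -> MultimodalRecording:
    """Assemble a :class:`MultimodalRecording` from the two on-disk files."""
    data, labels, fs, annotations = read_edf(edf_path)
    groups = partition_labels(labels)
    idx = {l: i for i, l in enumerate(labels)}
    eeg = data[[idx[l] for l in groups["eeg"]]]
    eog = data[[idx[l] for l in groups["eog"]]]
    ecg = data[[idx[l] for l in groups["ecg"]]]
    start = next(on for on, d in annotations if d == START_LABEL)
    ends = [on for on, d in annotations if d == END_LABEL]
    tensor, t = read_fnirs_table(fnirs_path)
    return MultimodalRecording(
        eeg=eeg, eog=eog, ecg=ecg, eeg_fs=fs,
        fnirs_intensity=tensor, fnirs_fs=1.0 / float(np.median(np.diff(t))),
        condition=condition, eeg_labels=groups["eeg"], bad_channels=bad_channels,
        start_trigger_s=float(start), end_trigger_s=float(ends[0]) if ends else None,
        fnirs_start_s=float(t[0]), fnirs_end_s=float(t[-1] + np.median(np.diff(t))),
    )
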