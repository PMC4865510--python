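"""End-to-end orchestration: simulate -> preprocess -> features -> DCL -> classify.

The pipeline mirrors one subject of the driving study: a well-rested and
a sleep-deprived session are simulated (or loaded), each stream is
preprocessed and reduced to per-trial and per-minute features, the
Driving Condition Level is computed on normalization bounds pooled over
both sessions, and single-modality plus stacked-fusion FLDA accuracies
are estimated over the 30 sliding time-ordered splits.

Everything is driven by a schema-validated :class:`PipelineConfig`
(unknown keys rejected) and is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import cardiac, dcl as dcl_mod, eeg as eeg_mod, io as io_mod, montage, nirs, preprocess as pp
from .classify import evaluate_modality, fuse_classifiers, make_splits
from .eeg import RegionSpec, segment_trials
from .simulate import PRESETS, SessionParams, generate_session

log = logging.getLogger("drivefatigue")

CONDITIONS = ("well_rested", "sleep_deprived")


class SplitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_reps: int = 30
    train_frac: float = 0.7
    buffer_trials: int = 6
    shift_trials: int = 6
    circular: bool = True


class IcaConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    max_iter: int = 100
    decim: int = 8
    r_threshold: float = 0.7


class PipelineConfig(BaseModel):
    """Resolved parameters for one subject's two-session analysis."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "drivefatigue_out"
    seed: int = 0
    duration_s: float = 600.0
    trial_len_s: float = 10.0
    alpha_region: list[str] = Field(
        default_factory=lambda: list(montage.DEFAULT_ALPHA_REGION))
    beta_region: list[str] = Field(
        default_factory=lambda: list(montage.DEFAULT_BETA_REGION))
    bad_channels: list[str] = Field(default_factory=list)
    ica: IcaConfig = Field(default_factory=IcaConfig)
    split: SplitConfig = Field(default_factory=SplitConfig)
    r_peak_k_sd: float = 2.5
    r_peak_refractory_s: float = 0.3
    blink_k_sd: float = 3.0
    session_overrides: dict[str, dict] = Field(default_factory=dict)

    def session_params(self, condition: str) -> SessionParams:
        overrides = dict(self.session_overrides.get(condition, {}))
        overrides.setdefault("duration_s", self.duration_s)
        overrides.setdefault("seed", self.seed + {"well_rested": 0, "sleep_deprived": 1}[condition])
        base = PRESETS[condition]
        valid = {f.name for f in dataclasses.fields(SessionParams)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown session parameter(s): {sorted(unknown)}")
        return dataclasses.replace(base, **overrides)

    def regions(self) -> RegionSpec:
        return RegionSpec(alpha_region=tuple(self.alpha_region),
                          beta_region=tuple(self.beta_region))


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    data = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    data.update(overrides)
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# stages

def simulate_stage(config: PipelineConfig) -> dict[str, dict[str, Path]]:
    """Generate both sessions and write EDF / fNIRS table / truth JSON."""
    raw_dir = Path(config.out_dir) / "raw"
    raw_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for condition in CONDITIONS:
        params = config.session_params(condition)
        log.info("simulating %s: %s", condition, params)
        session = generate_session(params)
        paths[condition] = {
            "edf": io_mod.write_session_edf(raw_dir / f"{condition}.edf", session),
            "fnirs": io_mod.write_fnirs_table(raw_dir / f"{condition}_fnirs.tsv",
                                              session.fnirs_intensity, params.fnirs_fs),
            "truth": io_mod.write_ground_truth(raw_dir / f"{condition}_truth.json", session,
                                               include_hemo=False),
        }
    return paths


def preprocess_recording(rec: io_mod.MultimodalRecording, config: PipelineConfig,
                         ) -> dict[str, np.ndarray]:
    """Filter/clean one aligned recording into analysis-ready streams."""
    rec = rec.drop_bad_channels()
    fs = rec.eeg_fs
    eeg = rec.eeg
    if config.ica.enabled:
        hp = pp.FilterSpec("highpass", 1.0)
        eeg_hp = pp.apply_filter(eeg, fs, hp)
        eog_hp = pp.apply_filter(rec.eog, fs, hp)
        ica = pp.fit_infomax_ica(eeg_hp[:, :: config.ica.decim],
                                 max_iter=config.ica.max_iter, seed=0)
        try:
            eeg, removed = pp.remove_eog_components(eeg_hp, ica, eog_hp,
                                                    r_threshold=config.ica.r_threshold)
            log.info("ICA removed %d ocular component(s)", len(removed))
        except ValueError as exc:
            raise RuntimeError(f"preprocess: ICA cleaning failed ({exc})") from exc
    eeg = pp.apply_filter(eeg, fs, pp.EEG_BANDPASS)
    ecg = pp.detrend(pp.apply_filter(rec.ecg, fs, pp.ECG_BANDPASS))
    eog_v = pp.apply_filter(rec.eog[1], fs, pp.EOG_BANDPASS)
    return {"eeg": eeg, "ecg": ecg, "eog_v": eog_v,
            "fnirs_intensity": rec.fnirs_intensity, "labels": rec.eeg_labels}


def extract_features(streams: dict, eeg_fs: float, fnirs_fs: float,
                     config: PipelineConfig) -> dict:
    """Per-trial and per-minute features for one session."""
    duration = streams["eeg"].shape[1] / eeg_fs
    trials = segment_trials(duration, config.trial_len_s)
    n_min = int(duration // 60)

    rpl = eeg_mod.trial_rpls(streams["eeg"], eeg_fs, trials)
    alpha_cp, beta_fc, ratio = eeg_mod.region_features(
        rpl, config.regions(), labels=tuple(streams["labels"]))

    hr_leads, rr_leads = [], []
    for lead in streams["ecg"]:
        peaks = cardiac.detect_r_peaks(lead, eeg_fs, k_sd=config.r_peak_k_sd,
                                       refractory_s=config.r_peak_refractory_s)
        hr_leads.append(cardiac.heart_rate(peaks, duration))
        rr_leads.append(cardiac.rr_features(peaks, trials))
    hr = cardiac.mean_heart_rate_two_leads(*hr_leads)
    rr = np.nanmean(np.vstack(rr_leads), axis=0)

    blink_pm = cardiac.blink_rate(streams["eog_v"], eeg_fs, duration,
                                  k_sd=config.blink_k_sd)

    baseline = nirs.compute_baseline(streams["fnirs_intensity"], fnirs_fs)
    dhbo_raw, dhbr_raw = nirs.mbll_convert(streams["fnirs_intensity"], baseline)
    # trial-level classification features: drift-high-passed + smoothed
    dhbo = nirs.smooth_overlap(nirs.drift_highpass(dhbo_raw, fnirs_fs), fnirs_fs)
    dhbr = nirs.smooth_overlap(nirs.drift_highpass(dhbr_raw, fnirs_fs), fnirs_fs)
    hbo_trial = nirs.trial_amplitudes(dhbo, fnirs_fs, trials)
    hbr_trial = nirs.trial_amplitudes(dhbr, fnirs_fs, trials)
    # index-level HbO: baseline-referenced without the high-pass, because the
    # session-scale oxygenation rise the index encodes lies below any
    # practical drift cutoff and would be removed along with the drift
    hbo_index = nirs.trial_amplitudes(nirs.smooth_overlap(dhbo_raw, fnirs_fs),
                                      fnirs_fs, trials)

    trials_per_min = int(60 / config.trial_len_s)

    def per_minute(x):
        return np.array([np.nanmean(x[m * trials_per_min:(m + 1) * trials_per_min])
                         for m in range(n_min)])

    return {
        "n_trials": trials.n_trials,
        "n_minutes": n_min,
        "trial": {
            "alpha_cp": alpha_cp, "beta_fc": beta_fc, "ratio": ratio,
            "mean_rr_s": rr, "hbo": hbo_trial, "hbr": hbr_trial,
        },
        "minute": {
            "ratio": per_minute(ratio),
            "hbo": per_minute(hbo_index),
            "hr": hr.hr_per_min[:n_min],
            "blink_rate": blink_pm[:n_min],
        },
        "mean_hr": hr.mean_hr,
    }


def compute_dcl_stage(features: dict[str, dict]) -> dict:
    """Pooled-bounds normalization, per-minute DCL, rDCL, contributions."""
    comp = {}
    bounds = {}
    for key in ("ratio", "hbo", "hr"):
        pooled = np.concatenate([features[c]["minute"][key] for c in CONDITIONS])
        try:
            bounds[key] = dcl_mod.fit_bounds(pooled)
        except ValueError:
            # a feature with zero range across both sessions carries no
            # condition information; pin its normalized value to 1/2
            bounds[key] = None

    def _norm(values, b):
        return dcl_mod.normalize(values, b) if b is not None else np.full(len(values), 0.5)

    for c in CONDITIONS:
        comp[c] = dcl_mod.DclComponents(
            norm_ratio=_norm(features[c]["minute"]["ratio"], bounds["ratio"]),
            norm_hbo=_norm(features[c]["minute"]["hbo"], bounds["hbo"]),
            norm_hr=_norm(features[c]["minute"]["hr"], bounds["hr"]),
        )
    records = {c: dcl_mod.compute_dcl(comp[c], condition=c) for c in CONDITIONS}
    best_w, best_diff = dcl_mod.grid_search_weights(comp["well_rested"], comp["sleep_deprived"])
    return {
        "dcl_per_min": {c: records[c].dcl_per_min.tolist() for c in CONDITIONS},
        "dcl_session": {c: records[c].dcl_session for c in CONDITIONS},
        "rdcl_percent": dcl_mod.compute_rdcl(records["well_rested"].dcl_session,
                                             records["sleep_deprived"].dcl_session),
        "modality_contributions": dcl_mod.modality_contributions(
            comp["well_rested"], comp["sleep_deprived"]),
        "weighted_dcl": {"best_weights": list(best_w), "best_difference": best_diff},
    }


def classify_stage(features: dict[str, dict], config: PipelineConfig) -> dict:
    """Single-modality and fused accuracies over the sliding splits."""
    n_trials = features["well_rested"]["n_trials"]
    splits = make_splits(n_trials=n_trials, train_frac=config.split.train_frac,
                         buffer_trials=config.split.buffer_trials,
                         n_reps=config.split.n_reps, shift_trials=config.split.shift_trials,
                         circular=config.split.circular)

    def matrices(c):
        t = features[c]["trial"]
        return {
            "eeg": np.column_stack([t["alpha_cp"], t["beta_fc"]]),
            "ecg": np.asarray(t["mean_rr_s"])[:, None],
            "fnirs": np.column_stack([t["hbo"], t["hbr"]]),
        }

    mw, ms = matrices("well_rested"), matrices("sleep_deprived")
    out = {"per_repetition": {}, "mean_accuracy": {}}
    for name in ("eeg", "ecg", "fnirs"):
        acc = evaluate_modality(mw[name], ms[name], splits)
        out["per_repetition"][name] = acc.tolist()
        out["mean_accuracy"][name] = float(acc.mean())
    fused = fuse_classifiers([mw[m] for m in ("eeg", "ecg", "fnirs")],
                             [ms[m] for m in ("eeg", "ecg", "fnirs")], splits)
    out["per_repetition"]["eeg+ecg+fnirs"] = fused.tolist()
    out["mean_accuracy"]["eeg+ecg+fnirs"] = float(fused.mean())
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the JSON report plus CSV tables."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline config: %s", config.model_dump())
    paths = simulate_stage(config)

    features = {}
    for condition in CONDITIONS:
        rec = io_mod.load_recording(paths[condition]["edf"], paths[condition]["fnirs"],
                                    condition=condition,
                                    bad_channels=tuple(config.bad_channels))
        rec = io_mod.align_streams(rec)
        streams = preprocess_recording(rec, config)
        features[condition] = extract_features(streams, rec.eeg_fs, rec.fnirs_fs, config)

    dcl_report = compute_dcl_stage(features)
    cls_report = classify_stage(features, config)

    report = {
        "config": config.model_dump(),
        "features": {
            c: {
                "mean_hr_bpm": features[c]["mean_hr"],
                "mean_alpha_cp": float(np.mean(features[c]["trial"]["alpha_cp"])),
                "mean_beta_fc": float(np.mean(features[c]["trial"]["beta_fc"])),
                "mean_beta_over_alpha": float(np.mean(features[c]["trial"]["ratio"])),
                "mean_hbo_mM": float(np.mean(features[c]["trial"]["hbo"])),
                "mean_blink_rate_per_min": float(np.mean(features[c]["minute"]["blink_rate"])),
                "n_trials": features[c]["n_trials"],
            } for c in CONDITIONS
        },
        "dcl": dcl_report,
        "classification": cls_report,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    for c in CONDITIONS:
        pd.DataFrame(features[c]["trial"]).to_csv(out_dir / f"features_{c}_trials.csv",
                                                  index=False)
        pd.DataFrame(features[c]["minute"]).to_csv(out_dir / f"features_{c}_minutes.csv",
                                                   index=False)
    return report
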