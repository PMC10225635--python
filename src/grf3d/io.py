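"""Reading and writing trials, cohorts, predictions and reports.

On-disk layout per trial directory::

    meta.json          subject/meta fields, rates, units, force_present
    pelvis.csv         t, ax, ay, az         (m/s², axes AP/ML/vertical)
    tibia_left.csv     idem
    tibia_right.csv    idem
    force.csv          t, f_ml, f_ap, f_v    (newtons; absent at inference)

Cohort = directory of such trial directories, one per
(subject, velocity, stride-frequency) cell. Writing is deterministic:
fixed column order and float formatting, sorted JSON keys.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .types import (GRAVITY_MS2, EstimateSource, ForceStream, GrfEstimate,
                    SensorId, SensorStream, SfCondition, SubjectInfo, Trial,
                    TrialMeta)

_FLOAT_FMT = "%.17g"
_SENSOR_FILES = {
    SensorId.PELVIS: "pelvis.csv",
    SensorId.TIBIA_LEFT: "tibia_left.csv",
    SensorId.TIBIA_RIGHT: "tibia_right.csv",
}


class TrialFormatError(ValueError):
    """A trial directory does not follow the documented layout."""


def trial_dirname(trial: Trial) -> str:
    return (f"{trial.subject.subject_id}_v{trial.meta.velocity_kmh:g}"
            f"_{trial.meta.sf_condition.value}")


def _write_csv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def write_trial(trial: Trial, path) -> None:
    """Write ``trial`` under directory ``path`` (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    t = np.arange(trial.n_samples) / trial.rate_hz
    for sid, fname in _SENSOR_FILES.items():
        acc = trial.sensor(sid).acc
        df = pd.DataFrame({"t": t, "ax": acc[:, 0], "ay": acc[:, 1], "az": acc[:, 2]})
        _write_csv(path / fname, df)
    meta = {
        "subject_id": trial.subject.subject_id,
        "body_mass_kg": trial.subject.body_mass_kg,
        "velocity_kmh": trial.meta.velocity_kmh,
        "sf_condition": trial.meta.sf_condition.value,
        "duration_s": trial.meta.duration_s,
        "sensor_rate_hz": trial.rate_hz,
        "acc_units": "m/s^2",
        "force_units": "N",
        "force_present": trial.force is not None,
    }
    if trial.force is not None:
        meta["force_rate_hz"] = trial.force.rate_hz
        tf = np.arange(trial.force.n_samples) / trial.force.rate_hz
        df = pd.DataFrame({"t": tf, "f_ml": trial.force.grf[:, 0],
                           "f_ap": trial.force.grf[:, 1], "f_v": trial.force.grf[:, 2]})
        _write_csv(path / "force.csv", df)
    if trial.stride_window is not None:
        meta["stride_window"] = list(trial.stride_window)
    (path / "meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    if trial.stance_mask is not None:
        np.savetxt(path / "stance_mask.csv", trial.stance_mask.astype(int),
                   fmt="%d", header="stance", comments="")


def _read_stream_csv(path: Path, cols, what: str) -> np.ndarray:
    if not path.exists():
        raise TrialFormatError(f"missing {what} file: {path.name}")
    df = pd.read_csv(path, float_precision="round_trip")
    for c in cols:
        if c not in df.columns:
            raise TrialFormatError(f"{path.name}: missing required column '{c}'")
    arr = df[list(cols)].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(arr).all(axis=1))
    if bad.size:
        raise ValueError(f"{path.name}: non-finite value at row {int(bad[0])}")
    return arr


def read_trial(path) -> Trial:
    """Read a trial directory written by :func:`write_trial`.

    Acceleration declared in ``g`` units in the sidecar is converted by
    exactly 9.81 m/s² per g.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise TrialFormatError(f"missing meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    for key in ("subject_id", "body_mass_kg", "velocity_kmh", "sf_condition"):
        if key not in meta:
            raise TrialFormatError(f"meta.json: missing required field '{key}'")
    subject = SubjectInfo(meta["subject_id"], float(meta["body_mass_kg"]))
    tmeta = TrialMeta(float(meta["velocity_kmh"]), SfCondition(meta["sf_condition"]),
                      float(meta.get("duration_s", 90.0)))
    rate = float(meta.get("sensor_rate_hz", 240.0))
    acc_scale = GRAVITY_MS2 if meta.get("acc_units", "m/s^2") == "g" else 1.0
    sensors = {}
    for sid, fname in _SENSOR_FILES.items():
        arr = _read_stream_csv(path / fname, ("ax", "ay", "az"), f"sensor '{sid.value}'")
        sensors[sid] = SensorStream(sid, arr * acc_scale, rate)
    force = None
    if meta.get("force_present", (path / "force.csv").exists()):
        arr = _read_stream_csv(path / "force.csv", ("f_ml", "f_ap", "f_v"), "force")
        force = ForceStream(arr, float(meta.get("force_rate_hz", 2048.0)))
    stance_mask = None
    mask_path = path / "stance_mask.csv"
    if mask_path.exists():
        stance_mask = np.loadtxt(mask_path, skiprows=1, dtype=int).astype(bool)
    window = tuple(meta["stride_window"]) if "stride_window" in meta else None
    return Trial(subject, tmeta, sensors, force, stance_mask, window)


def read_cohort(path) -> List[Trial]:
    """Read all trial directories under ``path``.

    Returns trials sorted by (subject_id, velocity, sf_condition); missing
    cells are permitted, duplicated ones are an error.
    """
    path = Path(path)
    trials = []
    for sub in sorted(p for p in path.iterdir() if p.is_dir()):
        if (sub / "meta.json").exists():
            trials.append(read_trial(sub))
    if not trials:
        warnings.warn(f"no trials found under {path}")
        return []
    order = {c.value: i for i, c in enumerate(SfCondition)}
    keyed = {}
    for t in trials:
        key = (t.subject.subject_id, t.meta.velocity_kmh, t.meta.sf_condition.value)
        if key in keyed:
            raise ValueError(f"duplicate trial for subject/condition {key}")
        keyed[key] = t
    return [keyed[k] for k in sorted(keyed, key=lambda k: (k[0], k[1], order[k[2]]))]


def write_estimate(est: GrfEstimate, path, name: Optional[str] = None) -> Path:
    """Write an estimate as ``estimate_<source>.csv`` (t, f_ml_bw, f_ap_bw, f_v_bw)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    fname = name or f"estimate_{est.source.value}.csv"
    t = np.arange(est.n_samples) / est.rate_hz
    df = pd.DataFrame({"t": t, "f_ml_bw": est.values[:, 0],
                       "f_ap_bw": est.values[:, 1], "f_v_bw": est.values[:, 2]})
    _write_csv(path / fname, df)
    return path / fname


def read_estimate(path, source) -> GrfEstimate:
    df = pd.read_csv(path, float_precision="round_trip")
    vals = df[["f_ml_bw", "f_ap_bw", "f_v_bw"]].to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(df["t"]))) if len(df) > 1 else 240.0
    return GrfEstimate(vals, EstimateSource(source), round(rate, 6))


def group_by_subject(trials: List[Trial]) -> dict:
    out: dict = {}
    for t in trials:
        out.setdefault(t.subject.subject_id, []).append(t)
    return out
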