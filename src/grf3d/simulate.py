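"""Synthetic running-cohort simulator.

Generates physically consistent trials — 3D ground reaction force plus
three sensor free-acceleration streams — with the statistical structure
the estimation pipeline assumes:

* heel-strike vertical GRF per step: an impact bump (~12.5% stance) and an
  active bump (~45% stance), impulse-balanced so the stride-average
  vertical force equals body weight;
* anterior-posterior force: braking (negative) half-sine over the first
  40% of stance, then a propulsive (positive) half-sine;
* mediolateral force: a low-frequency half-sine of alternating sign per
  foot, small amplitude by design (poor ML observability is a feature of
  the real problem this mimics);
* sensor accelerations built by inverting the Newtonian vertical-GRF
  model (weights 0.55 pelvis / 0.23 per tibia), so that model is
  near-valid on the synthetic data; plus tibial impact transients, swing
  sway, subject-specific axis gains and white sensor noise;
* an unknown integer time offset between the force and sensor systems.

The generator emulates a treadmill protocol of 3 velocities × 3
stride-frequency conditions (preferred ± 10%) per subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import json
import numpy as np

from .io import trial_dirname, write_trial, _write_csv
from .types import (GRAVITY_MS2, ForceStream, SensorId, SensorStream,
                    SfCondition, SubjectInfo, Trial, TrialMeta)
from .preprocess import FilterSpec, butter_filter

import pandas as pd

# Inverse-model partition: pelvis carries the low-frequency share of the
# centre-of-mass acceleration, the tibias split the remainder.
WF_PELVIS = 0.55
WF_TIBIA = 0.23
_PELVIS_SPLIT = FilterSpec(order=2, cutoff_hz=6.0, bidirectional=True)


@dataclass
class GeneratorConfig:
    """Stated world of the synthetic cohort. Defaults mirror the emulated
    protocol: 12 subjects (73.7 ± 17.5 kg), 10/12/14 km/h × three
    stride-frequency conditions, 90 s trials at 240 Hz."""

    n_subjects: int = 12
    mass_mean_kg: float = 73.7
    mass_sd_kg: float = 17.5
    velocities_kmh: Sequence[float] = (10.0, 12.0, 14.0)
    sf_conditions: Sequence[str] = ("low", "preferred", "high")
    preferred_stride_hz_mean: float = 1.40
    preferred_stride_hz_sd: float = 0.07
    #: per-step timing jitter, sd as a fraction of the step period; real
    #: stride timing varies ~1-3% and this is what disambiguates the
    #: cross-correlation comb during synchronization
    step_jitter_frac: float = 0.02
    duty_factor: float = 0.35            # stance fraction of stride at 10 km/h
    duty_factor_slope_per_kmh: float = -0.015
    impact_peak_bw: float = 1.6
    active_peak_bw: float = 2.5          # at 10 km/h
    active_peak_slope_per_kmh: float = 0.05
    # stance-shape constants (fractions of stance unless noted)
    impact_peak_frac: float = 0.125
    impact_width_s: float = 0.025        # Gaussian sd of the impact bump
    active_peak_frac: float = 0.45
    active_width_frac: float = 0.18      # Gaussian sd of the active bump
    edge_rise_frac: float = 0.10         # cosine ramp at stance onset
    edge_fall_frac: float = 0.15         # cosine ramp at toe-off
    ap_peak_bw: float = 0.40
    ml_amp_bw: float = 0.12
    sensor_noise_sd_ms2: float = 0.5
    impact_transient_ms2: float = 15.0   # tibial heel-strike ringing, 20 Hz
    swing_amp_ms2: float = 0.5           # swing-leg sway on the tibias
    subject_gain_sd: float = 0.08
    offset_range_samples: Tuple[int, int] = (-240, 240)
    duration_s: float = 90.0
    sensor_rate_hz: float = 240.0
    force_rate_hz: float = 2048.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.duty_factor < 0.5):
            raise ValueError("duty_factor must be in (0, 0.5)")
        for name in ("preferred_stride_hz_mean", "sensor_rate_hz",
                     "force_rate_hz", "duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Per-trial simulation truth, for testing and evaluation only."""

    grf: np.ndarray                # (n, 3) newtons at sensor rate, (ML, AP, V)
    rate_hz: float
    foot_strikes: np.ndarray       # sample indices, alternating feet
    toe_offs: np.ndarray
    feet: np.ndarray               # 0 = left, 1 = right, per step
    offset_samples: int            # force system lags sensors by this many


def _stride_frequency(cfg: GeneratorConfig, preferred_hz: float,
                      cond: SfCondition) -> float:
    factor = {SfCondition.LOW: 0.9, SfCondition.PREFERRED: 1.0,
              SfCondition.HIGH: 1.1}[cond]
    return preferred_hz * factor


def _smooth_edge_window(s: np.ndarray, rise: float = 0.10,
                        fall: float = 0.15) -> np.ndarray:
    """Cosine-smooth ramp from 0 at both stance edges, 1 in between."""
    up = np.clip(s / rise, 0.0, 1.0)
    down = np.clip((1.0 - s) / fall, 0.0, 1.0)
    return np.sin(0.5 * np.pi * up) ** 2 * np.sin(0.5 * np.pi * down) ** 2


def generate_grf_waveform(meta: TrialMeta, subject: SubjectInfo,
                          rng: np.random.Generator,
                          cfg: Optional[GeneratorConfig] = None,
                          preferred_stride_hz: Optional[float] = None,
                          ) -> GroundTruth:
    """Simulate the true 3D GRF and step events for one trial.

    Vertical stance shape is a sum of two stance-limited Gaussian bumps
    (impact at 12.5% stance, ~25 ms width; active at 45% stance), rescaled
    per stride so the stride-average vertical force equals body weight.
    Flight samples are exactly zero on all axes.
    """
    cfg = cfg or GeneratorConfig()
    rate = cfg.sensor_rate_hz
    if preferred_stride_hz is None:
        preferred_stride_hz = cfg.preferred_stride_hz_mean
    f_stride = _stride_frequency(cfg, preferred_stride_hz, meta.sf_condition)
    stride_t = 1.0 / f_stride
    step_t = stride_t / 2.0
    duty = cfg.duty_factor + cfg.duty_factor_slope_per_kmh * (meta.velocity_kmh - 10.0)
    stance_t = duty * stride_t
    if stance_t < 0.06:
        raise ValueError(f"stance duration {stance_t:.3f} s too short for the "
                         "0.05 s labelling rule")
    if stance_t >= step_t:
        raise ValueError("duty factor leaves no flight phase")
    n = int(round(meta.duration_s * rate))
    t = np.arange(n) / rate
    bw = subject.bodyweight_n
    active_peak = (cfg.active_peak_bw
                   + cfg.active_peak_slope_per_kmh * (meta.velocity_kmh - 10.0))

    grf = np.zeros((n, 3))
    foot_strikes, toe_offs, feet = [], [], []
    t0 = 0.25 * step_t  # lead-in flight so the trial does not start mid-stance
    k = 0
    impact_sd_s = cfg.impact_width_s
    n_steps_max = int(np.ceil(meta.duration_s / step_t)) + 2
    jitter = (rng.normal(0.0, cfg.step_jitter_frac, size=n_steps_max) * step_t
              if cfg.step_jitter_frac > 0 else np.zeros(n_steps_max))
    while True:
        ts = t0 + k * step_t + jitter[k]
        te = ts + stance_t
        if te + 0.05 >= meta.duration_s:
            break
        i0, i1 = int(np.ceil(ts * rate)), int(np.ceil(te * rate))
        i1 = min(i1, n)
        if i1 <= i0:
            k += 1
            continue
        s = (t[i0:i1] - ts) / stance_t  # stance phase fraction in [0, 1)
        vert = (cfg.impact_peak_bw
                * np.exp(-0.5 * ((s - cfg.impact_peak_frac) * stance_t / impact_sd_s) ** 2)
                + active_peak * np.exp(-0.5 * ((s - cfg.active_peak_frac)
                                               / cfg.active_width_frac) ** 2))
        vert = vert * _smooth_edge_window(s, cfg.edge_rise_frac, cfg.edge_fall_frac)
        ap = np.where(
            s < 0.40,
            -cfg.ap_peak_bw * np.sin(np.pi * s / 0.40),
            cfg.ap_peak_bw * np.sin(np.pi * (s - 0.40) / 0.60),
        )
        foot = k % 2
        ml_sign = 1.0 if foot == 0 else -1.0
        ml = ml_sign * cfg.ml_amp_bw * np.sin(np.pi * s)
        grf[i0:i1, 0] = ml * bw
        grf[i0:i1, 1] = ap * bw
        grf[i0:i1, 2] = vert * bw
        foot_strikes.append(i0)
        toe_offs.append(i1)
        feet.append(foot)
        k += 1
    if len(foot_strikes) < 2:
        raise ValueError("trial too short: fewer than two steps generated")

    # impulse balance: stride-average vertical force must equal body weight.
    # One global amplitude rescale suffices because every stride is congruent.
    strides = len(foot_strikes) // 2
    a = foot_strikes[0]
    b = foot_strikes[2 * strides] if 2 * strides < len(foot_strikes) else toe_offs[-1]
    span_t = (b - a) / rate
    impulse = np.trapezoid(grf[a:b, 2], dx=1.0 / rate)
    grf[:, 2] *= bw * span_t / impulse

    offset_lo, offset_hi = cfg.offset_range_samples
    offset = int(rng.integers(offset_lo, offset_hi + 1))
    return GroundTruth(grf=grf, rate_hz=rate,
                       foot_strikes=np.array(foot_strikes, dtype=int),
                       toe_offs=np.array(toe_offs, dtype=int),
                       feet=np.array(feet, dtype=int), offset_samples=offset)


@dataclass
class SubjectGains:
    """Subject-specific multiplicative gains on the horizontal axis coupling
    between force (per unit mass) and each sensor's acceleration."""

    ap: np.ndarray  # (3,) one per sensor: pelvis, tibia_left, tibia_right
    ml: np.ndarray

    @classmethod
    def sample(cls, rng: np.random.Generator, sd: float) -> "SubjectGains":
        return cls(ap=rng.normal(1.0, sd, size=3), ml=rng.normal(1.0, sd, size=3))


def synthesize_sensor_streams(truth: GroundTruth, subject: SubjectInfo,
                              rng: np.random.Generator,
                              cfg: Optional[GeneratorConfig] = None,
                              gains: Optional[SubjectGains] = None,
                              ) -> Tuple[dict, ForceStream]:
    """Build the three sensor streams and the delayed 2048 Hz force stream.

    Vertical channels invert the Newtonian model: the pelvis carries the
    low-passed (2nd-order, 6 Hz) centre-of-mass acceleration and each tibia
    carries the residual scaled by 1/(2·0.23), so that
    0.55·a_pelvis + 0.23·(a_tibL + a_tibR) reproduces the centre-of-mass
    acceleration. The stance-side tibia additionally rings at 20 Hz after
    foot strike; both tibias sway at the stride frequency; horizontal
    channels couple to AP/ML force with subject-specific gains.
    """
    cfg = cfg or GeneratorConfig()
    if gains is None:
        gains = SubjectGains.sample(rng, cfg.subject_gain_sd)
    rate = truth.rate_hz
    n = truth.grf.shape[0]
    t = np.arange(n) / rate
    mb = subject.body_mass_kg
    a_com = truth.grf[:, 2] / mb - GRAVITY_MS2

    a_pelvis = butter_filter(a_com, _PELVIS_SPLIT, rate)
    resid = (a_com - WF_PELVIS * a_pelvis) / (2.0 * WF_TIBIA)
    tib = {0: resid.copy(), 1: resid.copy()}

    # heel-strike ringing on the striking tibia
    if cfg.impact_transient_ms2 > 0:
        dur = int(round(0.15 * rate))
        tau = 0.04
        for i0, foot in zip(truth.foot_strikes, truth.feet):
            j1 = min(n, i0 + dur)
            tt = (np.arange(j1 - i0)) / rate
            tib[foot][i0:j1] += (cfg.impact_transient_ms2
                                 * np.exp(-tt / tau) * np.sin(2 * np.pi * 20.0 * tt))
    # smooth low-amplitude swing sway, antiphase between legs
    if cfg.swing_amp_ms2 > 0 and len(truth.foot_strikes) >= 2:
        f_stride = rate / (2.0 * np.median(np.diff(truth.foot_strikes)))
        sway = cfg.swing_amp_ms2 * np.sin(2 * np.pi * f_stride * t)
        tib[0] += sway
        tib[1] -= sway

    ap_per_mass = truth.grf[:, 1] / mb
    ml_per_mass = truth.grf[:, 0] / mb
    order = [SensorId.PELVIS, SensorId.TIBIA_LEFT, SensorId.TIBIA_RIGHT]
    vert = {SensorId.PELVIS: a_pelvis, SensorId.TIBIA_LEFT: tib[0],
            SensorId.TIBIA_RIGHT: tib[1]}
    sensors = {}
    for j, sid in enumerate(order):
        acc = np.column_stack([
            gains.ap[j] * ap_per_mass,
            gains.ml[j] * ml_per_mass,
            vert[sid],
        ])
        if cfg.sensor_noise_sd_ms2 > 0:
            acc = acc + rng.normal(0.0, cfg.sensor_noise_sd_ms2, size=acc.shape)
        sensors[sid] = SensorStream(sid, acc, rate)

    # force system: native 2048 Hz clock, delayed by the true offset
    t_force = np.arange(0.0, t[-1], 1.0 / cfg.force_rate_hz)
    shift = truth.offset_samples / rate
    grf_hi = np.column_stack([
        np.interp(t_force - shift, t, truth.grf[:, j], left=0.0, right=0.0)
        for j in range(3)
    ])
    force = ForceStream(grf_hi, rate_hz=cfg.force_rate_hz)
    return sensors, force


def simulate_trial(meta: TrialMeta, subject: SubjectInfo,
                   rng: np.random.Generator,
                   cfg: Optional[GeneratorConfig] = None,
                   preferred_stride_hz: Optional[float] = None,
                   gains: Optional[SubjectGains] = None,
                   ) -> Tuple[Trial, GroundTruth]:
    """Generate one complete trial (sensors + delayed force) with its truth."""
    cfg = cfg or GeneratorConfig()
    truth = generate_grf_waveform(meta, subject, rng, cfg, preferred_stride_hz)
    sensors, force = synthesize_sensor_streams(truth, subject, rng, cfg, gains)
    return Trial(subject, meta, sensors, force), truth


def sample_subjects(cfg: GeneratorConfig,
                    rng: np.random.Generator) -> List[SubjectInfo]:
    """Draw subject masses ~ N(mass_mean, mass_sd) truncated to (40, 120) kg."""
    subjects = []
    for i in range(cfg.n_subjects):
        while True:
            m = rng.normal(cfg.mass_mean_kg, cfg.mass_sd_kg)
            if 40.0 < m < 120.0:
                break
        subjects.append(SubjectInfo(f"S{i + 1:02d}", float(m)))
    return subjects


def simulate_cohort(cfg: GeneratorConfig) -> List[Tuple[Trial, GroundTruth]]:
    """Generate the full cohort in memory, deterministically from cfg.seed.

    One master seed fans out per subject and per trial, so any subset of
    trials is reproducible independent of generation order.
    """
    master = np.random.SeedSequence(cfg.seed)
    subj_seeds = master.spawn(cfg.n_subjects)
    subject_rng = np.random.default_rng(master.spawn(1)[0])
    subjects = sample_subjects(cfg, subject_rng)
    out = []
    for subj, sseq in zip(subjects, subj_seeds):
        srng = np.random.default_rng(sseq)
        preferred = float(np.clip(
            srng.normal(cfg.preferred_stride_hz_mean, cfg.preferred_stride_hz_sd),
            1.0, 1.8))
        gains = SubjectGains.sample(srng, cfg.subject_gain_sd)
        trial_seqs = sseq.spawn(len(cfg.velocities_kmh) * len(cfg.sf_conditions))
        i = 0
        for v in cfg.velocities_kmh:
            for cond in cfg.sf_conditions:
                rng = np.random.default_rng(trial_seqs[i])
                i += 1
                meta = TrialMeta(float(v), SfCondition(cond), cfg.duration_s)
                out.append(simulate_trial(meta, subj, rng, cfg,
                                          preferred_stride_hz=preferred,
                                          gains=gains))
    return out


def generate_cohort(cfg: GeneratorConfig, out_dir) -> List[Path]:
    """Generate the cohort and write it to disk with ground-truth sidecars.

    Truth files (``truth.json``, ``truth_grf.csv``) exist for testing and
    evaluation only; the estimation pipeline never reads them.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for trial, truth in simulate_cohort(cfg):
        tdir = out_dir / trial_dirname(trial)
        write_trial(trial, tdir)
        tt = np.arange(truth.grf.shape[0]) / truth.rate_hz
        _write_csv(tdir / "truth_grf.csv",
                   pd.DataFrame({"t": tt, "f_ml": truth.grf[:, 0],
                                 "f_ap": truth.grf[:, 1], "f_v": truth.grf[:, 2]}))
        (tdir / "truth.json").write_text(json.dumps({
            "offset_samples": truth.offset_samples,
            "foot_strikes": truth.foot_strikes.tolist(),
            "toe_offs": truth.toe_offs.tolist(),
            "feet": truth.feet.tolist(),
            "rate_hz": truth.rate_hz,
        }, sort_keys=True) + "\n")
        paths.append(tdir)
    return paths


def read_truth(trial_dir) -> GroundTruth:
    """Load the ground-truth sidecar written by :func:`generate_cohort`."""
    trial_dir = Path(trial_dir)
    meta = json.loads((trial_dir / "truth.json").read_text())
    df = pd.read_csv(trial_dir / "truth_grf.csv")
    grf = df[["f_ml", "f_ap", "f_v"]].to_numpy(dtype=float)
    return GroundTruth(grf=grf, rate_hz=float(meta["rate_hz"]),
                       foot_strikes=np.array(meta["foot_strikes"], dtype=int),
                       toe_offs=np.array(meta["toe_offs"], dtype=int),
                       feet=np.array(meta["feet"], dtype=int),
                       offset_samples=int(meta["offset_samples"]))
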