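"""Signal conditioning, synchronization and stride segmentation.

The measured force is low-pass filtered (6th-order zero-phase Butterworth,
30 Hz) at its native rate, downsampled onto the sensor clock, aligned to
the IMUs by cross-correlating the summed tibia vertical free acceleration
with the vertical GRF, segmented into stance/flight phases with the
25 N / 0.05 s threshold rule, and finally cut to a 40-stride window from
the middle of the trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy import signal as sps

from .types import ForceStream, GaitEvents, SensorId, Trial

#: Vertical-force threshold separating ground contact from flight, newtons.
CONTACT_THRESHOLD_N = 25.0
#: Minimum duration a phase must exceed to be labelled, seconds.
MIN_PHASE_S = 0.05


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass specification.

    ``bidirectional`` selects forward+backward (zero-phase) filtering, whose
    effective attenuation is the single-pass magnitude squared.
    """

    order: int
    cutoff_hz: float
    bidirectional: bool = True


# Filters named throughout the pipeline.
FORCE_FILTER = FilterSpec(order=6, cutoff_hz=30.0, bidirectional=True)
ANN_INPUT_FILTER = FilterSpec(order=3, cutoff_hz=10.0, bidirectional=True)


class AmbiguousSyncWarning(UserWarning):
    """Cross-correlation peak was not unique within 1%."""


def butter_filter(x: np.ndarray, spec: FilterSpec, rate_hz: float) -> np.ndarray:
    """Apply a Butterworth low-pass along the first axis of ``x``."""
    x = np.asarray(x, dtype=float)
    if spec.cutoff_hz >= rate_hz / 2:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz >= Nyquist ({rate_hz / 2} Hz)")
    if x.shape[0] <= 3 * spec.order:
        raise ValueError(f"signal too short to filter: {x.shape[0]} <= {3 * spec.order}")
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=rate_hz, output="sos")
    if spec.bidirectional:
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


def resample_force(force: ForceStream, target_hz: float) -> ForceStream:
    """Downsample a (pre-filtered) force stream onto the sensor clock.

    Linear interpolation onto target timestamps; anti-aliasing is assumed
    to have been provided by the 30 Hz low-pass. Upsampling is unsupported.
    """
    if target_hz >= force.rate_hz:
        raise ValueError(f"target rate {target_hz} >= source rate {force.rate_hz}: "
                         "upsampling unsupported")
    t_src = np.arange(force.n_samples) / force.rate_hz
    t_dst = np.arange(0.0, t_src[-1] + 0.5 / force.rate_hz, 1.0 / target_hz)
    t_dst = t_dst[t_dst <= t_src[-1]]
    out = np.column_stack([np.interp(t_dst, t_src, force.grf[:, j]) for j in range(3)])
    return ForceStream(out, rate_hz=target_hz)


def filter_and_resample_force(force: ForceStream, target_hz: float,
                              spec: FilterSpec = FORCE_FILTER) -> ForceStream:
    filtered = ForceStream(butter_filter(force.grf, spec, force.rate_hz), force.rate_hz)
    return resample_force(filtered, target_hz)


def estimate_offset(acc_sum: np.ndarray, vgrf: np.ndarray, max_lag: int) -> int:
    """Lag (samples) by which ``vgrf`` trails ``acc_sum``, from normalized
    cross-correlation over lags in ±``max_lag``. Ties within 1% of the peak
    resolve to the smallest |lag|; a non-unique peak raises
    :class:`AmbiguousSyncWarning`.
    """
    a = acc_sum - acc_sum.mean()
    f = vgrf - vgrf.mean()
    n = min(len(a), len(f))
    a, f = a[:n], f[:n]
    denom = np.sqrt((a ** 2).sum() * (f ** 2).sum())
    if denom == 0:
        warnings.warn("flat signal: synchronization is ambiguous", AmbiguousSyncWarning)
        return 0
    full = sps.correlate(f, a, mode="full") / denom  # index n-1+k <-> lag k
    lags = np.arange(-max_lag, max_lag + 1)
    cc = full[n - 1 + lags]
    peak = cc.max()
    if peak < 0.2:
        # essentially flat correlation: no real alignment information
        warnings.warn(f"cross-correlation peak is weak ({peak:.3f}): "
                      "synchronization is ambiguous", AmbiguousSyncWarning)
    near = lags[cc >= peak - 0.01 * abs(peak)]
    if len(near) > 1 and (np.diff(np.sort(near)) > 1).any():
        # genuinely ambiguous (non-contiguous near-peak lags): tie-break
        # towards the smallest |lag|
        warnings.warn("cross-correlation peak not unique within 1%; "
                      "taking smallest |lag|", AmbiguousSyncWarning)
        best = int(near[np.argmin(np.abs(near))])
    else:
        best = int(lags[int(np.argmax(cc))])
    # parabolic refinement of the discrete peak, rounded back to an integer
    # lag; debiases the argmax when the two waveforms differ in shape
    i = best + max_lag
    if 0 < i < len(cc) - 1:
        denom = cc[i - 1] - 2 * cc[i] + cc[i + 1]
        if denom < 0:
            frac = 0.5 * (cc[i - 1] - cc[i + 1]) / denom
            if abs(frac) < 1:
                best = int(round(best + frac))
    return best


def synchronize(trial: Trial, max_lag_s: float = 1.25) -> Tuple[Trial, int]:
    """Remove the inter-system time offset from a trial.

    The force must already be on the sensor clock. Returns the aligned trial
    and the estimated offset in samples (positive = force was lagging).
    """
    if trial.force is None:
        raise ValueError("trial has no force stream to synchronize")
    if trial.force.rate_hz != trial.rate_hz:
        raise ValueError("force must be resampled to the sensor rate before sync")
    rate = trial.rate_hz
    max_lag = int(round(max_lag_s * rate))
    if trial.n_samples < 2 * max_lag:
        raise ValueError("signals shorter than twice the maximum lag")
    acc_sum = (trial.sensor(SensorId.TIBIA_LEFT).vertical
               + trial.sensor(SensorId.TIBIA_RIGHT).vertical)
    offset = estimate_offset(acc_sum, trial.force.vertical, max_lag)
    n = trial.n_samples
    nf = trial.force.n_samples
    if offset >= 0:
        grf = trial.force.grf[offset:]
        sensors = {k: v for k, v in trial.sensors.items()}
        m = min(n, grf.shape[0])
    else:
        grf = np.vstack([np.repeat(trial.force.grf[:1], -offset, axis=0),
                         trial.force.grf])[: nf]
        sensors = trial.sensors
        m = min(n, grf.shape[0])
    new_sensors = {}
    for sid, s in sensors.items():
        new_sensors[sid] = replace(s, acc=s.acc[:m])
    aligned = Trial(trial.subject, trial.meta, new_sensors,
                    ForceStream(grf[:m], rate), None, None)
    return aligned, offset


def detect_gait_events(vgrf: np.ndarray, rate_hz: float) -> GaitEvents:
    """Label stance/flight phases of a vertical GRF series (newtons).

    A phase is stance where the force exceeds 25 N and flight where it is
    below, but only runs strictly longer than 0.05 s are labelled; shorter
    runs (spikes, dropouts) are absorbed into the enclosing phase.
    """
    v = np.asarray(vgrf, dtype=float)
    n = len(v)
    if n == 0 or not (v > CONTACT_THRESHOLD_N).any():
        raise ValueError("no stance phase found (vertical GRF never exceeds 25 N)")
    above = v > CONTACT_THRESHOLD_N
    # run-length encode, then iteratively merge too-short interior runs
    min_len = MIN_PHASE_S * rate_hz  # strictly-greater rule: need len/rate > 0.05
    runs = []  # (label, start, end)
    start = 0
    for i in range(1, n + 1):
        if i == n or above[i] != above[start]:
            runs.append([bool(above[start]), start, i])
            start = i
    changed = True
    while changed and len(runs) > 1:
        changed = False
        # merge the shortest offending interior run first
        lengths = [(r[2] - r[1], i) for i, r in enumerate(runs)
                   if r[2] - r[1] <= min_len and 0 < i < len(runs) - 1]
        if lengths:
            _, i = min(lengths)
            runs[i][0] = runs[i - 1][0]
            merged = []
            for r in runs:
                if merged and merged[-1][0] == r[0]:
                    merged[-1][2] = r[2]
                else:
                    merged.append(r)
            runs = merged
            changed = True
    # short runs at the trial edges have a single neighbour to absorb them
    if len(runs) > 1 and runs[0][2] - runs[0][1] <= min_len:
        runs[1][1] = runs[0][1]
        runs = runs[1:]
    if len(runs) > 1 and runs[-1][2] - runs[-1][1] <= min_len:
        runs[-2][2] = runs[-1][2]
        runs = runs[:-1]
    intervals = [("stance" if lab else "flight", a, b) for lab, a, b in runs]
    if not any(lab == "stance" for lab, _, _ in intervals):
        raise ValueError("no stance phase found after labelling")
    return GaitEvents(intervals=intervals, rate_hz=rate_hz, n_samples=n)


def select_stride_window(trial: Trial, events: GaitEvents,
                         n_strides: int = 40) -> Trial:
    """Attach a window of exactly ``n_strides`` strides centred mid-trial.

    A stride is two consecutive steps (stance onset to the second-next
    stance onset); the window snaps to stance onsets.
    """
    onsets = events.stance_onsets()
    n_steps = len(onsets) - 1
    n_avail = n_steps // 2
    if n_avail < n_strides:
        raise ValueError(f"only {n_avail} strides available < {n_strides} requested")
    center_step = n_steps / 2.0
    start_step = int(round(center_step - n_strides))
    start_step = max(0, min(start_step, n_steps - 2 * n_strides))
    window = (int(onsets[start_step]), int(onsets[start_step + 2 * n_strides]))
    return Trial(trial.subject, trial.meta, trial.sensors, trial.force,
                 events.stance_mask(), window)


def preprocess_trial(trial: Trial, n_strides: int = 40, sync: bool = True,
                     max_lag_s: float = 1.25) -> Tuple[Trial, dict]:
    """Full conditioning chain for one trial with measured force.

    Filters + downsamples the force, synchronizes (optional), labels gait
    events, and selects the stride window. Returns the processed trial and
    an info dict (estimated offset, stride count).
    """
    if trial.force is None:
        raise ValueError("preprocessing requires a measured force stream")
    force = trial.force
    if force.rate_hz != trial.rate_hz:
        force = filter_and_resample_force(force, trial.rate_hz)
    staged = Trial(trial.subject, trial.meta, trial.sensors,
                   ForceStream(force.grf[: trial.n_samples], trial.rate_hz))
    offset = 0
    if sync:
        staged, offset = synchronize(staged, max_lag_s=max_lag_s)
    events = detect_gait_events(staged.force.vertical, staged.rate_hz)
    out = select_stride_window(staged, events, n_strides=n_strides)
    info = {"offset_samples": offset,
            "n_strides_available": (len(events.stance_onsets()) - 1) // 2,
            "events": events}
    return out, info
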