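"""Newtonian vertical-GRF estimator from pelvis and tibia accelerations.

Per sample::

    eGRF [N] = m_b·g + m_b·(WF_p·ã_z,pelvis + WF_t·ã_z,tibL + WF_t·ã_z,tibR)

where the ã are per-sensor low-pass-filtered vertical free accelerations
(pelvis: 2nd-order 5.97 Hz; tibias: 1st-order 8.74 Hz; all zero-phase) and
the weight factors are fixed at 0.55 (pelvis) and 0.23 (each tibia). The
estimate is returned in bodyweights, is exactly linear in body mass in
newtons, and is mass-invariant in BW. There is no physical model for the
ML/AP axes, so those columns are marked unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import FilterSpec, butter_filter
from .types import (GRAVITY_MS2, EstimateSource, GrfEstimate, SensorId, Trial)


@dataclass(frozen=True)
class PhysicalParams:
    wf_pelvis: float = 0.55
    wf_tibia: float = 0.23  # applied to each tibia
    pelvis_filter: FilterSpec = FilterSpec(order=2, cutoff_hz=5.97, bidirectional=True)
    tibia_filter: FilterSpec = FilterSpec(order=1, cutoff_hz=8.74, bidirectional=True)
    g: float = GRAVITY_MS2

    def __post_init__(self) -> None:
        if self.wf_pelvis < 0 or self.wf_tibia < 0:
            raise ValueError("weight factors must be non-negative")


def estimate_vertical_grf(trial: Trial,
                          params: PhysicalParams = PhysicalParams()) -> GrfEstimate:
    """Estimate vertical GRF in BW for every sample of the trial.

    Filtering is applied to the full continuous trial (not per stride) to
    avoid per-window edge artefacts. No non-negativity clipping is applied.
    """
    for sid in SensorId:
        if sid not in trial.sensors:
            raise ValueError(f"missing sensor: {sid.value}")
    rate = trial.rate_hz
    az_p = butter_filter(trial.sensor(SensorId.PELVIS).vertical,
                         params.pelvis_filter, rate)
    az_l = butter_filter(trial.sensor(SensorId.TIBIA_LEFT).vertical,
                         params.tibia_filter, rate)
    az_r = butter_filter(trial.sensor(SensorId.TIBIA_RIGHT).vertical,
                         params.tibia_filter, rate)
    # eGRF in BW = 1 + Σ WF_i · ã_z,i / g  (mass cancels)
    vertical_bw = 1.0 + (params.wf_pelvis * az_p
                         + params.wf_tibia * (az_l + az_r)) / params.g
    values = np.column_stack([np.full_like(vertical_bw, np.nan),
                              np.full_like(vertical_bw, np.nan),
                              vertical_bw])
    return GrfEstimate(values, EstimateSource.PHYSICAL, rate_hz=rate)
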