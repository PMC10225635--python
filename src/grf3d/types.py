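"""Shared domain types, units and axis conventions.

Conventions used throughout the package:

* Sensor acceleration is gravity-free ("free") acceleration in a
  gravity-aligned global frame, in m/s², with column order
  ``(ax, ay, az) = (anterior-posterior, mediolateral, vertical)``,
  vertical positive up, anterior positive forward.
* Ground reaction force (GRF) uses column order
  ``(ML, AP, vertical)`` — in newtons for measured force streams and in
  bodyweights (BW, i.e. force / (m_b · g)) for estimates.
* Sample intervals are half-open and 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple

import numpy as np

#: Gravitational acceleration used for all BW conversions, m/s².
GRAVITY_MS2: float = 9.81

#: Canonical GRF axis order for force arrays and estimates.
GRF_AXES: Tuple[str, str, str] = ("ml", "ap", "vertical")

#: Canonical sensor-acceleration axis order.
ACC_AXES: Tuple[str, str, str] = ("ap", "ml", "vertical")


class SensorId(str, Enum):
    PELVIS = "pelvis"
    TIBIA_LEFT = "tibia_left"
    TIBIA_RIGHT = "tibia_right"


class SfCondition(str, Enum):
    """Stride-frequency condition: preferred, or preferred ∓/± 10%."""

    LOW = "low"
    PREFERRED = "preferred"
    HIGH = "high"


class EstimateSource(str, Enum):
    PHYSICAL = "physical"
    DIRECT = "direct"
    HYBRID = "hybrid"
    ENSEMBLE = "ensemble"


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr).all(axis=-1) if arr.ndim > 1
                                 else ~np.isfinite(arr))[0])
        raise ValueError(f"{name} contains non-finite values (first bad row {bad})")


@dataclass
class SensorStream:
    """One sensor's 3D free-acceleration time series.

    ``acc`` has shape (n_samples, 3) with axes (AP, ML, vertical), m/s².
    """

    sensor_id: SensorId
    acc: np.ndarray
    rate_hz: float = 240.0

    def __post_init__(self) -> None:
        self.sensor_id = SensorId(self.sensor_id)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError(f"acc must be (n, 3), got {self.acc.shape}")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        _check_finite(self.acc, f"{self.sensor_id.value} acceleration")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def vertical(self) -> np.ndarray:
        return self.acc[:, 2]


@dataclass
class ForceStream:
    """Treadmill 3D GRF time series, axes (ML, AP, vertical), newtons."""

    grf: np.ndarray
    rate_hz: float = 2048.0

    def __post_init__(self) -> None:
        self.grf = np.asarray(self.grf, dtype=float)
        if self.grf.ndim != 2 or self.grf.shape[1] != 3:
            raise ValueError(f"grf must be (n, 3), got {self.grf.shape}")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        _check_finite(self.grf, "force")

    @property
    def n_samples(self) -> int:
        return self.grf.shape[0]

    @property
    def vertical(self) -> np.ndarray:
        return self.grf[:, 2]


@dataclass
class SubjectInfo:
    subject_id: str
    body_mass_kg: float

    def __post_init__(self) -> None:
        if not (20.0 < self.body_mass_kg < 200.0):
            raise ValueError(
                f"body_mass_kg={self.body_mass_kg} outside plausible range (20, 200)"
            )

    @property
    def bodyweight_n(self) -> float:
        """Body weight m_b · g in newtons."""
        return self.body_mass_kg * GRAVITY_MS2


@dataclass
class TrialMeta:
    velocity_kmh: float
    sf_condition: SfCondition
    duration_s: float = 90.0

    def __post_init__(self) -> None:
        self.sf_condition = SfCondition(self.sf_condition)
        if self.velocity_kmh not in (10.0, 12.0, 14.0):
            raise ValueError(f"velocity_kmh must be one of 10/12/14, got {self.velocity_kmh}")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")

    @property
    def condition_key(self) -> Tuple[float, str]:
        return (self.velocity_kmh, self.sf_condition.value)


@dataclass
class Trial:
    """A subject's recording for one (velocity, stride-frequency) condition.

    After synchronization all present streams share rate and length; the
    stance mask and the 40-stride window are attached by preprocessing.
    """

    subject: SubjectInfo
    meta: TrialMeta
    sensors: dict  # SensorId -> SensorStream, exactly the three locations
    force: Optional[ForceStream] = None
    stance_mask: Optional[np.ndarray] = None
    stride_window: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.sensors = {SensorId(k): v for k, v in self.sensors.items()}
        missing = [s.value for s in SensorId if s not in self.sensors]
        if missing:
            raise ValueError(f"trial is missing sensor stream(s): {missing}")
        rates = {s.rate_hz for s in self.sensors.values()}
        lengths = {s.n_samples for s in self.sensors.values()}
        if len(rates) != 1 or len(lengths) != 1:
            raise ValueError("sensor streams disagree on rate or length")
        if self.stance_mask is not None:
            self.stance_mask = np.asarray(self.stance_mask, dtype=bool)
            if self.stance_mask.shape[0] != self.n_samples:
                raise ValueError("stance_mask length does not match sample count")

    @property
    def rate_hz(self) -> float:
        return next(iter(self.sensors.values())).rate_hz

    @property
    def n_samples(self) -> int:
        return next(iter(self.sensors.values())).n_samples

    def sensor(self, sensor_id) -> SensorStream:
        return self.sensors[SensorId(sensor_id)]

    @property
    def is_synchronized(self) -> bool:
        return (self.force is not None
                and self.force.rate_hz == self.rate_hz
                and self.force.n_samples == self.n_samples)


@dataclass
class GrfEstimate:
    """Per-sample 3-axis estimated GRF in bodyweights.

    The physical model only estimates the vertical axis; its ML/AP columns
    are NaN and flagged unavailable.
    """

    values: np.ndarray
    source: EstimateSource
    rate_hz: float = 240.0

    def __post_init__(self) -> None:
        self.source = EstimateSource(self.source)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError(f"values must be (n, 3), got {self.values.shape}")
        if self.source is EstimateSource.PHYSICAL:
            if not np.all(np.isnan(self.values[:, :2])):
                raise ValueError("physical estimates must leave ML/AP unavailable (NaN)")
            _check_finite(self.values[:, 2], "physical vertical estimate")
        else:
            _check_finite(self.values, "estimate")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def vertical(self) -> np.ndarray:
        return self.values[:, 2]

    def axis_available(self, axis: int) -> bool:
        return not np.all(np.isnan(self.values[:, axis]))


@dataclass
class GaitEvents:
    """Alternating stance/flight intervals from the 25 N / 0.05 s rule.

    ``intervals`` is a list of ("stance" | "flight", start, end) with
    half-open 0-based sample indices, ordered and non-overlapping.
    """

    intervals: list
    rate_hz: float
    n_samples: int

    def stance_intervals(self):
        return [(a, b) for lab, a, b in self.intervals if lab == "stance"]

    def flight_intervals(self):
        return [(a, b) for lab, a, b in self.intervals if lab == "flight"]

    def stance_onsets(self) -> np.ndarray:
        return np.array([a for a, _ in self.stance_intervals()], dtype=int)

    def stance_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_samples, dtype=bool)
        for a, b in self.stance_intervals():
            mask[a:b] = True
        return mask
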