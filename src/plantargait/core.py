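"""Shared domain types for the plantar-pressure gait pipeline.

The in-shoe measurement system carries 8 pressure sensors per foot sampled
at 20 Hz.  Sensors 1-4 sit under the forefoot (2 medial, 4 lateral metatarsal
heads), 5-6 under the midfoot, and 7-8 under the heel (7 medial, 8 lateral).
All downstream modules share the container types defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Fixed sampling rate of the insole system (Hz).
SAMPLING_RATE = 20.0
#: Sampling interval (s).
DT = 1.0 / SAMPLING_RATE

#: Sensor ids (1-based) per anatomical region.
FOREFOOT_SENSORS = (1, 2, 3, 4)
MIDFOOT_SENSORS = (5, 6)
HEEL_SENSORS = (7, 8)
REGIONS = {
    "forefoot": FOREFOOT_SENSORS,
    "midfoot": MIDFOOT_SENSORS,
    "heel": HEEL_SENSORS,
}


class ConfigurationError(ValueError):
    """Invalid generator / pipeline configuration."""


class ValidationError(ValueError):
    """Invalid input data (shapes, units, weights...)."""


class SegmentationError(RuntimeError):
    """Gait-cycle segmentation failed."""


class NoGaitDetectedError(SegmentationError):
    """The total pressure curve never crosses the detection threshold."""


class InsufficientCyclesError(SegmentationError):
    """Fewer valid cycles than the analysis window requires."""


@dataclass(frozen=True)
class SensorLayout:
    """Geometry of the 8 sensors of one foot.

    ``coords_mm`` holds (x, y) positions in millimetres, x medial->lateral,
    y posterior->anterior, ordered by sensor id 1..8.  Coordinates are pooled
    across shoe sizes by normalizing x by ``foot_width`` and y by
    ``foot_length``, giving unit-square positions.
    """

    coords_mm: np.ndarray
    foot_length: float = 250.0
    foot_width: float = 95.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords_mm, dtype=float)
        if coords.shape != (8, 2):
            raise ValidationError(f"expected 8 sensor coordinates, got shape {coords.shape}")
        if self.foot_length <= 0 or self.foot_width <= 0:
            raise ValidationError("foot dimensions must be positive")
        object.__setattr__(self, "coords_mm", coords)
        norm = self.normalized_coords
        if np.any(norm < -1e-9) or np.any(norm > 1 + 1e-9):
            raise ValidationError("normalized sensor coordinates must lie in [0,1]x[0,1]")

    @property
    def normalized_coords(self) -> np.ndarray:
        """(8, 2) coordinates scaled to the unit square."""
        out = self.coords_mm.copy()
        out[:, 0] /= self.foot_width
        out[:, 1] /= self.foot_length
        return out


def default_layout() -> SensorLayout:
    """Representative insole layout (250 mm x 95 mm shoe)."""
    coords = np.array(
        [
            [45.0, 230.0],   # 1: hallux
            [25.0, 185.0],   # 2: medial forefoot (MTH1-2)
            [50.0, 190.0],   # 3: central forefoot
            [75.0, 180.0],   # 4: lateral forefoot (MTH4-5)
            [35.0, 115.0],   # 5: medial midfoot
            [65.0, 110.0],   # 6: lateral midfoot
            [35.0, 35.0],    # 7: medial heel
            [62.0, 30.0],    # 8: lateral heel
        ]
    )
    return SensorLayout(coords_mm=coords)


@dataclass
class PressureRecording:
    """Synchronized bilateral 8-channel pressure time series.

    ``left`` and ``right`` are (T, 8) matrices; units are raw sensor units
    (kg-force) until :func:`plantargait.segmentation.normalize_by_weight`
    converts them to fractions of body weight.
    """

    participant_id: str
    left: np.ndarray
    right: np.ndarray
    body_weight: float
    layout: SensorLayout
    sampling_rate: float = SAMPLING_RATE
    #: generator-only ground truth: {"left": [...], "right": [...]} landmark dicts
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.ndim != 2 or self.left.shape[1] != 8:
            raise ValidationError(f"left matrix must be (T, 8), got {self.left.shape}")
        if self.right.shape != self.left.shape:
            raise ValidationError("left and right matrices must have equal shape")
        if self.left.shape[0] < 3:
            raise ValidationError("recording must have at least 3 samples")
        if np.any(self.left < 0) or np.any(self.right < 0):
            raise ValidationError("pressures must be nonnegative")

    def foot(self, side: str) -> np.ndarray:
        if side not in ("left", "right"):
            raise ValidationError(f"invalid foot selector {side!r}")
        return self.left if side == "left" else self.right


@dataclass
class GaitCycle:
    """Landmark indices of one gait cycle (0-based, half-open [start, end)).

    ``heel_strike`` is the rise of the total vertical ground reaction force
    (VGRF) above the detection threshold; ``peak1``/``peak2`` the two force
    peaks of the bimodal stance; ``valley`` the minimum between them;
    ``toe_off`` the drop below threshold; ``cycle_end`` the next heel strike.
    ``channels`` optionally holds the (cycle length, 8) %BW slice.
    """

    foot: str
    heel_strike: int
    peak1: int
    valley: int
    peak2: int
    toe_off: int
    cycle_end: int
    channels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (
            self.heel_strike < self.peak1 <= self.valley <= self.peak2
            < self.toe_off <= self.cycle_end
        ):
            raise ValidationError(
                "landmark ordering violated: "
                f"hs={self.heel_strike} p1={self.peak1} v={self.valley} "
                f"p2={self.peak2} to={self.toe_off} end={self.cycle_end}"
            )

    @property
    def n_samples(self) -> int:
        return self.cycle_end - self.heel_strike

    def rel(self, index: int) -> int:
        """Convert an absolute sample index to a cycle-relative one."""
        return index - self.heel_strike


@dataclass
class CycleWindow:
    """The analysis window: 50 left/right-adjacent gait-cycle pairs."""

    left: list
    right: list
    threshold: float = field(default=0.0)

    def __post_init__(self) -> None:
        if len(self.left) != 50 or len(self.right) != 50:
            raise ValidationError(
                f"window must contain exactly 50 cycles per foot, "
                f"got {len(self.left)}/{len(self.right)}"
            )

    @property
    def pairs(self):
        return list(zip(self.left, self.right))
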