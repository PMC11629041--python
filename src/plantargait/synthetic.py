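"""Synthetic bilateral plantar-pressure recordings with known ground truth.

Real walking produces, per foot and gait cycle, a bimodal total vertical
ground reaction force (VGRF): a first peak at weight acceptance after heel
strike, a mid-stance valley, and a second peak at push-off, followed by a
swing phase with no load.  The generator emulates that structure so every
downstream stage (segmentation, feature extraction, selection, modelling)
can be tested against planted parameters:

* the *total* per-foot curve is a monotone (PCHIP) interpolation through the
  planted control points (heel strike 0, peak1, valley, peak2, toe-off 0),
  so peak and valley amplitudes are reproduced exactly at sample instants;
* the total is distributed over the 8 sensors with smooth region weights
  (heel early, midfoot mid-stance, forefoot late), preserving the total;
* the right foot is phase-shifted by half a cycle, so single- and
  double-limb support intervals exist whenever stance occupies more than
  half the cycle;
* cycle-to-cycle variability is a per-cycle random scaling of durations and
  amplitudes, shared between feet so that left/right asymmetry is controlled
  solely by ``left_right_asymmetry``.

Cohort generation couples two functional-test completion times (40 m
fast-paced walk test and timed up-and-go test, both in seconds) to the
planted gait parameters through a linear model with Gaussian noise, and
returns the planted parameters for recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .core import (
    DT,
    ConfigurationError,
    PressureRecording,
    SensorLayout,
    default_layout,
)

__all__ = [
    "WaveformParams",
    "LabelModel",
    "CohortSpec",
    "generate_recording",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

#: Default per-sensor amplitude shares within each region (sum to 1 each).
DEFAULT_REGION_SHARES: Dict[str, Tuple[float, ...]] = {
    "forefoot": (0.20, 0.30, 0.28, 0.22),
    "midfoot": (0.55, 0.45),
    "heel": (0.52, 0.48),
}


@dataclass(frozen=True)
class WaveformParams:
    """Planted parameters of one participant's gait waveform.

    Time fractions are fractions of the gait cycle; amplitudes are fractions
    of body weight (a typical adult walk peaks near 1.1 x body weight with a
    mid-stance valley near 0.75).
    """

    cycle_duration: float = 1.05          # s
    stance_fraction: float = 0.62
    peak1_time_fraction: float = 0.15
    peak2_time_fraction: float = 0.48
    peak1_amp: float = 1.10               # fraction of body weight
    peak2_amp: float = 1.05
    valley_amp: float = 0.75
    region_shares: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_SHARES)
    )
    cycle_jitter_sd: float = 0.02         # fractional, per-cycle
    left_right_asymmetry: float = 0.0     # fractional amplitude/timing offset
    n_cycles: int = 60
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.stance_fraction < 1:
            raise ConfigurationError("stance_fraction must lie in (0, 1)")
        if not (0 < self.peak1_time_fraction < self.peak2_time_fraction
                < self.stance_fraction):
            raise ConfigurationError(
                "require 0 < peak1_time_fraction < peak2_time_fraction < stance_fraction"
            )
        if min(self.peak1_amp, self.peak2_amp) <= 0:
            raise ConfigurationError("peak amplitudes must be positive")
        if not 0 <= self.valley_amp < min(self.peak1_amp, self.peak2_amp):
            raise ConfigurationError("valley_amp must be below both peak amplitudes")
        if self.cycle_jitter_sd < 0:
            raise ConfigurationError("cycle_jitter_sd must be >= 0")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        shares = self.region_shares
        if set(shares) != {"forefoot", "midfoot", "heel"}:
            raise ConfigurationError("region_shares must cover forefoot/midfoot/heel")
        lengths = {"forefoot": 4, "midfoot": 2, "heel": 2}
        for region, vals in shares.items():
            if len(vals) != lengths[region]:
                raise ConfigurationError(f"{region} share vector has wrong length")
            if min(vals) < 0 or abs(sum(vals) - 1.0) > 1e-9:
                raise ConfigurationError(f"{region} shares must be >= 0 and sum to 1")


# ---------------------------------------------------------------------------
# Single-recording generation
# ---------------------------------------------------------------------------

def _cycle_matrix(
    n: int,
    stance_n: int,
    i1: int,
    i2: int,
    amps: Tuple[float, float, float],
    shares: Dict[str, Tuple[float, ...]],
) -> Tuple[np.ndarray, Dict[str, int]]:
    """Build one cycle's (n, 8) %BW matrix plus its relative landmarks."""
    a1, a2, av = amps
    imid = (i1 + i2) // 2
    # Monotone interpolation through the planted landmarks: the sampled total
    # hits the peak/valley amplitudes exactly and is bimodal in between.
    nodes_x = np.array([0, i1, imid, i2, stance_n], dtype=float)
    nodes_y = np.array([0.0, a1, av, a2, 0.0])
    total = np.zeros(n)
    k = np.arange(stance_n + 1 if stance_n < n else n, dtype=float)
    total[: k.size] = PchipInterpolator(nodes_x, nodes_y)(k)
    total = np.clip(total, 0.0, None)

    # Smooth region weighting: heel loaded around peak1, forefoot around
    # peak2, midfoot bridging the valley.
    ks = np.arange(n, dtype=float)
    sig = max(1.5, 0.30 * stance_n)
    sig_mid = max(1.0, 0.18 * stance_n)
    w_heel = np.exp(-0.5 * ((ks - i1) / sig) ** 2)
    w_fore = np.exp(-0.5 * ((ks - i2) / sig) ** 2)
    w_mid = 0.6 * np.exp(-0.5 * ((ks - imid) / sig_mid) ** 2)
    w_sum = w_heel + w_fore + w_mid
    regional = {
        "heel": total * w_heel / w_sum,
        "midfoot": total * w_mid / w_sum,
        "forefoot": total * w_fore / w_sum,
    }
    channels = np.zeros((n, 8))
    sensor_cols = {"forefoot": [0, 1, 2, 3], "midfoot": [4, 5], "heel": [6, 7]}
    for region, cols in sensor_cols.items():
        for col, share in zip(cols, shares[region]):
            channels[:, col] = regional[region] * share + channels[:, col]
    landmarks = {
        "heel_strike": 0,
        "peak1": i1,
        "valley": imid,
        "peak2": i2,
        "toe_off": stance_n,
        "cycle_end": n,
    }
    return channels, landmarks


def _foot_params(params: WaveformParams, side: str) -> WaveformParams:
    """Apply the left/right asymmetry offsets to one foot's parameters."""
    a = params.left_right_asymmetry
    if side == "left" or a == 0:
        return params
    stance = min(0.90, params.stance_fraction * (1 + 0.5 * a))
    if stance <= params.peak2_time_fraction:
        raise ConfigurationError(
            "asymmetry pushes right stance_fraction below peak2_time_fraction"
        )
    return replace(
        params,
        peak1_amp=params.peak1_amp * (1 + a),
        peak2_amp=params.peak2_amp * (1 + a),
        valley_amp=params.valley_amp * (1 + a),
        stance_fraction=stance,
    )


def generate_recording(
    params: WaveformParams,
    layout: Optional[SensorLayout] = None,
    body_weight: float = 61.33,
    participant_id: str = "synthetic",
) -> PressureRecording:
    """Generate one bilateral recording with ground-truth landmarks.

    Returns a :class:`PressureRecording` in raw units (kg-force; divide by
    ``body_weight`` to recover %BW fractions), with
    ``recording.ground_truth["left"|"right"]`` holding per-cycle landmark
    index dicts and ``ground_truth["params"]`` the planted parameters.
    """
    params.validate()
    if body_weight <= 0:
        raise ConfigurationError("body_weight must be positive")
    layout = layout or default_layout()
    rng = np.random.default_rng(params.seed)

    n_nominal = int(round(params.cycle_duration / DT))
    offset = n_nominal // 2  # right foot lags by half a cycle

    # Per-cycle jitter factors are shared between feet: with asymmetry=0 the
    # two feet are identical up to the programmed phase offset.
    dur_factors = 1.0 + params.cycle_jitter_sd * rng.standard_normal(params.n_cycles)
    amp_factors = 1.0 + params.cycle_jitter_sd * rng.standard_normal(params.n_cycles)
    dur_factors = np.clip(dur_factors, 0.6, 1.4)
    amp_factors = np.clip(amp_factors, 0.6, 1.4)

    feet: Dict[str, Tuple[np.ndarray, List[dict]]] = {}
    for side in ("left", "right"):
        p = _foot_params(params, side)
        blocks: List[np.ndarray] = []
        landmarks: List[dict] = []
        start = 0
        for c in range(params.n_cycles):
            n = max(6, int(round(p.cycle_duration * dur_factors[c] / DT)))
            stance_n = int(round(p.stance_fraction * n))
            i1 = int(round(p.peak1_time_fraction * n))
            i2 = int(round(p.peak2_time_fraction * n))
            i1 = max(1, i1)
            i2 = max(i1 + 2, i2)
            # keep the push-off peak >= 2 samples before toe-off so it stays
            # an interior local maximum at 20 Hz
            stance_n = min(n - 1, max(i2 + 2, stance_n))
            amps = (
                p.peak1_amp * amp_factors[c],
                p.peak2_amp * amp_factors[c],
                p.valley_amp * amp_factors[c],
            )
            block, rel = _cycle_matrix(n, stance_n, i1, i2, amps, p.region_shares)
            blocks.append(block)
            landmarks.append({k: v + start for k, v in rel.items()})
            start += n
        feet[side] = (np.vstack(blocks), landmarks)

    left_sig, left_marks = feet["left"]
    right_sig, right_marks = feet["right"]
    total_len = max(left_sig.shape[0], offset + right_sig.shape[0]) + 2
    left = np.zeros((total_len, 8))
    right = np.zeros((total_len, 8))
    left[: left_sig.shape[0]] = left_sig
    right[offset: offset + right_sig.shape[0]] = right_sig
    right_marks = [{k: v + offset for k, v in m.items()} for m in right_marks]

    return PressureRecording(
        participant_id=participant_id,
        left=left * body_weight,
        right=right * body_weight,
        body_weight=body_weight,
        layout=layout,
        ground_truth={"left": left_marks, "right": right_marks, "params": params},
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelModel:
    """Linear model tying a test completion time to gait/physical parameters.

    ``y = intercept + sum_k beta_k * (x_k - ref_k) + N(0, noise_sd)`` where
    ``x_k`` ranges over planted waveform parameters and physical covariates.
    """

    intercept: float
    coefficients: Dict[str, float]
    reference: Dict[str, float]
    noise_sd: float = 1.0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        unknown = set(self.coefficients) - set(self.reference)
        if unknown:
            raise ConfigurationError(f"coefficients without reference point: {unknown}")

    def evaluate(self, values: Dict[str, float], noise: float) -> float:
        y = self.intercept + noise * self.noise_sd
        for name, beta in self.coefficients.items():
            y += beta * (values[name] - self.reference[name])
        return y


_DEFAULT_REFERENCE = {
    "cycle_duration": 1.05,
    "stance_fraction": 0.62,
    "left_right_asymmetry": 0.0,
    "age": 62.95,
}


def default_label_models() -> Dict[str, LabelModel]:
    """Default completion-time models for the two functional tests.

    Intercepts and dispersion target cohort statistics typical of knee
    osteoarthritis: 40mFPWT 28.6 (6.2) s, TUGT 11.4 (3.0) s.  Slower cycles,
    longer stance, greater asymmetry, and higher age all worsen (lengthen)
    the completion times.
    """
    return {
        "fpwt40": LabelModel(
            intercept=28.61,
            coefficients={
                "cycle_duration": 40.0,
                "stance_fraction": 30.0,
                "left_right_asymmetry": 40.0,
                "age": 0.40,
            },
            reference=dict(_DEFAULT_REFERENCE),
            noise_sd=2.5,
        ),
        "tugt": LabelModel(
            intercept=11.39,
            coefficients={
                "cycle_duration": 15.0,
                "stance_fraction": 15.0,
                "left_right_asymmetry": 25.0,
                "age": 0.15,
            },
            reference=dict(_DEFAULT_REFERENCE),
            noise_sd=1.2,
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Sampling scheme for a synthetic cohort of walking participants.

    Physical-characteristic distributions default to a representative knee
    osteoarthritis cohort (age 63 (8) y, height 158 (8) cm, weight 61 (10)
    kg).  Waveform parameters vary around :class:`WaveformParams` defaults.
    """

    n_participants: int = 92
    seed: int = 0
    base_waveform: WaveformParams = field(default_factory=WaveformParams)
    cycle_duration_sd: float = 0.08
    stance_fraction_sd: float = 0.03
    asymmetry_scale: float = 0.05     # half-normal scale of |asymmetry|
    age_mean: float = 62.95
    age_sd: float = 8.4
    height_mean: float = 158.08
    height_sd: float = 7.85
    weight_mean: float = 61.33
    weight_sd: float = 10.47
    label_models: Dict[str, LabelModel] = field(default_factory=default_label_models)

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        for sd in (self.cycle_duration_sd, self.stance_fraction_sd,
                   self.asymmetry_scale, self.age_sd, self.height_sd, self.weight_sd):
            if sd < 0:
                raise ConfigurationError("distribution scales must be >= 0")
        self.base_waveform.validate()
        for model in self.label_models.values():
            model.validate()


def generate_cohort(
    spec: CohortSpec,
    layout: Optional[SensorLayout] = None,
) -> Tuple[List[PressureRecording], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a cohort: recordings, physical table, labels, planted truth.

    Returns ``(recordings, physical, labels, truth)`` where ``physical`` has
    columns ``participant_id, age, height, weight, BMI``, ``labels`` has one
    column per label model (``fpwt40_s``, ``tugt_s``), and ``truth`` holds
    the planted per-participant waveform parameters for recovery tests.
    """
    spec.validate()
    layout = layout or default_layout()
    rng = np.random.default_rng(spec.seed)
    base = spec.base_waveform

    recordings: List[PressureRecording] = []
    physical_rows, label_rows, truth_rows = [], [], []
    for i in range(spec.n_participants):
        pid = f"P{i:03d}"
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 30, 95))
        height = float(np.clip(rng.normal(spec.height_mean, spec.height_sd), 130, 200))
        weight = float(np.clip(rng.normal(spec.weight_mean, spec.weight_sd), 35, 120))
        bmi = weight / (height / 100.0) ** 2

        T = float(np.clip(rng.normal(base.cycle_duration, spec.cycle_duration_sd),
                          0.7, 1.6))
        stance = float(np.clip(rng.normal(base.stance_fraction, spec.stance_fraction_sd),
                               base.peak2_time_fraction + 0.06, 0.80))
        asym = float(abs(rng.normal(0.0, spec.asymmetry_scale))) if spec.asymmetry_scale else 0.0
        params = replace(
            base,
            cycle_duration=T,
            stance_fraction=stance,
            left_right_asymmetry=asym,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        recordings.append(
            generate_recording(params, layout=layout, body_weight=weight,
                               participant_id=pid)
        )

        values = {
            "cycle_duration": T,
            "stance_fraction": stance,
            "left_right_asymmetry": asym,
            "age": age,
            "height": height,
            "weight": weight,
            "BMI": bmi,
        }
        row = {"participant_id": pid}
        for task, model in spec.label_models.items():
            y = model.evaluate(values, noise=float(rng.standard_normal()))
            if y <= 0:
                raise ConfigurationError(
                    f"label model {task!r} produced nonpositive time {y:.3f}"
                )
            row[f"{task}_s"] = y
        label_rows.append(row)
        physical_rows.append(
            {"participant_id": pid, "age": age, "height": height,
             "weight": weight, "BMI": bmi}
        )
        truth_rows.append({"participant_id": pid, **{
            k: values[k] for k in ("cycle_duration", "stance_fraction",
                                   "left_right_asymmetry")
        }})

    physical = pd.DataFrame(physical_rows).set_index("participant_id")
    labels = pd.DataFrame(label_rows).set_index("participant_id")
    truth = pd.DataFrame(truth_rows).set_index("participant_id")
    return recordings, physical, labels, truth
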