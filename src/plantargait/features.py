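"""Multidimensional plantar-pressure gait features.

Per gait cycle, 54 single-foot features are extracted from each foot's
8-channel %BW slice plus 2 bipedal temporal features (110 per-cycle values):

* **PPP** (15/foot) — peak plantar pressure: per-sensor maxima, regional
  maxima of the summed forefoot/midfoot/heel series, the two force peaks of
  the total curve, and the lateral/medial peak ratios 4/2 and 8/7.
* **PG** (25/foot) — pressure gradients: per-sensor and regional max/min of
  the discrete derivative, the loading rate (heel strike -> first peak), the
  off-loading rate (second peak -> stance end, signed negative), and the
  valley gradient sum between the two peaks.
* **Temporal** (5/foot + 2 bipedal) — stance/swing ratio, cycle time,
  stance fraction, normalized times to the two peaks; single- and
  double-limb support times.
* **PTI** (2/foot) — pressure-time integrals of the total curve, heel
  strike -> first peak and over the whole stance (trapezoidal, %BW*s).
* **COP** (7/foot) — centre-of-pressure trajectory statistics on normalized
  sensor coordinates: mean/SD in both axes, path length, and mean/SD of the
  resultant distance from the stance-mean COP point.

Averaging over the 50-cycle window, the per-foot SDs (suffix ``STD``), the
left/right symmetry indices (prefix ``SI``), and the weak-foot copies
(prefix ``W``, weak = foot with larger anterior-posterior COP variability)
expand these to 380 gait features; age, height, weight and BMI complete the
384-column participant vector.

Undefined values (zero-denominator ratios, COP with no loaded stance
sample) propagate as NaN and are excluded from cycle averages; imputation
is deferred to the modelling stage (training-split means).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    DT,
    CycleWindow,
    GaitCycle,
    PressureRecording,
    SensorLayout,
    ValidationError,
)
from .segmentation import segment_recording, normalize_by_weight, total_vgrf

__all__ = [
    "SINGLE_FOOT_FEATURES",
    "BIPEDAL_FEATURES",
    "sided",
    "participant_feature_names",
    "feature_dictionary",
    "ppp_features",
    "pg_features",
    "temporal_features",
    "pti_features",
    "cop_features",
    "cycle_features",
    "aggregate_cycles",
    "symmetry_index",
    "weak_foot_features",
    "assemble_features",
    "extract_participant_features",
]

_REGION_COLS = {"1-4": [0, 1, 2, 3], "5-6": [4, 5], "7-8": [6, 7]}

_PPP_NAMES = ([f"{s}_PPP" for s in range(1, 9)]
              + ["1-4_PPP", "5-6_PPP", "7-8_PPP", "peak1", "peak2",
                 "4/2_PPP", "8/7_PPP"])
_PG_NAMES = ([f"{s}_{kind}PG" for s in range(1, 9) for kind in ("Max", "Min")]
             + ["1-4_MaxPG", "1-4_MinPG", "5-6_MaxPG", "5-6_MinPG",
                "7-8_MaxPG", "7-8_MinPG", "loadr", "unloadr", "valleyPG"])
_TEMPORAL_NAMES = ["t_st/sw", "t_T", "t_st/T", "t_t1/T", "t_t2/T"]
_PTI_NAMES = ["PTI_1", "PTI_st"]
_COP_NAMES = ["xcop_mean", "xcop_std", "ycop_mean", "ycop_std",
              "cop_len", "cop_MRD", "cop_SRD"]

#: The 54 single-foot feature base names (before the L/R/W side prefix).
SINGLE_FOOT_FEATURES: List[str] = (
    _PPP_NAMES + _PG_NAMES + _TEMPORAL_NAMES + _PTI_NAMES + _COP_NAMES
)
BIPEDAL_FEATURES: List[str] = ["single_support_time", "double_support_time"]

_GROUP_OF_BASE = {}
for _n in _PPP_NAMES:
    _GROUP_OF_BASE[_n] = "PPP"
for _n in _PG_NAMES:
    _GROUP_OF_BASE[_n] = "PG"
for _n in _TEMPORAL_NAMES:
    _GROUP_OF_BASE[_n] = "temporal"
for _n in _PTI_NAMES:
    _GROUP_OF_BASE[_n] = "PTI"
for _n in _COP_NAMES:
    _GROUP_OF_BASE[_n] = "COP"

_UNITS_OF_GROUP = {"PPP": "%BW (ratios unitless)", "PG": "%BW/s",
                   "temporal": "s or unitless", "PTI": "%BW*s",
                   "COP": "normalized foot units"}


def sided(side: str, base: str) -> str:
    """Canonical sided feature name: ``L_1_PPP`` but ``LPTI_1`` (the PTI
    names historically omit the underscore after the side letter)."""
    return f"{side}{base}" if base.startswith("PTI") else f"{side}_{base}"


def participant_feature_names() -> List[str]:
    """The 384 canonical participant-level column names, in table order."""
    names: List[str] = []
    for side in ("L", "R"):
        names += [sided(side, b) for b in SINGLE_FOOT_FEATURES]
    names += BIPEDAL_FEATURES
    names += [f"SI_{b}" for b in SINGLE_FOOT_FEATURES]
    for side in ("L", "R"):
        names += [f"{sided(side, b)}_STD" for b in SINGLE_FOOT_FEATURES]
    names += [sided("W", b) for b in SINGLE_FOOT_FEATURES]
    names += [f"{sided('W', b)}_STD" for b in SINGLE_FOOT_FEATURES]
    names += ["age", "height", "weight", "BMI"]
    return names


def feature_dictionary() -> Dict[str, Dict[str, str]]:
    """Machine-readable dictionary: column name -> {group, units, derivation}."""
    out: Dict[str, Dict[str, str]] = {}
    for name in participant_feature_names():
        if name in ("age", "height", "weight", "BMI"):
            units = {"age": "years", "height": "cm", "weight": "kg",
                     "BMI": "kg/m^2"}[name]
            out[name] = {"group": "physical", "units": units,
                         "derivation": "physical characteristic"}
            continue
        if name in BIPEDAL_FEATURES:
            out[name] = {"group": "temporal", "units": "s",
                         "derivation": "bipedal support time, 50-cycle mean"}
            continue
        base = name
        derivation = "50-cycle mean"
        if base.startswith("SI_"):
            base = base[3:]
            group = "SI"
            derivation = "Robinson symmetry index of L/R means"
        elif base.endswith("_STD"):
            base = base[:-4]
            group = "STD"
            derivation = "50-cycle sample SD"
        else:
            group = None
        if base.startswith("W"):
            base = base[2:] if base.startswith("W_") else base[1:]
            group = "weak_foot"
            derivation = "weak-foot copy, " + derivation
        elif base.startswith(("L_", "R_", "LP", "RP")):
            base = base[2:] if base[1] == "_" else base[1:]
        base_group = _GROUP_OF_BASE[base]
        out[name] = {
            "group": group or base_group,
            "base_group": base_group,
            "units": _UNITS_OF_GROUP[base_group],
            "derivation": derivation,
        }
    return out


# ---------------------------------------------------------------------------
# Per-cycle single-foot features
# ---------------------------------------------------------------------------

def _require_channels(cycle: GaitCycle) -> np.ndarray:
    if cycle.channels is None:
        raise ValidationError("cycle has no channel slice attached")
    return cycle.channels


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den != 0 else np.nan


def ppp_features(cycle: GaitCycle) -> Dict[str, float]:
    """Peak plantar pressures of one cycle (15 values, %BW)."""
    ch = _require_channels(cycle)
    total = ch.sum(axis=1)
    vals: Dict[str, float] = {}
    per_sensor = ch.max(axis=0)
    for s in range(8):
        vals[f"{s + 1}_PPP"] = float(per_sensor[s])
    for region, cols in _REGION_COLS.items():
        vals[f"{region}_PPP"] = float(ch[:, cols].sum(axis=1).max())
    vals["peak1"] = float(total[cycle.rel(cycle.peak1)])
    vals["peak2"] = float(total[cycle.rel(cycle.peak2)])
    vals["4/2_PPP"] = _safe_ratio(per_sensor[3], per_sensor[1])
    vals["8/7_PPP"] = _safe_ratio(per_sensor[7], per_sensor[6])
    return vals


def pg_features(cycle: GaitCycle, dt: float = DT) -> Dict[str, float]:
    """Pressure gradients of one cycle (25 values, %BW/s)."""
    ch = _require_channels(cycle)
    if ch.shape[0] < 2:
        raise ValidationError("cycle shorter than 2 samples")
    total = ch.sum(axis=1)
    grad = np.diff(ch, axis=0) / dt
    vals: Dict[str, float] = {}
    for s in range(8):
        vals[f"{s + 1}_MaxPG"] = float(grad[:, s].max())
        vals[f"{s + 1}_MinPG"] = float(grad[:, s].min())
    for region, cols in _REGION_COLS.items():
        g = np.diff(ch[:, cols].sum(axis=1)) / dt
        vals[f"{region}_MaxPG"] = float(g.max())
        vals[f"{region}_MinPG"] = float(g.min())
    hs, p1 = cycle.rel(cycle.heel_strike), cycle.rel(cycle.peak1)
    p2, to = cycle.rel(cycle.peak2), cycle.rel(cycle.toe_off)
    vals["loadr"] = float((total[p1] - total[hs]) / ((p1 - hs) * dt))
    vals["unloadr"] = float((total[to] - total[p2]) / ((to - p2) * dt))
    vals["valleyPG"] = float(np.abs(np.diff(total[p1: p2 + 1]) / dt).sum())
    return vals


def temporal_features(cycle: GaitCycle, dt: float = DT) -> Dict[str, float]:
    """Single-foot temporal features of one cycle (5 values)."""
    hs = cycle.heel_strike
    stance = (cycle.toe_off - hs) * dt
    T = (cycle.cycle_end - hs) * dt
    swing = T - stance
    return {
        "t_st/sw": stance / swing if swing > 0 else np.nan,
        "t_T": T,
        "t_st/T": stance / T,
        "t_t1/T": (cycle.peak1 - hs) * dt / T,
        "t_t2/T": (cycle.peak2 - hs) * dt / T,
    }


def bipedal_support_times(cycle_left: GaitCycle, total_left: np.ndarray,
                          total_right: np.ndarray, threshold: float,
                          dt: float = DT) -> Dict[str, float]:
    """Single- and double-limb support time within the left cycle span (s)."""
    span = slice(cycle_left.heel_strike, cycle_left.cycle_end)
    above_l = total_left[span] > threshold
    above_r = total_right[span] > threshold
    double = float(np.count_nonzero(above_l & above_r) * dt)
    single = float(np.count_nonzero(above_l ^ above_r) * dt)
    return {"single_support_time": single, "double_support_time": double}


def pti_features(cycle: GaitCycle, dt: float = DT) -> Dict[str, float]:
    """Pressure-time integrals of the total curve (2 values, %BW*s)."""
    total = _require_channels(cycle).sum(axis=1)
    p1, to = cycle.rel(cycle.peak1), cycle.rel(cycle.toe_off)
    return {
        "PTI_1": float(np.trapezoid(total[: p1 + 1], dx=dt)),
        "PTI_st": float(np.trapezoid(total[: to + 1], dx=dt)),
    }


def cop_features(cycle: GaitCycle, layout: SensorLayout,
                 threshold: float = 0.0) -> Dict[str, float]:
    """Centre-of-pressure trajectory statistics over stance (7 values).

    The COP is the pressure-weighted mean sensor position, computed on
    normalized (unit-square) coordinates and only on stance samples whose
    total pressure exceeds ``threshold``.
    """
    ch = _require_channels(cycle)
    stance = ch[: cycle.rel(cycle.toe_off)]
    total = stance.sum(axis=1)
    loaded = total > threshold
    if not np.any(loaded):
        return {name: np.nan for name in _COP_NAMES}
    p = stance[loaded]
    w = total[loaded][:, None]
    coords = layout.normalized_coords
    cop = p @ coords / w
    mean_pt = cop.mean(axis=0)
    steps = np.diff(cop, axis=0)
    rd = np.linalg.norm(cop - mean_pt, axis=1)
    return {
        "xcop_mean": float(mean_pt[0]),
        "xcop_std": float(cop[:, 0].std(ddof=0)),
        "ycop_mean": float(mean_pt[1]),
        "ycop_std": float(cop[:, 1].std(ddof=0)),
        "cop_len": float(np.linalg.norm(steps, axis=1).sum()) if steps.size else 0.0,
        "cop_MRD": float(rd.mean()),
        "cop_SRD": float(rd.std(ddof=0)),
    }


def single_foot_features(cycle: GaitCycle, layout: SensorLayout,
                         cop_threshold: float = 0.0) -> Dict[str, float]:
    """All 54 single-foot features of one cycle, keyed by base name."""
    out: Dict[str, float] = {}
    out.update(ppp_features(cycle))
    out.update(pg_features(cycle))
    out.update(temporal_features(cycle))
    out.update(pti_features(cycle))
    out.update(cop_features(cycle, layout, threshold=cop_threshold))
    return out


def cycle_features(cycle_left: GaitCycle, cycle_right: GaitCycle,
                   layout: SensorLayout, total_left: np.ndarray,
                   total_right: np.ndarray, threshold: float
                   ) -> Dict[str, float]:
    """The 110 per-cycle features of one adjacent left/right cycle pair."""
    out: Dict[str, float] = {}
    for side, cyc in (("L", cycle_left), ("R", cycle_right)):
        for base, value in single_foot_features(cyc, layout,
                                                cop_threshold=threshold).items():
            out[sided(side, base)] = value
    out.update(bipedal_support_times(cycle_left, total_left, total_right,
                                     threshold))
    return out


# ---------------------------------------------------------------------------
# Participant-level assembly
# ---------------------------------------------------------------------------

def aggregate_cycles(per_cycle: pd.DataFrame
                     ) -> Tuple[pd.Series, pd.Series]:
    """Mean of all 110 per-cycle features and sample SD (ddof=1) of the 108
    single-foot ones; NaN-flagged cycle values are excluded."""
    means = per_cycle.mean(skipna=True)
    sided_cols = [sided(side, b) for side in ("L", "R")
                  for b in SINGLE_FOOT_FEATURES]
    stds = per_cycle[sided_cols].std(ddof=1, skipna=True)
    stds.index = [f"{c}_STD" for c in stds.index]
    return means, stds


def symmetry_index(left: float, right: float) -> float:
    """Robinson symmetry index, percent: ``|L-R| / (0.5 (L+R)) * 100``.

    Zero for perfect symmetry; NaN when the mean is zero.
    """
    denom = 0.5 * (left + right)
    if denom == 0 or not np.isfinite(denom):
        return np.nan
    return abs(left - right) / abs(denom) * 100.0


def weak_foot_features(means: pd.Series, stds: pd.Series) -> Tuple[str, pd.Series]:
    """Copy the weak foot's 54 means and 54 SDs under the ``W`` prefix.

    The weak foot is the one with larger anterior-posterior COP variability
    (``ycop_std``); ties resolve to the left foot.
    """
    weak = "R" if means[sided("R", "ycop_std")] > means[sided("L", "ycop_std")] else "L"
    values = {}
    for base in SINGLE_FOOT_FEATURES:
        values[sided("W", base)] = means[sided(weak, base)]
    for base in SINGLE_FOOT_FEATURES:
        values[f"{sided('W', base)}_STD"] = stds[f"{sided(weak, base)}_STD"]
    return weak, pd.Series(values)


def assemble_features(window: CycleWindow, layout: SensorLayout,
                      total_left: np.ndarray, total_right: np.ndarray,
                      threshold: float,
                      physical: Optional[Dict[str, float]] = None
                      ) -> pd.Series:
    """Assemble the 384-entry participant feature vector from a window.

    ``physical`` maps age/height/weight/BMI; missing entries become NaN.
    """
    rows = [cycle_features(lc, rc, layout, total_left, total_right, threshold)
            for lc, rc in window.pairs]
    per_cycle = pd.DataFrame(rows)
    means, stds = aggregate_cycles(per_cycle)
    si = pd.Series({
        f"SI_{b}": symmetry_index(means[sided("L", b)], means[sided("R", b)])
        for b in SINGLE_FOOT_FEATURES
    })
    _, weak = weak_foot_features(means, stds)
    phys = pd.Series({k: (physical or {}).get(k, np.nan)
                      for k in ("age", "height", "weight", "BMI")}, dtype=float)
    out = pd.concat([means, si, stds, weak, phys])
    out = out.reindex(participant_feature_names())
    if len(out) != 384:
        raise AssertionError(f"feature count mismatch: {len(out)} != 384")
    return out


def extract_participant_features(rec: PressureRecording,
                                 physical: Optional[Dict[str, float]] = None,
                                 threshold_fraction: float = 0.05
                                 ) -> pd.Series:
    """Full extraction for one raw recording: normalize, segment the
    50-cycle window, and assemble the 384-column feature vector."""
    window = segment_recording(rec, threshold_fraction=threshold_fraction)
    norm = normalize_by_weight(rec)
    return assemble_features(
        window, rec.layout,
        total_vgrf(norm, "left"), total_vgrf(norm, "right"),
        window.threshold, physical=physical,
    )


def extract_cohort_features(recordings, physical: pd.DataFrame,
                            threshold_fraction: float = 0.05) -> pd.DataFrame:
    """Feature table for a cohort: one row per participant, 384 columns."""
    rows = {}
    for rec in recordings:
        phys = physical.loc[rec.participant_id].to_dict() \
            if rec.participant_id in physical.index else None
        rows[rec.participant_id] = extract_participant_features(
            rec, physical=phys, threshold_fraction=threshold_fraction)
    table = pd.DataFrame(rows).T
    table.index.name = "participant_id"
    return table
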