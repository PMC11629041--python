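"""Gait-cycle segmentation from bilateral total-pressure curves.

A gait cycle runs from one heel strike (rise of the total VGRF above a
detection threshold) to the next.  Within the stance phase the bimodal total
curve yields five landmarks: heel strike, first force peak (weight
acceptance), valley (mid-stance), second peak (push-off), and toe-off (drop
below threshold).  The analysis window discards the first two detected steps
of each foot and keeps the next 50 cycles with left/right adjacency.
"""

from __future__ import annotations

import logging
from dataclasses import replace as _dc_replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .core import (
    CycleWindow,
    GaitCycle,
    InsufficientCyclesError,
    NoGaitDetectedError,
    PressureRecording,
    SegmentationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Detection threshold as a fraction of the recording's maximum total VGRF.
DEFAULT_THRESHOLD_FRACTION = 0.05
#: Samples a rise must persist above threshold to count as a heel strike.
HYSTERESIS_SAMPLES = 2

__all__ = [
    "normalize_by_weight",
    "total_vgrf",
    "detection_threshold",
    "detect_heel_strikes",
    "detect_cycles",
    "select_window",
    "segment_recording",
]


def normalize_by_weight(rec: PressureRecording) -> PressureRecording:
    """Divide every channel by body weight, giving fractions of body weight.

    Not idempotent: the pipeline applies it exactly once, directly after
    loading a raw recording.
    """
    if rec.body_weight <= 0:
        raise ValidationError("body_weight must be positive")
    return PressureRecording(
        participant_id=rec.participant_id,
        left=rec.left / rec.body_weight,
        right=rec.right / rec.body_weight,
        body_weight=rec.body_weight,
        layout=rec.layout,
        sampling_rate=rec.sampling_rate,
        ground_truth=rec.ground_truth,
    )


def total_vgrf(rec: PressureRecording, foot: str) -> np.ndarray:
    """Total vertical ground reaction force: sum of the foot's 8 channels."""
    return rec.foot(foot).sum(axis=1)


def detection_threshold(rec: PressureRecording,
                        fraction: float = DEFAULT_THRESHOLD_FRACTION) -> float:
    """Heel-strike threshold: ``fraction`` of the recording's peak total VGRF
    across both feet."""
    peak = max(total_vgrf(rec, "left").max(), total_vgrf(rec, "right").max())
    return fraction * peak


def detect_heel_strikes(total: np.ndarray, threshold: float) -> np.ndarray:
    """Indices where the total curve rises above ``threshold`` and stays
    there for at least ``HYSTERESIS_SAMPLES`` samples."""
    total = np.asarray(total, dtype=float)
    if total.size < 3:
        raise ValidationError("series must have at least 3 samples")
    above = total > threshold
    rises = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    strikes = []
    for i in rises:
        if np.all(above[i: i + HYSTERESIS_SAMPLES]) and i + HYSTERESIS_SAMPLES <= total.size:
            strikes.append(i)
    if not strikes:
        raise NoGaitDetectedError("no gait detected: total pressure never "
                                  "rises above the threshold")
    return np.asarray(strikes, dtype=int)


def _stance_landmarks(total: np.ndarray, hs: int, toe_off: int
                      ) -> Optional[Tuple[int, int, int]]:
    """Locate (peak1, valley, peak2) inside stance, or None if unimodal."""
    seg = total[hs:toe_off]
    peaks, props = find_peaks(seg)
    if peaks.size < 2:
        return None
    heights = seg[peaks]
    # Two largest local maxima; ties broken toward the earlier sample.
    order = np.lexsort((peaks, -heights))[:2]
    chosen = np.sort(peaks[order])
    i1, i2 = int(chosen[0]), int(chosen[1])
    valley = i1 + int(np.argmin(seg[i1: i2 + 1]))
    return hs + i1, hs + valley, hs + i2


def detect_cycles(total: np.ndarray, threshold: float, foot: str = "left"
                  ) -> List[GaitCycle]:
    """Segment a total-VGRF series into complete gait cycles.

    Cycles whose stance is unimodal (fewer than two interior local maxima)
    are excluded with a warning rather than fabricating a valley; the
    trailing cycle (no subsequent heel strike) is discarded as incomplete.
    """
    total = np.asarray(total, dtype=float)
    strikes = detect_heel_strikes(total, threshold)
    cycles: List[GaitCycle] = []
    excluded = 0
    for hs, nxt in zip(strikes[:-1], strikes[1:]):
        below = np.flatnonzero(total[hs:nxt] <= threshold)
        if below.size == 0:
            excluded += 1
            continue
        toe_off = hs + int(below[0])
        marks = _stance_landmarks(total, hs, toe_off)
        if marks is None:
            excluded += 1
            continue
        p1, valley, p2 = marks
        try:
            cycles.append(GaitCycle(foot=foot, heel_strike=int(hs), peak1=p1,
                                    valley=valley, peak2=p2, toe_off=toe_off,
                                    cycle_end=int(nxt)))
        except ValidationError:
            excluded += 1
    if excluded:
        logger.warning("%s foot: excluded %d cycle(s) with unimodal or "
                       "degenerate stance", foot, excluded)
    return cycles


def _adjacent(left: GaitCycle, right: GaitCycle) -> bool:
    """Left/right adjacency: stance overlap, or the right heel strike falls
    within the left cycle span."""
    stance_overlap = max(left.heel_strike, right.heel_strike) < min(left.toe_off,
                                                                    right.toe_off)
    hs_within = left.heel_strike <= right.heel_strike < left.cycle_end
    return stance_overlap or hs_within


def select_window(cycles_left: Sequence[GaitCycle],
                  cycles_right: Sequence[GaitCycle],
                  n_cycles: int = 50, n_skip: int = 2) -> CycleWindow:
    """Drop the first ``n_skip`` steps per foot and pair the next
    ``n_cycles`` adjacent left/right cycles."""
    for name, cycles in (("left", cycles_left), ("right", cycles_right)):
        available = len(cycles)
        if available < n_skip + n_cycles:
            raise InsufficientCyclesError(
                f"insufficient cycles on {name} foot "
                f"({available} < {n_skip + n_cycles})"
            )
    lefts = list(cycles_left)[n_skip:]
    rights = list(cycles_right)[n_skip:]
    pairs: List[Tuple[GaitCycle, GaitCycle]] = []
    j = 0
    for lc in lefts:
        # skip right cycles that started before this left cycle: they belong
        # to an earlier (possibly excluded) left step
        while j < len(rights) and rights[j].heel_strike < lc.heel_strike:
            j += 1
        if j >= len(rights):
            break
        if _adjacent(lc, rights[j]):
            pairs.append((lc, rights[j]))
            j += 1
        if len(pairs) == n_cycles:
            break
    if len(pairs) < n_cycles:
        raise InsufficientCyclesError(
            f"only {len(pairs)} adjacent left/right pairs found "
            f"(need {n_cycles})"
        )
    return CycleWindow(left=[p[0] for p in pairs], right=[p[1] for p in pairs])


def segment_recording(rec: PressureRecording,
                      threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                      n_cycles: int = 50, n_skip: int = 2) -> CycleWindow:
    """Normalize, segment both feet, select the analysis window, and attach
    %BW channel slices to every cycle.

    ``rec`` must be a raw recording; weight normalization is applied here.
    """
    norm = normalize_by_weight(rec)
    threshold = detection_threshold(norm, threshold_fraction)
    cycles = {}
    for foot in ("left", "right"):
        total = total_vgrf(norm, foot)
        cycles[foot] = detect_cycles(total, threshold, foot=foot)
    window = select_window(cycles["left"], cycles["right"],
                           n_cycles=n_cycles, n_skip=n_skip)
    for foot in ("left", "right"):
        mat = norm.foot(foot)
        seq = window.left if foot == "left" else window.right
        for i, cyc in enumerate(seq):
            seq[i] = _dc_replace(cyc,
                                 channels=mat[cyc.heel_strike: cyc.cycle_end].copy())
    window.threshold = threshold
    return window
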