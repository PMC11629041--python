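"""Plain-text I/O for recordings, labels and feature tables.

Recording CSV dialect: columns ``t, L1..L8, R1..R8`` (raw pressure units),
with a JSON sidecar (same stem, ``.json``) carrying body weight, foot
dimensions, sensor coordinates and physical characteristics.  Labels:
``participant_id, fpwt40_s, tugt_s``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .core import DT, PressureRecording, SensorLayout

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_feature_table",
    "read_feature_table",
]

_CHANNEL_COLS = [f"L{i}" for i in range(1, 9)] + [f"R{i}" for i in range(1, 9)]


def write_recording_csv(rec: PressureRecording, path,
                        physical: Optional[Dict[str, float]] = None) -> None:
    path = Path(path)
    t = np.arange(rec.left.shape[0]) * (1.0 / rec.sampling_rate)
    df = pd.DataFrame(np.column_stack([t, rec.left, rec.right]),
                      columns=["t"] + _CHANNEL_COLS)
    df.to_csv(path, index=False, float_format="%.6g")
    sidecar = {
        "participant_id": rec.participant_id,
        "body_weight": rec.body_weight,
        "sampling_rate": rec.sampling_rate,
        "foot_length": rec.layout.foot_length,
        "foot_width": rec.layout.foot_width,
        "sensor_coords_mm": rec.layout.coords_mm.tolist(),
        "physical": physical or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2,
                                                    sort_keys=True))


def read_recording_csv(path) -> PressureRecording:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    layout = SensorLayout(
        coords_mm=np.asarray(meta["sensor_coords_mm"], dtype=float),
        foot_length=meta["foot_length"],
        foot_width=meta["foot_width"],
    )
    return PressureRecording(
        participant_id=meta["participant_id"],
        left=df[[f"L{i}" for i in range(1, 9)]].to_numpy(),
        right=df[[f"R{i}" for i in range(1, 9)]].to_numpy(),
        body_weight=meta["body_weight"],
        layout=layout,
        sampling_rate=meta.get("sampling_rate", 1.0 / DT),
    )


def read_recording_physical(path) -> Dict[str, float]:
    """Physical characteristics stored in a recording's JSON sidecar."""
    return json.loads(Path(path).with_suffix(".json").read_text()).get("physical", {})


def write_labels_csv(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=True, float_format="%.6g")


def read_labels_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id")


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=True)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id")
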