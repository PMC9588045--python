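"""File-format helpers: NIfTI volumes, event tables, YAML configs.

Event files are 3-column tab-separated tables (onset, duration, condition)
with onsets in seconds, one row per block, sorted by onset.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

EVENT_COLUMNS = ["onset", "duration", "condition"]


def write_events(path: str | Path, events: list[tuple[str, float, float]]) -> None:
    """Write (condition, onset, duration) blocks as an onset/duration/condition TSV."""
    df = pd.DataFrame(
        [(onset, duration, cond) for cond, onset, duration in events],
        columns=EVENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_events(path: str | Path) -> list[tuple[str, float, float]]:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event file {path} lacks columns: {sorted(missing)}")
    rows = df.sort_values("onset")
    return [(str(r.condition), float(r.onset), float(r.duration)) for r in rows.itertuples()]


def save_volume(path: str | Path, data: np.ndarray, voxel_size: float = 1.0) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_mask(path: str | Path, mask: np.ndarray, voxel_size: float = 1.0) -> None:
    save_volume(path, mask.astype(np.uint8), voxel_size)


def load_mask(path: str | Path) -> np.ndarray:
    return load_volume(path) > 0.5


def write_yaml(path: str | Path, obj: Mapping[str, Any]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=False)


def read_yaml(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_json(path: str | Path, obj: Any) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
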