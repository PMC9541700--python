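"""On-disk formats: float32 TIFF rasters with JSON sidecars, CSV tables.

A BMD map is stored as ``<stem>.tif`` (float32, NaN outside the mask),
``<stem>.json`` (subject id, age, scanner, pixel spacing) and
``<stem>.landmarks.csv`` (index, x_mm, y_mm; 65 rows). Cohort tables are
plain CSV. The atlas has its own HDF5 format (see atlas.PixelQuantileAtlas).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import BMDMap, ConfigurationError

__all__ = [
    "write_bmd_map",
    "read_bmd_map",
    "write_cohort",
    "read_cohort",
    "write_landmarks",
    "read_landmarks",
]


def write_landmarks(path, landmarks: np.ndarray):
    df = pd.DataFrame({
        "index": np.arange(len(landmarks)),
        "x_mm": landmarks[:, 0],
        "y_mm": landmarks[:, 1],
    })
    df.to_csv(path, index=False)


def read_landmarks(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("x_mm", "y_mm"):
        if col not in df.columns:
            raise ConfigurationError(f"landmark file {path} lacks column {col}")
    df = df.sort_values("index") if "index" in df.columns else df
    return df[["x_mm", "y_mm"]].to_numpy(dtype=float)


def write_bmd_map(directory, stem: str, m: BMDMap):
    """Write one map as TIFF + JSON sidecar (+ landmarks CSV if present)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / f"{stem}.tif", m.values.astype(np.float32))
    sidecar = {
        "subject_id": m.meta.get("subject_id", stem),
        "age_years": m.meta.get("age_years"),
        "scanner": m.meta.get("scanner"),
        "pixel_spacing_mm": m.spacing,
    }
    sidecar.update({k: v for k, v in m.meta.items()
                    if k not in sidecar and _jsonable(v)})
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    if m.landmarks is not None:
        write_landmarks(directory / f"{stem}.landmarks.csv", m.landmarks)


def _jsonable(v) -> bool:
    return isinstance(v, (bool, int, float, str, type(None)))


def read_bmd_map(directory, stem: str) -> BMDMap:
    directory = Path(directory)
    values = tifffile.imread(directory / f"{stem}.tif").astype(float)
    meta = json.loads((directory / f"{stem}.json").read_text())
    spacing = float(meta.pop("pixel_spacing_mm", 0.5))
    lm_path = directory / f"{stem}.landmarks.csv"
    landmarks = read_landmarks(lm_path) if lm_path.exists() else None
    return BMDMap(values, np.isfinite(values), spacing, landmarks, meta)


def iter_map_stems(directory):
    return sorted(p.stem for p in Path(directory).glob("*.tif"))


COHORT_COLUMNS = ["subject_id", "age_years", "scanner", "bmi",
                  "fracture_status", "followup_years"]


def write_cohort(path, cohort: pd.DataFrame):
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ConfigurationError(f"cohort table lacks columns {missing}")
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"cohort table lacks columns {missing}")
    return df
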