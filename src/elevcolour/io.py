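"""Readers, writers and validation for the pipeline's tabular interfaces."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .synthetic import METADATA_COLUMNS

__all__ = ["read_metadata", "read_features", "write_features", "to_jsonable", "write_report"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a specimen metadata CSV.

    Required columns: image_id, species_id, genus_id, family_id,
    elevation_m, temperature_c, precip_mm.  Unknown columns are preserved.
    """
    df = pd.read_csv(path)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"metadata is missing required column: {col}")
    if df["image_id"].duplicated().any():
        dup = df.loc[df["image_id"].duplicated(), "image_id"].iloc[0]
        raise ValueError(f"duplicate image_id: {dup}")
    if (df["elevation_m"] < 0).any():
        raise ValueError("elevation_m must be nonnegative")
    return df


def write_features(vectors: dict[str, np.ndarray], path: str | Path) -> None:
    """Write feature vectors as CSV with columns image_id, v0..v{D-1}."""
    ids = sorted(vectors)
    mat = np.stack([vectors[i] for i in ids])
    df = pd.DataFrame(mat, columns=[f"v{j}" for j in range(mat.shape[1])])
    df.insert(0, "image_id", ids)
    df.to_csv(path, index=False)


def read_features(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    if "image_id" not in df.columns:
        raise ValueError("features CSV is missing required column: image_id")
    return {
        str(r): df.iloc[i, 1:].to_numpy(dtype=float)
        for i, r in enumerate(df["image_id"])
    }


def to_jsonable(obj: Any) -> Any:
    """Recursively convert dataclasses / numpy / pandas objects for JSON."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    return obj


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(to_jsonable(report), indent=2))
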