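"""Delimited-text readers and writers for shapes, spectra, and grids.

Shape files hold one station per row with columns ``u_mm``, ``z_upper_mm``,
``z_lower_mm``, ``w_mm`` (one file per structure: body, bladder); a JSON
manifest per fish records species, total length and the structure file names.
Spectrum files hold columns ``f_hz``, ``ts_db`` and serve both for export of
KRM spectra and for import of externally computed full-wave reference spectra.
Writers emit tab-separated files; readers accept comma or tab.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import InvalidShapeError
from .shapes import FishModel, ShapeProfile

__all__ = [
    "read_shape",
    "write_shape",
    "read_fish",
    "write_fish",
    "read_spectrum",
    "write_spectrum",
    "spectrum_frame",
]

_SHAPE_COLUMNS = ["u_mm", "z_upper_mm", "z_lower_mm", "w_mm"]


def _read_delimited(path: Union[str, Path]) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - message formatting only
        raise InvalidShapeError(f"cannot parse {path}: {exc}") from exc


def read_shape(path: Union[str, Path]) -> ShapeProfile:
    """Read one station table (comma- or tab-separated)."""
    df = _read_delimited(path)
    missing = [c for c in _SHAPE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidShapeError(f"{path}: missing columns {missing}")
    try:
        return ShapeProfile(
            u=df["u_mm"].to_numpy(float),
            z_upper=df["z_upper_mm"].to_numpy(float),
            z_lower=df["z_lower_mm"].to_numpy(float),
            w=df["w_mm"].to_numpy(float),
        )
    except InvalidShapeError as exc:
        raise InvalidShapeError(f"{path}: {exc}") from exc


def write_shape(profile: ShapeProfile, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "u_mm": profile.u,
            "z_upper_mm": profile.z_upper,
            "z_lower_mm": profile.z_lower,
            "w_mm": profile.w,
        }
    ).to_csv(path, sep="\t", index=False)


def write_fish(fish: FishModel, out_dir: Union[str, Path], stem: str) -> Path:
    """Write a fish (shape files + JSON manifest); returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "species": fish.species,
        "total_length_cm": fish.total_length_cm,
        "note": fish.note,
        "body": None,
        "bladder": None,
    }
    if fish.body is not None:
        name = f"{stem}_body.tsv"
        write_shape(fish.body, out / name)
        manifest["body"] = name
    if fish.bladder is not None:
        name = f"{stem}_bladder.tsv"
        write_shape(fish.bladder, out / name)
        manifest["bladder"] = name
    path = out / f"{stem}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_fish(manifest_path: Union[str, Path]) -> FishModel:
    """Read a fish from its JSON manifest and the shape files it names."""
    path = Path(manifest_path)
    meta = json.loads(path.read_text())
    body = read_shape(path.parent / meta["body"]) if meta.get("body") else None
    bladder = (
        read_shape(path.parent / meta["bladder"]) if meta.get("bladder") else None
    )
    return FishModel(
        species=meta["species"],
        total_length_cm=float(meta["total_length_cm"]),
        body=body,
        bladder=bladder,
        note=meta.get("note", ""),
    )


def spectrum_frame(f_hz: np.ndarray, ts_db: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"f_hz": np.asarray(f_hz, float), "ts_db": np.asarray(ts_db, float)})


def write_spectrum(spectrum: pd.DataFrame, path: Union[str, Path]) -> None:
    spectrum[["f_hz", "ts_db"]].to_csv(path, sep="\t", index=False)


def read_spectrum(path: Union[str, Path]) -> pd.DataFrame:
    df = _read_delimited(path)
    missing = [c for c in ("f_hz", "ts_db") if c not in df.columns]
    if missing:
        raise InvalidShapeError(f"{path}: missing columns {missing}")
    return df[["f_hz", "ts_db"]].astype(float)
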