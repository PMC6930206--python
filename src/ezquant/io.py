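"""Reading and writing B-scans, sidecar metadata and measurement tables.

Images travel as 8/16-bit grayscale TIFF or PNG; scan geometry (pixel
pitches, meridian, fovea column, working-scale flag) that image formats
cannot carry goes in a JSON sidecar next to the image
(``<image>.json``).  Measurement tables are plain CSV:

* calibration pairs: ``unit_id,group,mm,am`` (``unit_id`` optional);
* validation replicates: ``unit_id,group,am,mm_rep1..mm_repK``;
* per-sector output: ``eye_id,scan_id,meridian,sector_id,center_um,mezi,
  excluded,reason``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image as PILImage

from .bands import BScanImage

__all__ = [
    "read_bscan", "write_bscan", "write_truth", "read_truth",
    "read_paired_csv", "write_paired_csv",
    "read_validation_csv", "write_validation_csv",
    "SchemaError",
]


class SchemaError(ValueError):
    """A CSV does not match its expected schema."""


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_bscan(image: BScanImage, path) -> Path:
    """Write a B-scan as 16-bit TIFF/PNG plus a JSON geometry sidecar.

    Working-scale values are rounded to integers; the geometry and the
    ``is_log_transformed`` flag go to ``<path>.json``.
    """
    path = Path(path)
    arr = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        PILImage.fromarray(arr, mode="I;16").save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    meta = {
        "lateral_um_per_px": image.lateral_um_per_px,
        "axial_um_per_px": image.axial_um_per_px,
        "scan_id": image.scan_id,
        "meridian": image.meridian,
        "is_log_transformed": image.is_log_transformed,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_bscan(path, lateral_um_per_px: float | None = None,
               axial_um_per_px: float | None = None,
               meridian: str | None = None,
               is_log_transformed: bool | None = None) -> BScanImage:
    """Read a grayscale TIFF/PNG B-scan; explicit arguments override the sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(PILImage.open(path))
    if arr.ndim == 3:  # tolerate single-channel-replicated RGB
        arr = arr[..., 0]
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    lat = lateral_um_per_px if lateral_um_per_px is not None else meta.get("lateral_um_per_px")
    axi = axial_um_per_px if axial_um_per_px is not None else meta.get("axial_um_per_px")
    if lat is None or axi is None:
        raise ValueError(
            f"{path}: scan geometry unknown; supply pixel pitches or a sidecar")
    return BScanImage(
        pixels=arr.astype(float),
        lateral_um_per_px=float(lat), axial_um_per_px=float(axi),
        scan_id=meta.get("scan_id", path.stem),
        meridian=meridian if meridian is not None else meta.get("meridian", "horizontal"),
        is_log_transformed=(is_log_transformed if is_log_transformed is not None
                            else bool(meta.get("is_log_transformed", False))),
    )


def write_truth(truth, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1))
    return path


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_paired_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    cols = [c for c in ("unit_id", "group", "mm", "am") if c in df.columns]
    df[cols].to_csv(path, index=False)
    return path


def read_paired_csv(path) -> pd.DataFrame:
    """Load a calibration table; requires ``mm`` and ``am`` columns."""
    df = pd.read_csv(path)
    for col in ("mm", "am"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for i, row in df.iterrows():
        if pd.isna(row["mm"]) or pd.isna(row["am"]):
            raise SchemaError(f"{path}: missing value in row {i + 2}")
    if "unit_id" not in df.columns:
        df.insert(0, "unit_id", [f"u{i:04d}" for i in range(len(df))])
    if "group" not in df.columns:
        df.insert(1, "group", "unknown")
    return df


def write_validation_csv(df: pd.DataFrame, path) -> Path:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return Path(path)


def read_validation_csv(path, n_reps: int = 5) -> pd.DataFrame:
    """Load a validation table with ``am`` and ``mm_rep1..mm_repK`` columns."""
    df = pd.read_csv(path)
    rep_cols = [f"mm_rep{i + 1}" for i in range(n_reps)]
    missing = [c for c in ["am", *rep_cols] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for i, row in df.iterrows():
        if row[["am", *rep_cols]].isna().any():
            raise SchemaError(f"{path}: missing replicate in row {i + 2}")
    if "unit_id" not in df.columns:
        df.insert(0, "unit_id", [f"u{i:04d}" for i in range(len(df))])
    return df
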