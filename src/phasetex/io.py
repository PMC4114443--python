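"""TIFF + JSON-sidecar persistence for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import DomainError
from .imaging import ProjectionImage, Sinogram


def write_json(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_tiff(path: str | Path, array: np.ndarray) -> Path:
    path = Path(path)
    arr = np.asarray(array)
    if arr.dtype != np.uint8:
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)
    return path


def read_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def save_projection(proj: ProjectionImage, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.tif`` plus ``<stem>.json`` metadata."""
    stem = Path(stem)
    tif = write_tiff(stem.with_suffix(".tif"), np.atleast_2d(proj.data))
    meta = dict(proj.meta, angle=proj.angle, pixel_size=proj.pixel_size,
                dtype=str(np.asarray(proj.data).dtype))
    return tif, write_json(stem.with_suffix(".json"), meta)


def save_sinogram(sino: Sinogram, stem: str | Path) -> tuple[Path, Path]:
    stem = Path(stem)
    tif = write_tiff(stem.with_suffix(".tif"), sino.data)
    meta = dict(sino.meta, pixel_size=sino.pixel_size,
                angles={"start": float(sino.angles[0]),
                        "step": float(sino.angles[1] - sino.angles[0])
                        if sino.angles.size > 1 else 0.0,
                        "count": int(sino.angles.size)})
    return tif, write_json(stem.with_suffix(".json"), meta)


def load_sinogram(stem: str | Path) -> Sinogram:
    stem = Path(stem)
    data = read_tiff(stem.with_suffix(".tif"))
    meta = read_json(stem.with_suffix(".json"))
    ang = meta.get("angles")
    if not isinstance(ang, dict):
        raise DomainError(f"{stem}.json lacks an 'angles' record")
    angles = ang["start"] + ang["step"] * np.arange(ang["count"])
    return Sinogram(np.asarray(data, dtype=float), angles,
                    float(meta["pixel_size"]), meta)
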