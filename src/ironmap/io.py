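"""File I/O: NIfTI series and maps with JSON sidecars, TIFF, CSV tracks.

Conventions
-----------
* MR image series: one NIfTI volume per series with the acquisition-time
  axis last, plus a JSON sidecar ``{kind, times_ms, noise_sigma, seed}``.
* Parameter maps: three NIfTI volumes (values, quality, validity mask).
* Microscopy channels: one 16-bit TIFF per channel.
* Tracks: CSV with header ``track_id,t_s,x_um,y_um``.
* Reports: JSON with sorted keys (byte-reproducible for a fixed input).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .phantom import AcquisitionSchedule, EchoSeries, TrackTable
from .relaxometry import ParameterMap

__all__ = [
    "save_series",
    "load_series",
    "save_parameter_map",
    "load_parameter_map",
    "save_labels",
    "load_labels",
    "save_tiff",
    "load_tiff",
    "save_tracks",
    "load_tracks",
    "write_json_report",
    "file_sha256",
]


def _affine(pixel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = pixel_size
    return aff


def save_series(series: EchoSeries, path: str | Path, seed: int | None = None) -> Path:
    """Write an EchoSeries as NIfTI (time axis last) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.moveaxis(series.images, 0, -1)
    img = nib.Nifti1Image(data.astype(np.float64), _affine(series.pixel_size))
    nib.save(img, path)
    sidecar = dict(series.schedule.to_dict())
    if seed is None:
        seed = series.provenance.get("noise_seed")
    sidecar["seed"] = seed
    sidecar["provenance"] = series.provenance
    sidecar_path = path.with_suffix("").with_suffix("")  # strip .nii[.gz]
    sidecar_path = Path(str(sidecar_path) + ".json")
    write_json_report(sidecar, sidecar_path)
    return path


def load_series(path: str | Path, sidecar: str | Path | None = None) -> EchoSeries:
    """Read a NIfTI series and its JSON sidecar back into an EchoSeries."""
    path = Path(path)
    if sidecar is None:
        stem = path.with_suffix("").with_suffix("")
        sidecar = Path(str(stem) + ".json")
    meta = json.loads(Path(sidecar).read_text())
    img = nib.load(path)
    data = np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0)
    # drop singleton z-axis written for 2D series
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    schedule = AcquisitionSchedule.from_dict(meta)
    pixel_size = float(img.header.get_zooms()[0])
    return EchoSeries(images=data, schedule=schedule, pixel_size=pixel_size,
                      provenance=meta.get("provenance", {}))


def save_parameter_map(pmap: ParameterMap, out_dir: str | Path, stem: str,
                       pixel_size: float = 1.0) -> dict[str, Path]:
    """Write values/quality/valid-mask volumes for one ParameterMap."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr, dtype in (
        ("values", pmap.values, np.float64),
        ("quality", pmap.quality, np.float64),
        ("valid", pmap.valid_mask.astype(np.uint8), np.uint8),
    ):
        p = out_dir / f"{stem}_{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), _affine(pixel_size)), p)
        paths[name] = p
    meta = {"kind": pmap.kind}
    if pmap.schedule_used is not None:
        meta["schedule"] = pmap.schedule_used.to_dict()
    meta_path = out_dir / f"{stem}_map.json"
    write_json_report(meta, meta_path)
    paths["meta"] = meta_path
    return paths


def load_parameter_map(out_dir: str | Path, stem: str) -> ParameterMap:
    out_dir = Path(out_dir)
    values = np.asarray(nib.load(out_dir / f"{stem}_values.nii").dataobj, dtype=float)
    quality = np.asarray(nib.load(out_dir / f"{stem}_quality.nii").dataobj, dtype=float)
    valid = np.asarray(nib.load(out_dir / f"{stem}_valid.nii").dataobj) > 0
    meta = json.loads((out_dir / f"{stem}_map.json").read_text())
    schedule = None
    if "schedule" in meta:
        schedule = AcquisitionSchedule.from_dict(meta["schedule"])
    return ParameterMap(values=values, quality=quality, valid_mask=valid,
                        kind=meta["kind"], schedule_used=schedule)


def save_labels(labels: np.ndarray, path: str | Path, pixel_size: float = 1.0) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(labels.astype(np.int16), _affine(pixel_size)), path)
    return path


def load_labels(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj).astype(np.int16)


def save_tiff(image: np.ndarray, path: str | Path, *, scale_to_uint16: bool = True) -> Path:
    """Write one channel as 16-bit TIFF (values clipped to [0, 65535])."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if scale_to_uint16:
        data = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    else:
        data = image
    tifffile.imwrite(path, data)
    return path


def load_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def save_tracks(tracks: TrackTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tracks.frame.to_csv(path, index=False)
    return path


def load_tracks(path: str | Path, field_extent=(450.0, 350.0),
                duration: float = 60.0) -> TrackTable:
    frame = pd.read_csv(path)
    return TrackTable(frame=frame, field_extent=tuple(field_extent),
                      duration=float(duration))


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return super().default(o)


def write_json_report(obj: dict, path: str | Path) -> Path:
    """Write a JSON report deterministically (sorted keys, fixed separators)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = json.dumps(obj, sort_keys=True, indent=2, cls=_ReportEncoder)
    path.write_text(text + "\n")
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
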