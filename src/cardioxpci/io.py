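"""Volume, mask, label and report I/O.

Volumes travel as multi-page TIFF stacks (or directories of numbered
single-page TIFFs) with an optional JSON sidecar carrying the voxel
size and generation metadata.  Label volumes are unsigned-integer TIFF
with the class map {0: background, 1: cardiomyocyte, 2: collagen};
masks are 8-bit 0/255.  Reports are JSON, profiles CSV.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import Volume3D
from .mask import TissueMask
from .orientation import TransmuralProfile


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix \
        else path / "meta.json"


def write_volume(v: Volume3D, path, metadata: dict | None = None) -> None:
    """Write a volume as a multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(v.data), photometric="minisblack")
    meta = {"voxel_size_um": float(v.voxel_size),
            "origin_um": list(v.origin),
            "dtype": str(np.asarray(v.data).dtype)}
    meta.update(metadata or {})
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_volume(path, voxel_size: float | None = None) -> Volume3D:
    """Read a multi-page TIFF stack or a directory of numbered TIFFs.

    A sidecar ``<name>.json`` (or ``meta.json`` in a directory)
    overrides the ``voxel_size`` argument; with neither, the voxel size
    defaults to 1 um.  Round trips through :func:`write_volume` are
    lossless for float32 and 8/16-bit integer data.
    """
    path = Path(path)
    if path.is_dir():
        data = _read_numbered_dir(path)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 3D stack in {path}, got {data.ndim}D")
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    vs = meta.get("voxel_size_um", voxel_size)
    if vs is None:
        vs = 1.0
    origin = tuple(meta.get("origin_um", (0.0, 0.0, 0.0)))
    return Volume3D(data, float(vs), origin)


def _read_numbered_dir(path: Path) -> np.ndarray:
    pages = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff"))
    if not pages:
        raise ValueError(f"no TIFF pages found in {path}")
    nums = []
    for p in pages:
        m = re.search(r"(\d+)(?=\.[^.]+$)", p.name)
        if not m:
            raise ValueError(f"unnumbered page {p.name} in {path}")
        nums.append(int(m.group(1)))
    order = np.argsort(nums)
    nums = [nums[i] for i in order]
    pages = [pages[i] for i in order]
    expect = range(nums[0], nums[0] + len(nums))
    for n, e in zip(nums, expect):
        if n != e:
            raise ValueError(f"missing page {e} in numbered sequence in {path}")
    arrs = []
    for i, p in enumerate(pages):
        a = tifffile.imread(p)
        if arrs and a.shape != arrs[0].shape:
            raise ValueError(
                f"page {i} ({p.name}) shape {a.shape} differs from "
                f"page 0 shape {arrs[0].shape}")
        arrs.append(a)
    return np.stack(arrs, axis=0)


def write_mask(m: TissueMask, path) -> None:
    """Write a tissue mask as 8-bit TIFF (0/255) with a sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (m.data.astype(np.uint8) * 255),
                     photometric="minisblack")
    _sidecar(path).write_text(json.dumps(
        {"voxel_size_um": float(m.voxel_size),
         "provenance": m.provenance}, indent=2, sort_keys=True, default=float))


def read_mask(path) -> TissueMask:
    path = Path(path)
    data = tifffile.imread(path) > 0
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    return TissueMask(data, meta.get("voxel_size_um", 1.0),
                      provenance=meta.get("provenance", {}))


def write_profile_csv(profile: TransmuralProfile, path) -> None:
    """Transmural profile as CSV columns (d, HA_deg, n_voxels)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["d", "HA_deg", "n_voxels"])
        for d, ha, n in zip(profile.depth, profile.ha_deg, profile.n_voxels):
            w.writerow([f"{d:.6f}", "" if np.isnan(ha) else f"{ha:.4f}", n])


def write_report_json(report: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))


def load_config(path) -> dict:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
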