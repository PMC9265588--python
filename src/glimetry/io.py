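"""File formats: TIFF grids, JSON metadata, trace archives, CSV tables.

Grids travel as multi-page TIFF — 32-bit float for intensities and phase,
8-bit for label masks — with a JSON sidecar holding the acquisition
metadata and the stored shape.  Traces are JSON-lines
(``{"cell_id", "z", "xy": [[x, y], ...]}``) or ImageJ ROI zip archives
whose entries are named ``<cellID>-z<INDEX>.roi``.  All round trips are
lossless at the stored precision.
"""

from __future__ import annotations

import json
import re
import zipfile
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import imagej_roi
from .acquisition import AcquisitionConfig
from .reconstruct import PhaseTomogram
from .segment import CellMask, CellTrace
from .simulate import InterferogramStack


class FormatError(ValueError):
    """Raised on shape or schema mismatches between a TIFF and its metadata."""


def _sidecar(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(path: str | Path, stack: InterferogramStack) -> None:
    """4-frame stack as multi-page float32 TIFF, page order (z, frame 0..3)."""
    frames = stack.frames
    if frames.ndim == 3:  # single plane
        frames = frames[:, None]
    pages = np.transpose(frames, (1, 0, 2, 3)).reshape(-1, *frames.shape[-2:])
    tifffile.imwrite(path, pages.astype(np.float32), photometric="minisblack")
    meta = stack.config.to_dict()
    meta["shape_zyx"] = [frames.shape[1], frames.shape[2], frames.shape[3]]
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_stack(path: str | Path, meta_path: str | Path | None = None) -> InterferogramStack:
    pages = tifffile.imread(path)
    meta = json.loads(Path(meta_path or _sidecar(path)).read_text())
    for key in ("wavelength_um", "shear_um", "voxel_um", "phase_shifts", "shape_zyx"):
        if key not in meta:
            raise FormatError(f"metadata missing required key {key!r}")
    z, y, x = meta.pop("shape_zyx")
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape != (4 * z, y, x):
        raise FormatError(
            f"TIFF pages {pages.shape} do not match metadata shape "
            f"{(4 * z, y, x)} (z={z}, 4 frames per z)")
    frames = np.transpose(pages.reshape(z, 4, y, x), (1, 0, 2, 3)).astype(np.float64)
    config = AcquisitionConfig.from_dict(meta)
    return InterferogramStack(frames=frames, config=config)


def write_tomogram(path: str | Path, tomo: PhaseTomogram) -> None:
    phi = tomo.phi if tomo.phi.ndim == 3 else tomo.phi[None]
    tifffile.imwrite(path, phi.astype(np.float32), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "voxel_um": list(tomo.voxel_um),
        "shape_zyx": list(phi.shape),
        "provenance": tomo.provenance,
    }, indent=2))


def read_tomogram(path: str | Path, meta_path: str | Path | None = None) -> PhaseTomogram:
    phi = tifffile.imread(path)
    if phi.ndim == 2:
        phi = phi[None]
    meta = json.loads(Path(meta_path or _sidecar(path)).read_text())
    if "voxel_um" not in meta:
        raise FormatError("metadata missing required key 'voxel_um'")
    if tuple(meta.get("shape_zyx", phi.shape)) != phi.shape:
        raise FormatError(f"TIFF shape {phi.shape} != metadata shape "
                          f"{tuple(meta['shape_zyx'])}")
    return PhaseTomogram(phi=phi.astype(np.float64),
                         voxel_um=tuple(meta["voxel_um"]),
                         provenance=meta.get("provenance", {}))


def write_labels(path: str | Path, masks: list[CellMask]) -> None:
    """Masks as one 8-bit label TIFF plus a JSON label → cell_id map."""
    if not masks:
        raise ValueError("no masks to write")
    if len(masks) > 255:
        raise ValueError("8-bit label TIFF supports at most 255 cells")
    grid = np.zeros(masks[0].coarse.shape, dtype=np.uint8)
    mapping = {}
    for i, m in enumerate(masks, start=1):
        grid[m.best] = i
        mapping[str(i)] = m.cell_id
    tifffile.imwrite(path, grid, photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "labels": mapping,
        "voxel_um": list(masks[0].voxel_um),
        "shape_zyx": list(grid.shape),
    }, indent=2))


def read_labels(path: str | Path) -> list[CellMask]:
    grid = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    voxel = tuple(meta["voxel_um"])
    out = []
    for lab, cell_id in meta["labels"].items():
        m = grid == int(lab)
        out.append(CellMask(cell_id=cell_id, coarse=m, refined=m, voxel_um=voxel))
    return out


def write_traces_jsonl(path: str | Path, traces: list[CellTrace]) -> None:
    with open(path, "w") as fh:
        for t in traces:
            for z, xy in t.polygons:
                fh.write(json.dumps({"cell_id": t.cell_id, "z": z,
                                     "xy": np.asarray(xy).tolist()}) + "\n")


def read_traces_jsonl(path: str | Path, source: str = "manual") -> list[CellTrace]:
    polys: dict[str, list] = defaultdict(list)
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        polys[rec["cell_id"]].append((int(rec["z"]), np.asarray(rec["xy"])))
    return [CellTrace(cid, ps, source=source) for cid, ps in polys.items()]


_ROI_NAME = re.compile(r"^(?P<cell>.+)-z(?P<z>\d+)\.roi$")


def write_traces_roizip(path: str | Path, traces: list[CellTrace]) -> None:
    """ImageJ ROI zip archive, one polygon entry per traced slice."""
    with zipfile.ZipFile(path, "w") as zf:
        for t in traces:
            for z, xy in t.polygons:
                zf.writestr(f"{t.cell_id}-z{z}.roi", imagej_roi.encode_polygon(xy))


def read_traces_roizip(path: str | Path, source: str = "manual") -> list[CellTrace]:
    polys: dict[str, list] = defaultdict(list)
    with zipfile.ZipFile(path) as zf:
        for name in sorted(zf.namelist()):
            m = _ROI_NAME.match(Path(name).name)
            if m is None:
                raise FormatError(f"ROI entry {name!r} not named <cellID>-z<INDEX>.roi")
            xy = imagej_roi.decode_polygon(zf.read(name))
            polys[m["cell"]].append((int(m["z"]), xy))
    return [CellTrace(cid, ps, source=source) for cid, ps in polys.items()]


def read_traces(path: str | Path) -> list[CellTrace]:
    path = Path(path)
    if path.suffix == ".zip":
        return read_traces_roizip(path)
    return read_traces_jsonl(path)


def read_groups(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"cell_id", "animal_id", "group"} - set(df.columns)
    if missing:
        raise FormatError(f"groups CSV missing columns {sorted(missing)}")
    return df


def write_cells(path: str | Path, cells: pd.DataFrame) -> None:
    cells.to_csv(path, index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
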