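"""3D single-cell segmentation from sparse per-slice traces.

A cell is annotated by polygon outlines on a small number of z-slices
(manually, or derived from a colocalised fluorescence-like channel).  The
vertex point cloud, lifted to physical coordinates, is Delaunay-
triangulated and voxelised into a coarse convex mask; the mask is then
refined with the quantitative phase itself, discarding near-zero-phase
background voxels.  Negative-phase voxels are retained so that damaged,
phase-depleted cells remain measurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage import filters, measure

from .reconstruct import PhaseTomogram, _robust_sigma

log = logging.getLogger(__name__)


class DegenerateTraceError(ValueError):
    """Trace does not span a 3D volume (single plane or < 4 non-coplanar points)."""


@dataclass
class CellTrace:
    """Sparse polygon annotation of one cell.

    ``polygons`` maps z-slice index to an (N, 2) array of (x, y) vertices
    in pixel units of that slice.
    """

    cell_id: str
    polygons: list[tuple[int, np.ndarray]]
    source: str = "manual"  # or "fluorescence"

    def __post_init__(self) -> None:
        self.polygons = [(int(z), np.asarray(xy, dtype=np.float64))
                         for z, xy in self.polygons]
        zs = {z for z, _ in self.polygons}
        if len(zs) < 2:
            raise DegenerateTraceError(
                f"trace {self.cell_id!r} spans {len(zs)} z-slice(s); need >= 2")
        for z, xy in self.polygons:
            if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 3:
                raise ValueError(f"polygon at z={z} needs >= 3 (x, y) vertices")
            if not _ShapelyPolygon(xy).is_simple:
                raise ValueError(f"polygon at z={z} is self-intersecting")

    def z_indices(self) -> list[int]:
        return sorted({z for z, _ in self.polygons})

    def dilated(self, px: float) -> "CellTrace":
        """Grow every polygon outward by ``px`` pixels about its centroid."""
        out = []
        for z, xy in self.polygons:
            c = xy.mean(axis=0)
            d = xy - c
            r = np.linalg.norm(d, axis=1, keepdims=True)
            out.append((z, c + d * (1 + px / np.maximum(r, 1e-9))))
        return CellTrace(self.cell_id, out, self.source)


@dataclass
class CellMask:
    """Coarse (convex-hull) and phase-refined 3D boolean masks of one cell."""

    cell_id: str
    coarse: np.ndarray
    voxel_um: tuple[float, float, float]
    refined: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def best(self) -> np.ndarray:
        return self.refined if self.refined is not None else self.coarse

    def n_voxels(self, which: str = "refined") -> int:
        m = self.refined if which == "refined" else self.coarse
        if m is None:
            raise ValueError("mask has not been refined")
        return int(m.sum())


def voxelize_trace(
    trace: CellTrace,
    grid_shape: tuple[int, int, int],
    voxel_um: tuple[float, float, float],
) -> CellMask:
    """Coarse mask: voxels whose centres lie inside the Delaunay hull of the
    trace vertices lifted to physical coordinates (boundary counts inside)."""
    dx, dy, dz = voxel_um
    pts = []
    for z, xy in trace.polygons:
        for x, y in xy:
            pts.append((x * dx, y * dy, z * dz))
    pts = np.asarray(pts)
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise DegenerateTraceError(
            f"trace {trace.cell_id!r} has no 3D volume (coplanar/degenerate "
            f"vertices): {e}") from e
    # evaluate only within the vertex bounding box
    lo = np.floor(pts.min(axis=0) / (dx, dy, dz)).astype(int)
    hi = np.ceil(pts.max(axis=0) / (dx, dy, dz)).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, (grid_shape[2], grid_shape[1], grid_shape[0]))
    coarse = np.zeros(grid_shape, dtype=bool)
    if np.any(hi <= lo):
        return CellMask(trace.cell_id, coarse, voxel_um)
    xs = np.arange(lo[0], hi[0]) * dx
    ys = np.arange(lo[1], hi[1]) * dy
    zs = np.arange(lo[2], hi[2]) * dz
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    inside = tri.find_simplex(centers) >= 0
    coarse[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] = inside.reshape(zz.shape)
    return CellMask(trace.cell_id, coarse, voxel_um,
                    meta={"source": trace.source, "n_trace_slices": len(trace.z_indices())})


def phase_background_sigma(phase: PhaseTomogram, masks: list[CellMask] | None = None) -> float:
    """Robust (MAD-based) σ of the phase outside all coarse masks."""
    outside = np.ones(phase.phi.shape, dtype=bool)
    for m in masks or []:
        outside &= ~m.coarse
    if not outside.any():
        raise ValueError("no background voxels left outside the masks")
    return _robust_sigma(phase.phi[outside])


def default_phase_threshold(phase: PhaseTomogram, masks: list[CellMask] | None = None) -> float:
    """Default refinement threshold τ: 3× the robust background phase σ."""
    return 3.0 * phase_background_sigma(phase, masks)


def refine_mask(mask: CellMask, phase: PhaseTomogram, tau: float | None = None) -> CellMask:
    """Refined mask = coarse ∧ (|φ| > τ).

    Near-zero-phase (background) voxels are removed; negative-phase voxels
    are kept so damaged cells can still be quantified.  τ defaults to 3×
    the robust phase σ outside this cell's coarse mask.
    """
    if mask.coarse.shape != phase.phi.shape:
        raise ValueError(
            f"mask grid {mask.coarse.shape} != phase grid {phase.phi.shape}")
    if tau is None:
        tau = default_phase_threshold(phase, [mask])
    refined = mask.coarse & (np.abs(phase.phi) > tau)
    if not refined.any():
        warnings.warn(
            f"cell {mask.cell_id!r}: refinement removed every voxel "
            f"(tau={tau:.3g}); cell will be excluded downstream", stacklevel=2)
    meta = dict(mask.meta, tau=float(tau))
    return replace(mask, refined=refined, meta=meta)


def traces_from_fluorescence(
    label_channel: np.ndarray,
    threshold: float | str = "otsu",
    slice_step: int = 2,
    min_voxels: int = 30,
    max_vertices: int = 24,
) -> list[CellTrace]:
    """Derive coarse traces from a fluorescence-like channel.

    The channel is thresholded (Otsu by default), connected components are
    extracted, and each component's outline is sampled on every
    ``slice_step``-th occupied z-slice — mimicking coarse manual tracing.
    Touching somata may merge into one component; the count is then below
    the true number and a warning is logged.
    """
    chan = np.asarray(label_channel, dtype=np.float64)
    thr = filters.threshold_otsu(chan) if threshold == "otsu" else float(threshold)
    binary = chan > thr
    labelled, n = measure.label(binary, return_num=True, connectivity=3)
    traces: list[CellTrace] = []
    for k in range(1, n + 1):
        comp = labelled == k
        if comp.sum() < min_voxels:
            continue
        z_occ = np.flatnonzero(comp.any(axis=(1, 2)))
        z_pick = sorted(set(z_occ[::slice_step]) | {z_occ[0], z_occ[-1]})
        polys = []
        for z in z_pick:
            contours = measure.find_contours(comp[z].astype(float), 0.5)
            if not contours:
                continue
            c = max(contours, key=len)  # (row=y, col=x)
            step = max(1, len(c) // max_vertices)
            xy = c[::step][:, ::-1]
            if len(xy) >= 3:
                polys.append((int(z), xy))
        if len({z for z, _ in polys}) >= 2:
            traces.append(CellTrace(f"fluo-{len(traces) + 1}", polys,
                                    source="fluorescence"))
        else:
            log.info("fluorescence component %d too thin to trace; skipped", k)
    log.info("fluorescence tracing produced %d trace(s) from %d component(s)",
             len(traces), n)
    return traces
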