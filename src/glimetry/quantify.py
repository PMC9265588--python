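"""Per-cell volume, dry mass, density and damaged-cell classification.

Dry mass follows quantitative-phase densitometry: the phase of a voxel is
converted to a refractive-index contrast δn = φ·λ/(2π·ζ) — ζ being the
axial optical-section thickness, which prevents multi-counting a voxel's
contribution across the axial PSF support — and summed,

    m = (1/α) Σ_{r ∈ mask} δn(r) dV,

with α = 0.2 mL/g the refractive-index increment of cellular dry matter.
Negative totals are allowed and mark "damaged" cells whose content is
less dense than the surrounding tissue.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig
from .reconstruct import PhaseTomogram
from .segment import CellMask
from .units import G_PER_L_PER_PG_PER_UM3, UM3_PER_ML

log = logging.getLogger(__name__)

DEFAULT_ALPHA_ML_PER_G = 0.2


@dataclass
class CellRecord:
    """One quantified cell: morphology, mass and grouping metadata."""

    cell_id: str
    animal_id: str
    group: str                    # "day" | "night"
    volume_um3: float
    dry_mass_pg: float
    density_g_per_L: float
    damaged: bool
    n_voxels: int
    n_voxels_coarse: int
    mean_phase_rad: float
    Vm_mV: float | None = None
    Rin_MOhm: float | None = None


def compute_volume(mask: CellMask, which: str = "refined") -> float:
    """Volume (µm³) = refined voxel count × voxel volume."""
    m = mask.refined if which == "refined" else mask.coarse
    if m is None:
        raise ValueError(f"cell {mask.cell_id!r}: mask has not been refined")
    dx, dy, dz = mask.voxel_um
    n = int(m.sum())
    if n == 0:
        warnings.warn(f"cell {mask.cell_id!r}: empty mask, volume 0", stacklevel=2)
    return n * dx * dy * dz


def compute_dry_mass(
    mask: CellMask,
    phase: PhaseTomogram,
    alpha_ml_per_g: float = DEFAULT_ALPHA_ML_PER_G,
    config: AcquisitionConfig | None = None,
    *,
    wavelength_um: float | None = None,
    axial_psf_um: float | None = None,
    axial_norm: str = "psf",
) -> float:
    """Dry mass (pg) of the in-mask phase.

    ``axial_norm='psf'`` (default) applies the optical-section
    normalisation δn = φ·λ/(2π·ζ) per voxel and integrates over the 3D
    mask.  ``axial_norm='slice2d'`` instead integrates φ over the single
    best-focus slice, m = λ/(2π·α)·Σ φ dA.
    """
    if alpha_ml_per_g <= 0:
        raise ValueError("alpha must be positive")
    if config is not None:
        wavelength_um = wavelength_um or config.wavelength_um
        axial_psf_um = axial_psf_um or config.axial_psf_um
    if wavelength_um is None or (axial_norm == "psf" and axial_psf_um is None):
        raise ValueError("wavelength_um and axial_psf_um metadata are required "
                         "(pass an AcquisitionConfig or the values explicitly)")
    m = mask.best
    if m.shape != phase.phi.shape:
        raise ValueError(f"mask grid {m.shape} != phase grid {phase.phi.shape}")
    dx, dy, dz = mask.voxel_um
    alpha_um3_per_pg = alpha_ml_per_g * UM3_PER_ML * 1e-12  # µm³ per pg
    if axial_norm == "psf":
        delta_n = phase.phi * wavelength_um / (2 * np.pi * axial_psf_um)
        return float(delta_n[m].sum() * dx * dy * dz / alpha_um3_per_pg)
    if axial_norm == "slice2d":
        per_slice = np.array([phase.phi[z][m[z]].sum() for z in range(m.shape[0])])
        z_best = int(np.argmax(np.abs(per_slice)))
        opl_sum_um = per_slice[z_best] * wavelength_um / (2 * np.pi)
        return float(opl_sum_um * dx * dy / alpha_um3_per_pg)
    raise ValueError(f"unknown axial_norm {axial_norm!r}")


def build_cell_table(
    masks: list[CellMask],
    phase: PhaseTomogram,
    groups: pd.DataFrame,
    config: AcquisitionConfig,
    alpha_ml_per_g: float = DEFAULT_ALPHA_ML_PER_G,
    axial_norm: str = "psf",
) -> pd.DataFrame:
    """Join refined masks with the (cell_id, animal_id, group) table into one
    :class:`CellRecord` row per non-empty mask, ordered by (animal_id, cell_id).

    Empty refined masks are logged and dropped; a mask without a matching
    grouping row is an error listing the offenders.
    """
    required = {"cell_id", "animal_id", "group"}
    if not required.issubset(groups.columns):
        raise ValueError(f"groups table must have columns {sorted(required)}")
    gidx = groups.set_index("cell_id")
    missing = [m.cell_id for m in masks if m.cell_id not in gidx.index]
    if missing:
        raise KeyError(f"cells without a grouping row: {missing}")
    rows = []
    for mask in masks:
        if mask.refined is None or not mask.refined.any():
            log.warning("cell %r excluded: empty refined mask", mask.cell_id)
            continue
        info = gidx.loc[mask.cell_id]
        vol = compute_volume(mask)
        mass = compute_dry_mass(mask, phase, alpha_ml_per_g, config,
                                axial_norm=axial_norm)
        rows.append(CellRecord(
            cell_id=str(mask.cell_id),
            animal_id=str(info["animal_id"]),
            group=str(info["group"]),
            volume_um3=vol,
            dry_mass_pg=mass,
            density_g_per_L=mass / vol * G_PER_L_PER_PG_PER_UM3,
            damaged=bool(mass < 0),
            n_voxels=int(mask.refined.sum()),
            n_voxels_coarse=int(mask.coarse.sum()),
            mean_phase_rad=float(phase.phi[mask.refined].mean()),
            Vm_mV=float(info["Vm_mV"]) if "Vm_mV" in info and pd.notna(info["Vm_mV"]) else None,
            Rin_MOhm=float(info["Rin_MOhm"]) if "Rin_MOhm" in info and pd.notna(info["Rin_MOhm"]) else None,
        ))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df):
        df = df.sort_values(["animal_id", "cell_id"]).reset_index(drop=True)
    return df
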