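"""Acquisition geometry and interferometric modulation settings.

A GLIM acquisition is characterised by the illumination wavelength, the
lateral shear between the two orthogonally polarised beams, the voxel
spacing of the tomographic grid, the axial extent of the optical section,
and the four liquid-crystal phase shifts (0, π/2, π, 3π/2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

_QUARTER_SHIFTS = (0.0, math.pi / 2, math.pi, 3 * math.pi / 2)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Optical and sampling parameters of a 4-frame GLIM acquisition.

    Parameters
    ----------
    wavelength_um
        Centre wavelength of the (IR LED) illumination, µm.
    shear_um
        Lateral offset δx between the two sheared fields, µm. Default is
        half the 0.75 µm lateral resolution of the reference instrument.
    voxel_um
        (dx, dy, dz) voxel spacing of the tomogram grid, µm.
    axial_psf_um
        Full width of the axial sectioning kernel (axial resolution), µm.
    phase_shifts
        The four modulation offsets ε_n; must equal nπ/2 to 1e-12.
    na, condenser_na
        Objective and condenser numerical apertures; used only for the
        diffraction-limit reference frequency in spectral QC.
    seed
        Seed for any stochastic simulation tied to this acquisition.
    """

    wavelength_um: float = 0.780
    shear_um: float = 0.375
    voxel_um: tuple[float, float, float] = (0.25, 0.25, 1.0)
    axial_psf_um: float = 1.5
    phase_shifts: tuple[float, float, float, float] = _QUARTER_SHIFTS
    na: float = 0.75
    condenser_na: float = 0.55
    seed: int = 0
    flip_gradient_sign: bool = False

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength must be positive")
        if self.shear_um <= 0:
            raise ValueError("shear must be positive")
        if len(self.voxel_um) != 3 or any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel_um must be three positive lengths")
        if self.axial_psf_um <= 0:
            raise ValueError("axial_psf_um must be positive")
        if len(self.phase_shifts) != 4:
            raise ValueError("exactly four phase shifts are required")
        if any(abs(e - q) > 1e-12 for e, q in zip(self.phase_shifts, _QUARTER_SHIFTS)):
            raise ValueError("phase shifts must be 0, pi/2, pi, 3pi/2")

    @property
    def shear_px(self) -> float:
        """Shear expressed in pixels of the lateral (x) grid."""
        return self.shear_um / self.voxel_um[0]

    @property
    def diffraction_limit_cyc_per_um(self) -> float:
        """Partially coherent lateral cutoff frequency (NA_obj + NA_cond)/λ."""
        return (self.na + self.condenser_na) / self.wavelength_um

    def to_dict(self) -> dict:
        d = asdict(self)
        d["voxel_um"] = list(self.voxel_um)
        d["phase_shifts"] = list(self.phase_shifts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        d = dict(d)
        if "voxel_um" in d:
            d["voxel_um"] = tuple(d["voxel_um"])
        if "phase_shifts" in d:
            d["phase_shifts"] = tuple(d["phase_shifts"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed + salt) % (2**31))
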