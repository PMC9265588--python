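"""Forward optical model and synthetic-data generator.

Builds refractive-index phantoms that emulate astrocyte somata in a
scattering acute-slice background, renders the quantitative phase the
microscope would section optically, and synthesises the four
phase-shifted interferograms

    I_n(r) = I + I' + 2 γ cos(Δφ(r) + ε_n),   ε_n = nπ/2,

that the reconstruction module consumes — with exact per-cell ground
truth (volume, dry mass) for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .acquisition import AcquisitionConfig
from .reconstruct import PhaseTomogram

log = logging.getLogger(__name__)

#: refractive-index increment (mL/g) used to convert phantom δn to truth mass
DEFAULT_ALPHA_ML_PER_G = 0.2


class PhantomPlacementError(RuntimeError):
    """Raised when the requested number of non-overlapping cells does not fit."""


class ShearSamplingError(ValueError):
    """Raised when the shear is below one pixel on the current grid."""


@dataclass
class Phantom:
    """Ground-truth refractive-index field with per-cell labels.

    ``delta_n`` is the index contrast n(r) − n0 on a (Z, Y, X) grid;
    ``labels`` assigns voxels to cells (0 = background); ``cell_truth``
    tabulates exact per-cell volume (µm³) and dry mass (pg).
    """

    delta_n: np.ndarray
    labels: np.ndarray
    cell_truth: pd.DataFrame
    config: AcquisitionConfig
    n0: float = 1.337
    background_texture_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta_n.shape != self.labels.shape:
            raise ValueError("delta_n and labels must share a shape")


@dataclass
class InterferogramStack:
    """Four phase-shifted intensity frames, frame n at offset ε_n = nπ/2."""

    frames: np.ndarray  # (4, Z, Y, X) or (4, Y, X)
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.shape[0] != 4:
            raise ValueError("frames axis must have length 4")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")


def _ellipsoid_rho(shape, center_vox, radii_um, voxel_um):
    """Normalised ellipsoid radius field over the bounding box; returns
    (slices, rho) with rho evaluated at voxel centres."""
    dz, dy, dx = voxel_um[2], voxel_um[1], voxel_um[0]
    spac = np.array([dz, dy, dx])
    half_vox = np.ceil(np.asarray(radii_um) / spac).astype(int) + 1
    lo = np.maximum(np.asarray(center_vox, int) - half_vox, 0)
    hi = np.minimum(np.asarray(center_vox, int) + half_vox + 1, shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    zz, yy, xx = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    rho = np.sqrt(
        ((zz - center_vox[0]) * dz / radii_um[0]) ** 2
        + ((yy - center_vox[1]) * dy / radii_um[1]) ** 2
        + ((xx - center_vox[2]) * dx / radii_um[2]) ** 2
    )
    return sl, rho


def make_phantom(
    shape: tuple[int, int, int],
    n_cells: int,
    mean_radius_um: float = 4.0,
    volume_scale: float = 1.0,
    config: AcquisitionConfig | None = None,
    *,
    delta_n_cell: float = 0.02,
    constant_mass: bool = True,
    background_amplitude: float = 0.002,
    background_corr_um: float = 2.0,
    edge_width: float = 0.05,
    rng: np.random.Generator | None = None,
    max_tries: int = 200,
) -> Phantom:
    """Generate soma-like ellipsoidal inclusions over a correlated background.

    ``volume_scale`` rescales cell volumes (night groups use < 1); with
    ``constant_mass`` the interior index contrast is scaled by
    1/volume_scale so that ground-truth dry mass is invariant — the
    constant-dry-mass volume regulation the cohort studies emulate.

    Raises :class:`PhantomPlacementError` if ``n_cells`` non-overlapping
    cells cannot be placed within ``max_tries`` attempts per cell.
    """
    config = config or AcquisitionConfig()
    if any(s <= 0 for s in shape):
        raise ValueError("shape must be positive")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if volume_scale <= 0:
        raise ValueError("volume_scale must be positive")
    rng = rng if rng is not None else config.rng()
    dx, dy, dz = config.voxel_um
    shape = tuple(int(s) for s in shape)

    # correlated zero-mean background texture (tissue scattering surrogate)
    sigma_vox = np.array([background_corr_um / dz, background_corr_um / dy,
                          background_corr_um / dx])
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = texture.std()
    if sd > 0 and background_amplitude > 0:
        texture *= background_amplitude / sd
        texture -= texture.mean()
    else:
        texture = np.zeros(shape)

    labels = np.zeros(shape, dtype=np.int32)
    cells = np.zeros(shape, dtype=np.float64)
    dn_eff = delta_n_cell / volume_scale if constant_mass else delta_n_cell
    base_radius = mean_radius_um * volume_scale ** (1.0 / 3.0)
    rows = []
    voxel_vol = dx * dy * dz
    for k in range(1, n_cells + 1):
        placed = False
        for _ in range(max_tries):
            radii = base_radius * rng.uniform(0.85, 1.15, size=3)  # (rz, ry, rx)
            margin_vox = np.ceil(np.array([radii[0] / dz, radii[1] / dy,
                                           radii[2] / dx])).astype(int) + 1
            if np.any(2 * margin_vox >= shape):
                raise PhantomPlacementError(
                    f"cell radius {base_radius:.2f} µm does not fit grid {shape}")
            center = np.array([rng.integers(m, s - m) for m, s in zip(margin_vox, shape)])
            sl, rho = _ellipsoid_rho(shape, center, radii, config.voxel_um)
            inside = rho <= 1.0
            clearance = rho <= 1.15
            if np.any(labels[sl][clearance]):
                continue
            labels[sl][inside] = k
            cells[sl] += dn_eff * np.clip((1.0 - rho) / edge_width, 0.0, 1.0)
            n_vox = int(inside.sum())
            mass_pg = float(cells[sl][inside].sum() * voxel_vol / DEFAULT_ALPHA_ML_PER_G)
            rows.append({"cell_id": f"cell-{k}", "label": k,
                         "volume_um3": n_vox * voxel_vol, "drymass_pg": mass_pg,
                         "n_voxels": n_vox,
                         "center_zyx": tuple(int(c) for c in center)})
            placed = True
            break
        if not placed:
            raise PhantomPlacementError(
                f"placed only {k - 1} of {n_cells} cells without overlap")
    cell_truth = pd.DataFrame(
        rows, columns=["cell_id", "label", "volume_um3", "drymass_pg",
                       "n_voxels", "center_zyx"])
    return Phantom(
        delta_n=texture + cells, labels=labels, cell_truth=cell_truth,
        config=config, background_texture_params={
            "amplitude": background_amplitude, "corr_um": background_corr_um})


def _axial_kernel(axial_psf_um: float, dz: float) -> np.ndarray:
    """Triangular sectioning kernel of full width axial_psf, unit integral."""
    half = axial_psf_um / 2.0
    m = int(np.ceil(half / dz))
    s = np.arange(-m, m + 1) * dz
    w = np.clip(1.0 - np.abs(s) / half, 0.0, None)
    if w.sum() == 0:
        w = np.array([1.0])
    return w / (w.sum() * dz)


def project_phase(phantom: Phantom, config: AcquisitionConfig | None = None) -> PhaseTomogram:
    """Optically sectioned phase: per slice z,

        φ(x,y,z) = (2π/λ) · ζ · Σ_z' δn(x,y,z') w(z−z') dz,

    with w a normalised triangular kernel of full width ζ = axial_psf, so
    that a homogeneous slab thicker than the kernel yields the slab phase
    2π·δn·ζ/λ at its centre."""
    config = config or phantom.config
    dz = config.voxel_um[2]
    zeta = config.axial_psf_um
    w = _axial_kernel(zeta, dz)
    smoothed = ndimage.convolve1d(phantom.delta_n, w, axis=0, mode="constant", cval=0.0)
    phi = (2 * np.pi / config.wavelength_um) * zeta * smoothed * dz
    return PhaseTomogram(phi=phi, voxel_um=config.voxel_um,
                         provenance={"source": "project_phase",
                                     "axial_psf_um": zeta})


def shift_along_shear(phi: np.ndarray, shear_px: float) -> np.ndarray:
    """φ(r + δ): shift the phase field by the shear along x.

    Integer shifts replicate the edge column; fractional shifts use
    Fourier interpolation (periodic)."""
    if abs(shear_px - round(shear_px)) < 1e-9:
        k = int(round(shear_px))
        if k == 0:
            return phi.copy()
        out = np.empty_like(phi)
        out[..., :-k] = phi[..., k:]
        out[..., -k:] = phi[..., -1:]
        return out
    freq = np.fft.fftfreq(phi.shape[-1])
    return np.fft.ifft(np.fft.fft(phi, axis=-1)
                       * np.exp(2j * np.pi * freq * shear_px), axis=-1).real


def simulate_interferograms(
    phase: PhaseTomogram,
    gamma: float | np.ndarray = 1.0,
    base_intensity: float | np.ndarray = 1.0,
    config: AcquisitionConfig | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    incoherent_background: float | np.ndarray = 0.0,
) -> InterferogramStack:
    """Render the four phase-shifted frames of the interference model.

    ``incoherent_background`` adds a common (unmodulated) offset to every
    frame — the multiple-scattering halo that phase retrieval rejects.
    """
    config = config or AcquisitionConfig(voxel_um=phase.voxel_um)
    if np.any(np.asarray(gamma) < 0):
        raise ValueError("gamma must be non-negative")
    if np.any(np.asarray(base_intensity) <= 0):
        raise ValueError("base_intensity must be positive")
    s_px = config.shear_px
    if s_px < 1.0 - 1e-9:
        raise ShearSamplingError(
            f"shear of {config.shear_um} µm is {s_px:.2f} px on a "
            f"{config.voxel_um[0]} µm grid; supersample the lateral grid so "
            "the shear spans at least one pixel")
    phi = phase.phi
    delta_phi = shift_along_shear(phi, s_px) - phi
    eps = np.asarray(config.phase_shifts)
    frames = np.stack([
        2.0 * np.asarray(base_intensity)
        + np.asarray(incoherent_background)
        + 2.0 * np.asarray(gamma) * np.cos(delta_phi + e)
        for e in eps
    ])
    if noise_sd > 0:
        rng = rng if rng is not None else config.rng(salt=1)
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return InterferogramStack(frames=np.clip(frames, 0.0, None), config=config)


def fluorescence_channel(
    phantom: Phantom,
    blur_px: float = 1.0,
    photons: float = 80.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """SR101-like label channel: blurred cell occupancy with Poisson noise."""
    rng = rng if rng is not None else phantom.config.rng(salt=2)
    body = ndimage.gaussian_filter((phantom.labels > 0).astype(np.float64), blur_px)
    return rng.poisson(photons * body).astype(np.float64)
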