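"""Phase retrieval from 4-frame GLIM stacks.

The four interferograms recorded at modulation offsets ε_n = nπ/2,

    I_n(r) = I(r) + I(r+δ) + 2 γ(r) cos(Δφ(r) + ε_n),

determine the sheared phase difference Δφ = φ(r+δ) − φ(r) and the mutual
intensity γ through two pairwise frame subtractions,

    Δφ = atan2(I_3 − I_1, I_0 − I_2),   γ = ¼ √((I_0−I_2)² + (I_3−I_1)²).

Any additive background that is common to the four frames — the incoherent
multiple-scattering halo of a thick slice — cancels exactly in the
subtractions; this is the background rejection that distinguishes GLIM from
plain DIC.  Δφ/δx approximates the phase gradient along the shear, which a
regularised spectral (Hilbert-transform) division integrates back to the
quantitative phase φ, defined up to a per-slice additive constant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig

log = logging.getLogger(__name__)


@dataclass
class PhaseTomogram:
    """Quantitative phase per voxel (radians) on a physical grid."""

    phi: np.ndarray  # (Z, Y, X) or (Y, X)
    voxel_um: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64)
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phase tomogram must be finite everywhere")

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.voxel_um
        return dx * dy * dz


@dataclass
class PhaseGradientMap:
    """Sheared phase difference, gradient and fringe modulation per pixel."""

    grad_x: np.ndarray          # rad/µm
    delta_phi: np.ndarray       # rad, wrapped to (−π, π]
    gamma: np.ndarray           # intensity units, ≥ 0
    modulation_ok: np.ndarray   # bool
    config: AcquisitionConfig


def _border_mask(shape: tuple[int, int], width: int) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[:width, :] = m[-width:, :] = True
    m[:, :width] = m[:, -width:] = True
    return m


def _robust_sigma(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=np.float64).ravel()
    return 1.4826 * float(np.median(np.abs(v - np.median(v))))


def default_modulation_threshold(gamma: np.ndarray, border_px: int | None = None) -> float:
    """2× the robust noise level of γ estimated in an image border ring."""
    g = gamma if gamma.ndim == 2 else gamma.reshape(-1, *gamma.shape[-2:])[0]
    if border_px is None:
        border_px = max(4, min(g.shape) // 20)
    return 2.0 * _robust_sigma(gamma[..., _border_mask(gamma.shape[-2:], border_px)])


def retrieve_phase_gradient(
    stack, tau_mod: Optional[float] = None
) -> PhaseGradientMap:
    """Solve the 4-frame interference model for Δφ, γ and the phase gradient.

    Pixels whose fringe modulation γ does not exceed ``tau_mod`` (default:
    2× the robust γ noise in the image border) are flagged in
    ``modulation_ok`` and their Δφ set to 0.
    """
    frames = np.asarray(stack.frames, dtype=np.float64)
    config = stack.config
    if frames.shape[0] != 4:
        raise ValueError(f"expected 4 frames, got {frames.shape[0]}")
    i0, i1, i2, i3 = frames
    cos_term = i0 - i2          # 4 γ cos Δφ
    sin_term = i3 - i1          # 4 γ sin Δφ
    gamma = 0.25 * np.hypot(cos_term, sin_term)
    delta_phi = np.arctan2(sin_term, cos_term)
    delta_phi[delta_phi <= -np.pi] = np.pi  # wrap convention (−π, π]
    if config.flip_gradient_sign:
        delta_phi = -delta_phi

    if not np.any(gamma > 0):
        warnings.warn("all-zero fringe modulation: no usable pixels", stacklevel=2)
        tau = 0.0
        ok = np.zeros_like(gamma, dtype=bool)
    else:
        tau = default_modulation_threshold(gamma) if tau_mod is None else float(tau_mod)
        ok = gamma > tau
    delta_phi = np.where(ok, delta_phi, 0.0)
    grad_x = delta_phi / config.shear_um
    return PhaseGradientMap(grad_x=grad_x, delta_phi=delta_phi, gamma=gamma,
                            modulation_ok=ok, config=config)


def integrate_gradient_hilbert(
    gmap: PhaseGradientMap | np.ndarray,
    config: AcquisitionConfig | None = None,
    eta: float = 1e-3,
) -> PhaseTomogram:
    """Integrate ∇xφ to φ by regularised spectral division along x.

    Per slice: Φ(kx) = G(kx) / (i·kx + η·k_Nyq), with the DC component set
    to zero.  Integration along x leaves one additive constant per image
    row undetermined (the kx = 0 column carries no gradient information);
    that gauge is fixed by the physical property that most of every row is
    background with phase near zero: the row median is subtracted.  The
    remaining per-slice spatial mean is then removed — the global additive
    constant of an integrated gradient is not observable.
    """
    if isinstance(gmap, PhaseGradientMap):
        grad = np.asarray(gmap.grad_x, dtype=np.float64)
        config = gmap.config
    else:
        grad = np.asarray(gmap, dtype=np.float64)
        if config is None:
            raise ValueError("config required when passing a bare gradient array")
    if not np.all(np.isfinite(grad)):
        raise ValueError("gradient must be finite")
    nx = grad.shape[-1]
    if nx < 2:
        raise ValueError("x dimension must have at least 2 pixels to integrate")
    dx = config.voxel_um[0]
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=dx)
    k_nyq = np.pi / dx
    denom = 1j * kx + eta * k_nyq
    g_hat = np.fft.fft(grad, axis=-1)
    phi_hat = g_hat / denom
    phi_hat[..., kx == 0] = 0.0
    phi = np.fft.ifft(phi_hat, axis=-1).real
    phi -= np.median(phi, axis=-1, keepdims=True)  # row gauge: background → 0
    phi -= phi.mean(axis=(-2, -1), keepdims=True)
    return PhaseTomogram(
        phi=phi,
        voxel_um=config.voxel_um,
        provenance={"method": "hilbert_spectral", "eta": eta,
                    "shear_um": config.shear_um},
    )


def radial_power_spectrum(
    image: np.ndarray, config: AcquisitionConfig | None = None
) -> pd.DataFrame:
    """Radially averaged power spectrum, log-scaled and normalised to unit max.

    Returns a DataFrame with columns ``freq_cyc_per_um``, ``power`` and
    ``log_power_norm`` (log10 of power normalised to its maximum).  The
    partially coherent diffraction-limit frequency for the configured
    apertures is stored in ``df.attrs['diffraction_limit_cyc_per_um']``.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    config = config or AcquisitionConfig()
    dy, dx = config.voxel_um[1], config.voxel_um[0]
    power = np.abs(np.fft.fftshift(np.fft.fft2(img))) ** 2
    fy = np.fft.fftshift(np.fft.fftfreq(img.shape[0], d=dy))
    fx = np.fft.fftshift(np.fft.fftfreq(img.shape[1], d=dx))
    fr = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    df_bin = max(fx[1] - fx[0], fy[1] - fy[0])
    bins = np.round(fr / df_bin).astype(int)
    n = np.bincount(bins.ravel())
    p = np.bincount(bins.ravel(), weights=power.ravel()) / n
    freq = np.arange(len(p)) * df_bin
    p_norm = p / p.max() if p.max() > 0 else p
    with np.errstate(divide="ignore"):
        logp = np.log10(p_norm, where=p_norm > 0, out=np.full_like(p_norm, -np.inf))
    out = pd.DataFrame({"freq_cyc_per_um": freq, "power": p, "log_power_norm": logp})
    out.attrs["diffraction_limit_cyc_per_um"] = config.diffraction_limit_cyc_per_um
    return out


def high_frequency_power_fraction(
    image: np.ndarray, config: AcquisitionConfig, freq_cyc_per_um: float | None = None
) -> float:
    """Fraction of non-DC spectral power above a frequency (default: half the
    diffraction limit).  Used as the contrast QC contrasting GLIM vs DIC."""
    spec = radial_power_spectrum(image, config)
    if freq_cyc_per_um is None:
        freq_cyc_per_um = 0.5 * spec.attrs["diffraction_limit_cyc_per_um"]
    nondc = spec["freq_cyc_per_um"] > 0
    total = spec.loc[nondc, "power"].sum()
    high = spec.loc[nondc & (spec["freq_cyc_per_um"] >= freq_cyc_per_um), "power"].sum()
    return float(high / total) if total > 0 else 0.0
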