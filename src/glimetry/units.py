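"""Unit conversions used throughout the package.

Conventions: phase in radians, lengths in micrometres (µm), dry mass in
picograms (pg), mass density in grams per litre (g/L), refractive-index
increment alpha in mL/g.

1 pg/µm³ = 1000 g/L; 1 mL = 1e12 µm³; 1 µm³ = 1e-15 L.
"""

from __future__ import annotations

import math

UM3_PER_ML = 1.0e12
L_PER_UM3 = 1.0e-15
G_PER_PG = 1.0e-12
G_PER_L_PER_PG_PER_UM3 = 1000.0


def density_g_per_L(mass_pg: float, volume_um3: float) -> float:
    """Mass density in g/L of a cell of given dry mass (pg) and volume (µm³)."""
    if volume_um3 <= 0:
        raise ValueError("density is defined only for positive volume")
    return mass_pg / volume_um3 * G_PER_L_PER_PG_PER_UM3


def density_from_slope(slope_L_per_g: float) -> float:
    """Density (g/L) as the reciprocal of a volume-vs-mass slope (L/g)."""
    if slope_L_per_g == 0:
        raise ValueError("slope must be non-zero")
    return 1.0 / slope_L_per_g


def round_sig(x: float, sig: int = 2) -> float:
    """Round to `sig` significant figures (display convention for densities)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
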