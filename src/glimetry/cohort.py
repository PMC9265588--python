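"""Record-level synthetic cohorts for the day/night statistics.

Emulates the study design — two groups of animals, several cells per
animal — with the biology the imaging study established: nocturnal cell
volumes scaled down at constant dry mass, so that volume regulation is
purely aqueous.  Cell dry masses are lognormal around a soma-scale mean
with an animal-level random effect; the volume of each cell follows its
mass through the group's effective density, with extra cell-level noise.

These cohorts feed the statistical layer directly (no image simulation),
which is what makes repeated power / type-I studies affordable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .units import G_PER_L_PER_PG_PER_UM3

#: defaults representing a realistic astrocyte-soma cohort
DEFAULTS = dict(
    n_animals_per_group=9,
    cells_per_animal=7,
    mean_mass_pg=500.0,          # ~520 µm³ soma at ~960 g/L
    day_density_g_per_L=980.0,
    night_volume_scale=0.75,     # 25% nocturnal volume reduction
    mass_cv=0.15,                # within-animal lognormal mass spread
    animal_sd_log=0.06,          # between-animal random effect (log scale)
    volume_noise_sd_log=0.08,    # cell-level volume noise beyond mass
)


def simulate_cohort(
    seed: int | np.random.Generator = 0,
    n_animals_per_group: int = DEFAULTS["n_animals_per_group"],
    cells_per_animal: int = DEFAULTS["cells_per_animal"],
    mean_mass_pg: float = DEFAULTS["mean_mass_pg"],
    day_density_g_per_L: float = DEFAULTS["day_density_g_per_L"],
    night_volume_scale: float = DEFAULTS["night_volume_scale"],
    mass_cv: float = DEFAULTS["mass_cv"],
    animal_sd_log: float = DEFAULTS["animal_sd_log"],
    volume_noise_sd_log: float = DEFAULTS["volume_noise_sd_log"],
) -> pd.DataFrame:
    """Simulate per-cell records (same columns as the imaging cell table).

    Night volumes are scaled by ``night_volume_scale`` at unchanged dry
    mass; ``night_volume_scale=1`` gives a null cohort for type-I studies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma_mass = np.sqrt(np.log1p(mass_cv**2))
    rows = []
    for group, scale in (("day", 1.0), ("night", night_volume_scale)):
        for a in range(n_animals_per_group):
            animal_id = f"{group}-a{a + 1}"
            u = rng.normal(0.0, animal_sd_log)
            for c in range(cells_per_animal):
                mass_pg = mean_mass_pg * np.exp(u + rng.normal(0.0, sigma_mass))
                base_vol = mass_pg / day_density_g_per_L * G_PER_L_PER_PG_PER_UM3
                vol_um3 = base_vol * scale * np.exp(rng.normal(0.0, volume_noise_sd_log))
                rows.append({
                    "cell_id": f"{animal_id}-c{c + 1}",
                    "animal_id": animal_id,
                    "group": group,
                    "volume_um3": vol_um3,
                    "dry_mass_pg": mass_pg,
                    "density_g_per_L": mass_pg / vol_um3 * G_PER_L_PER_PG_PER_UM3,
                    "damaged": False,
                })
    return pd.DataFrame(rows)
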