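"""Segment cells from a fluorescence-like channel and measure dry mass.

Runs the measurement chain the instrument workflow uses: coarse traces from
the colocalised fluorescence channel, Delaunay voxelization, phase-threshold
refinement, then per-cell volume (µm³), dry mass (pg) and density (g/L).
"""

import numpy as np
import pandas as pd

import glimetry as g

cfg = g.AcquisitionConfig(seed=7)
rng = cfg.rng()

phantom = g.make_phantom((24, 320, 320), n_cells=4, config=cfg, rng=rng)
stack = g.simulate_interferograms(g.project_phase(phantom, cfg),
                                  config=cfg, noise_sd=0.01, rng=rng)
recon = g.integrate_gradient_hilbert(g.retrieve_phase_gradient(stack))

fluo = g.fluorescence_channel(phantom, rng=rng)
traces = g.traces_from_fluorescence(fluo)
masks = [g.voxelize_trace(t, recon.phi.shape, cfg.voxel_um) for t in traces]
tau = g.default_phase_threshold(recon, masks)
masks = [g.refine_mask(m, recon, tau) for m in masks]
print(f"{len(masks)} cells traced; refinement threshold tau = {tau:.3f} rad")

groups = pd.DataFrame({"cell_id": [m.cell_id for m in masks],
                       "animal_id": "demo-animal", "group": "day"})
cells = g.build_cell_table(masks, recon, groups, cfg)
print(cells[["cell_id", "volume_um3", "dry_mass_pg",
             "density_g_per_L", "damaged"]].round(2).to_string(index=False))
truth = phantom.cell_truth
print(f"\nground truth: median volume {truth.volume_um3.median():.1f} µm³, "
      f"median mass {truth.drymass_pg.median():.2f} pg")
print(f"recovered:    median volume {cells.volume_um3.median():.1f} µm³, "
      f"median mass {cells.dry_mass_pg.median():.2f} pg")
# Volumes and masses land within ~10% of truth; density ~100 g/L reflects
# the phantom's delta-n of 0.02 at alpha = 0.2 mL/g.
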