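# glimetry

Quantitative phase tomography and single-cell dry-mass densitometry for
**gradient light interference microscopy (GLIM)** — aimed at researchers
measuring cell morphology inside thick, strongly scattering live tissue
(e.g. astrocyte somata in acute brain slices), where ordinary DIC gives
only qualitative contrast.

GLIM upgrades a DIC microscope with four controlled phase shifts
ε_n = nπ/2 between the two sheared beams. From the four interferograms

    I_n(r) = I(r) + I(r+δ) + 2 γ(r) cos(Δφ(r) + ε_n),

the package retrieves the sheared phase difference and fringe modulation

    Δφ = atan2(I₃ − I₁, I₀ − I₂),   γ = ¼ √((I₀−I₂)² + (I₃−I₁)²),

(incoherent background offsets cancel exactly in the subtractions),
integrates the phase gradient ∇xφ ≈ Δφ/δx to a quantitative phase
tomogram by a regularised spectral (Hilbert) division, segments single
cells in 3D from sparse polygon traces (Delaunay voxelization + phase-
threshold refinement), and converts masked phase to biophysics:

    volume V = N_voxels · dV,
    dry mass m = (1/α) Σ_mask δn·dV   with δn = φ·λ/(2π·ζ),  α = 0.2 mL/g,
    density ρ = m/V  (g/L),           damaged ⇔ m < 0.

Day-vs-night cohorts are compared with both an exact Mann-Whitney U test
and a one-way mixed-model ANOVA (animal as random intercept, REML), plus
the per-group volume-vs-mass regression whose reciprocal slope is the
effective cell density. A forward optical simulator (phantoms with exact
ground truth, optical sectioning, interferogram rendering, a
fluorescence-like label channel) makes the whole chain testable without
instrument data.

## Worked example

`examples/02_segment_and_quantify.py` simulates a tomogram with four
cells, reconstructs the phase, segments from the fluorescence-like
channel and quantifies each cell:

```
4 cells traced; refinement threshold tau = 0.075 rad
cell_id  volume_um3  dry_mass_pg  density_g_per_L  damaged
 fluo-1      189.94        17.59            92.60    False
 fluo-2      190.50        17.66            92.70    False
 fluo-3      203.06        19.65            96.76    False
 fluo-4      235.06        20.33            86.51    False

ground truth: median volume 221.6 µm³, median mass 20.55 pg
recovered:    median volume 196.8 µm³, median mass 18.65 pg
```

Volumes and dry masses land within ~10% of the phantom's ground truth;
the ~90–100 g/L densities reflect the phantom's index contrast
δn = 0.02 at α = 0.2 mL/g (δn/α = 100 g/L). The other examples show the
reconstruction round trip (`01_simulate_and_reconstruct.py`) and the
cohort statistics at the full design scale of 9 animals × ~7 cells per
group (`03_cohort_statistics.py`), where night volumes are ~25% below day
at statistically unchanged dry mass.

A thin CLI mirrors the library for shell use:

```bash
glimetry simulate out/ --n-cells 5 --seed 1
glimetry reconstruct out/stack.tif --out out/phase.tif --spectrum out/spec.csv
glimetry segment out/phase.tif --fluorescence out/fluorescence.tif --out out/masks.tif
glimetry quantify out/phase.tif --masks out/masks.tif --groups groups.csv --out cells.csv
glimetry stats cells.csv --out-dir out/
glimetry run config.json        # full pipeline from one JSON config
```

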