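# Methods

`glimetry` implements the quantitative measurement chain of gradient light
interference microscopy (GLIM): from four phase-shifted interferograms to a
quantitative phase tomogram, from sparse cell traces to refined 3D masks,
and from masked phase to per-cell volume, dry mass, density and group
statistics. A forward optical simulator with exact ground truth makes every
stage testable without instrument data. This note records the models, the
parameters that matter, and the numerical and design choices.

## Interference model and phase retrieval

The detector sees the coherent superposition of two laterally sheared
copies of the image field. With the liquid-crystal retarder stepping the
inter-beam offset through ε_n = nπ/2 (n = 0…3), the irradiance is

    I_n(r) = I(r) + I(r+δ) + 2 γ(r) cos(Δφ(r) + ε_n),

where δ = δx·x̂ is the shear, Δφ = φ(r+δ) − φ(r) and γ is the mutual
intensity (fringe modulation). Two pairwise subtractions solve this
exactly:

    Δφ = atan2(I₃ − I₁, I₀ − I₂),    γ = ¼ √((I₀−I₂)² + (I₃−I₁)²).

Any additive contribution common to the four frames — the incoherent
multiple-scattering halo of a thick slice — cancels in the subtractions to
machine precision; this is the background rejection that separates GLIM
from plain DIC, and it is asserted as an invariant in the tests.
Δφ/δx approximates the phase gradient along the shear. Pixels whose γ does
not exceed a modulation threshold τ_mod (default: 2× the robust
MAD-based noise of γ in the image border) are flagged and excluded from
later mass sums. No phase unwrapping is applied: per-slice gradients of
soma-scale objects stay well inside (−π, π]; strongly retarding objects
are a documented limitation. A configuration switch flips the gradient
sign for data acquired with reversed shear orientation.

The shear δx is an acquisition parameter in µm (default 0.375 µm, half the
0.75 µm lateral resolution of the reference instrument, which is stated
only as "about half the PSF diameter"). It is converted to pixels at
simulation time; integer shifts replicate the edge column, fractional
shifts use Fourier interpolation. Simulation refuses sub-pixel shears and
asks for lateral supersampling instead.

## Gradient integration (Hilbert/spectral)

Per z-slice the gradient is integrated spectrally:
Φ(kx) = G(kx)/(i·kx + η·k_Nyq) with η = 1e-3 and the DC term zeroed. The
regulariser only prevents blow-up near kx = 0; results are
constant-equivalent for any small η (halving η changes the Gaussian-bump
RMSE below, not its order of magnitude).

An x-only gradient determines φ up to one additive constant **per image
row** — the kx = 0 column of the spectrum carries no gradient information.
That gauge must be fixed physically: because most of every row is
background whose true phase is near zero, the integrator subtracts each
row's **median**. (Subtracting the row *mean* instead would remove part of
the object's own phase — for a mask spanning a fraction f of the row it
biases in-mask dry mass by about −f, which on an 80 µm test field is a
double-digit percentage.) The remaining per-slice spatial mean is then
removed; the global additive constant of an integrated phase is not
observable. Accuracy oracle: the analytic x-derivative of a Gaussian bump
(A = 1 rad, σ = 10 px, 256² grid) is recovered with RMSE ≈ 0.6% of A.

## Forward simulator and phantoms

Phantoms are ellipsoidal soma-like inclusions (default mean radius 4 µm,
per-axis radii jittered ±15%) of index contrast δn = 0.02 over a zero-mean
Gaussian random background texture (amplitude 0.002, correlation length
2 µm) standing in for tissue scattering. The index step at the cell edge
is sub-resolution (ramp width 5% of the radius, ~0.2 µm): refractive-index
transitions at membranes are far below the instrument's 0.75 µm lateral /
1.5 µm axial resolution, so image-domain smoothness must come from the
optics, not the object. Placement rejects overlaps with bounded retries
and reports the achieved count on failure. Ground truth is exact by
construction: volume = labelled-voxel count × voxel volume; dry mass =
Σ δn·dV / α.

Optical sectioning is modelled per slice as
φ(x,y,z) = (2π/λ)·ζ·Σ_z′ δn(x,y,z′)·w(z−z′)·dz with w a normalised
triangular kernel of full width ζ = 1.5 µm (the stated axial resolution;
the true kernel shape is uncharacterised and the choice is configurable).
A homogeneous slab thicker than the kernel then carries the slab phase
2π·δn·ζ/λ at its centre, which the dry-mass conversion inverts exactly.

Frame noise is additive Gaussian with σ = 1% of the unit base intensity —
the shot-noise level of an sCMOS camera near full well. Noise on the
*gradient* is amplified as 1/k by integration, so the background phase
noise of a reconstruction is dominated by low frequencies; at 1% frame
noise the scattering texture, not the camera, dominates the background,
matching the instrument's described imagery.

The fluorescence-like channel (for segmentation without patch-clamp
identification) is the blurred cell occupancy (σ = 1 px) scaled to ~80
photons and Poisson-sampled — a stand-in for an SR101 label, with no
photophysics.

What the simulator does **not** emulate: multiple scattering and
shift-variant aberrations, halo/shade-off artefacts, anisotropic PSFs,
camera fixed-pattern noise, astrocyte processes (somata only — consistent
with the measurement's stated preference for cell bodies). Passing
recovery tests therefore demonstrates correctness of the measurement
chain, not robustness to every property of real tissue.

## Segmentation

Sparse per-slice polygon traces (manual JSON-lines / ImageJ ROI archives,
or derived from the fluorescence channel by Otsu thresholding, 3D
connected components and per-slice contours every 2nd occupied slice) are
lifted to physical coordinates (z anisotropy respected), Delaunay-
triangulated, and voxelised by a boundary-inclusive voxel-centre test.
The convex hull cannot represent concavities; somata are near-convex so
this matches the annotation style, and it is a documented limitation.

Refinement keeps coarse voxels with |φ| > τ, with τ = 3× the robust
(MAD-based) σ of the phase outside all coarse masks. Near-zero-phase
background is removed; **negative**-phase voxels are deliberately
retained so that phase-depleted (damaged) cells remain measurable with
negative total mass — resolving in favour of measurability the tension
between "accumulate positive phase" and the existence of negative-mass
cells. At default settings, phantom recovery gives median Jaccard ≈ 0.9
against true labels and median volume error ≈ 8% over 20 seeds.

## Dry mass, volume, density

Volume is the refined voxel count times the voxel volume (the coarse count
is recorded alongside, since either convention is defensible). Dry mass
converts phase to index contrast per voxel, δn = φ·λ/(2π·ζ), and sums

    m = (1/α) Σ_mask δn·dV,   α = 0.2 mL/g,

equivalent to the scattering-potential integral under
χ = n² − n₀² ≈ 2n₀(n − n₀). The ζ normalisation is this package's
resolution of the z-stack ambiguity of phase summation: without it, a
voxel's contribution is counted ≈ (thickness/ζ) times across the axial
PSF support. An alternative `slice2d` mode integrates φ over the single
best-focus slice (m = λ/(2πα)·Σφ·dA). Units are centralised: phase rad,
lengths µm, mass pg, density g/L (1 pg/µm³ = 1000 g/L).

Mass from reconstructed tomograms is slightly underestimated (−3 to −5%
on a 5 µm calibration sphere in a 96 µm field): the per-slice zero-mean
normalisation removes the object's share of the slice mean, and residual
axial-smear tails fall outside any finite mask. The bias shrinks with
field size and is shared by both comparison groups; group *ratios* are
recovered much more accurately than absolute masses — which is also the
regime the instrument's own measurements are interpreted in.

Damaged-cell rule: a cell whose total in-mask dry mass is negative (less
dense than the surrounding tissue) is flagged `damaged = True` and
excluded from group statistics, with the exclusion logged.

## Statistics

Both of the study design's analyses are always computed:

* **Mann-Whitney U**, two-sided, midrank ties. The p-value is exact by
  exhaustive enumeration of group assignments whenever C(n₁+n₂, n₁) ≤
  2·10⁵ (or n₁·n₂ ≤ 400); otherwise the tie-corrected normal
  approximation is used and cross-checked against an independent
  implementation in the tests.
* **One-way mixed-model ANOVA**: value ~ time-of-day (fixed, 2 levels) +
  animal (random intercept), REML. With two levels, Tukey's post-hoc
  reduces to the same single contrast. F is the squared Wald t of the
  contrast; the denominator df is the between-animal df (n_animals − 2),
  which keeps the type-I error near nominal (measured 3–8% at α = 0.05
  over 200 null cohorts). The response is standardised before fitting for
  optimiser conditioning (F is affine-invariant; variance components are
  rescaled back); several optimisers are tried and the best finite-REML
  solution kept, because gradient-based optimisers can diverge at the
  variance boundary — where the model correctly degenerates to ordinary
  one-way ANOVA.

`significant` in reports is taken from the mixed model by default because
it respects the cells-within-animal nesting (configurable); both p-values
are always shown and neither analysis is silently preferred. SEM is over
cells, matching the study's error-bar convention; α = 0.05.

The volume–mass relationship per group is OLS of volume (L) on mass (g);
density = 1/slope in g/L, displayed at 2 significant figures (printed
slopes of 1.02×10⁻³ and 1.17×10⁻³ L/g correspond to 980 and 850 g/L).

## Synthetic cohorts

Record-level cohorts (no image simulation) emulate the study design for
power and calibration studies: 9 animals per group, 7 cells per animal.
Per cell, dry mass is lognormal around 500 pg (≈ a 520 µm³ soma at
~960 g/L) with within-animal CV 0.15 and a between-animal random effect
of SD 0.06 (log scale); volume follows mass through the day density of
980 g/L with extra cell-level noise of SD 0.08 (log scale); night volumes
are scaled by 0.75 at unchanged mass — the constant-dry-mass aqueous
volume regulation of the biology, with `night_volume_scale = 1` giving
null cohorts. These spreads are what a practitioner would call realistic
for somata of a single cell type. At this design the volume test's power
exceeds 95% while the mass test rejects at ≈ the nominal 5% rate; the
recovered group volume ratio scatters around the injected 0.75 with an SD
of ≈ 3 points, so single-cohort checks use medians over seeds.

## Problem sizes

Simulated tomograms in tests and examples use 160–480 px lateral grids at
0.25 µm (40–120 µm fields, vs the instrument's 175 µm) and 20–36 z-slices
at 0.5–1 µm; group-recovery experiments use 5 tomograms × 4 cells per
group (20 cells/group) and statistical calibrations 50–200 replicate
cohorts. These sizes were chosen so the full property suite demonstrates
every claim at interactive cost; all are parameters, and nothing in the
implementation depends on them.

## Known limitations

* x-only gradient: the per-row integration constant is restored by a
  background prior (row median), which biases fields whose objects span
  most of a row; fields should be a few times wider than the cells.
* Convex coarse masks; no process/arborisation segmentation; no tracking.
* No absolute refractive-index tomography and no correction for dense
  background surrounding cells — absolute densities are comparable only
  within similarly acquired data, as for the instrument itself.
* Exact Mann-Whitney enumeration cost grows combinatorially; beyond the
  enumeration bound the normal approximation is used.
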