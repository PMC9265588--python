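"""Volume, dry-mass densitometry, damaged-cell rule, cell-table assembly."""

import numpy as np
import pandas as pd
import pytest

import glimetry as g
from glimetry.simulate import Phantom


def _mask(shape, sel, voxel, cell_id="c"):
    m = np.zeros(shape, dtype=bool)
    m[sel] = True
    return g.CellMask(cell_id, m, voxel, refined=m)


class TestComputeVolume:
    def test_voxel_count_arithmetic(self):
        mask = _mask((10, 10, 10), np.s_[:], (0.1, 0.1, 0.2))
        assert g.compute_volume(mask) == pytest.approx(1000 * 0.002)

    def test_empty_mask_warns_and_returns_zero(self, acq):
        mask = _mask((4, 4, 4), np.s_[0:0], acq.voxel_um)
        with pytest.warns(UserWarning, match="empty"):
            assert g.compute_volume(mask) == 0.0


class TestComputeDryMass:
    def test_zero_phase_zero_mass(self, acq):
        mask = _mask((4, 8, 8), np.s_[1:3], acq.voxel_um)
        tomo = g.PhaseTomogram(np.zeros((4, 8, 8)), acq.voxel_um)
        assert g.compute_dry_mass(mask, tomo, config=acq) == 0.0

    def test_homogeneous_sphere_closed_form(self):
        """δn = 0.02 sphere of R = 5 µm at α = 0.2 mL/g weighs 52.36 pg."""
        cfg = g.AcquisitionConfig(voxel_um=(0.25, 0.25, 0.25))
        n, nz = 96, 96
        zz, yy, xx = np.meshgrid(*(np.arange(s) * 0.25 - s * 0.125
                                   for s in (nz, n, n)), indexing="ij")
        r = np.sqrt(zz**2 + yy**2 + xx**2)
        # phase equivalent of the sectioned sphere: δn → φ with the same
        # normalisation the mass conversion inverts
        phi = (2 * np.pi / cfg.wavelength_um) * cfg.axial_psf_um * \
            np.where(r <= 5.0, 0.02, 0.0)
        mask = _mask(r.shape, r <= 5.3, cfg.voxel_um)
        tomo = g.PhaseTomogram(phi, cfg.voxel_um)
        m = g.compute_dry_mass(mask, tomo, config=cfg)
        v_sphere = 4 / 3 * np.pi * 125
        expected = 0.02 * v_sphere / 0.2  # = 52.36 pg
        # voxelised sphere vs analytic volume: ~1% discretisation
        assert m == pytest.approx(expected, rel=0.02)

    def test_mass_linear_in_phase_and_additive(self, acq):
        rng = np.random.default_rng(4)
        phi = rng.normal(0, 0.1, (6, 16, 16))
        tomo = g.PhaseTomogram(phi, acq.voxel_um)
        tomo2 = g.PhaseTomogram(3 * phi, acq.voxel_um)
        m1 = _mask(phi.shape, np.s_[0:3], acq.voxel_um)
        m2 = _mask(phi.shape, np.s_[3:6], acq.voxel_um)
        both = _mask(phi.shape, np.s_[0:6], acq.voxel_um)
        a = g.compute_dry_mass(m1, tomo, config=acq)
        assert g.compute_dry_mass(m1, tomo2, config=acq) == pytest.approx(3 * a, rel=1e-12)
        assert g.compute_dry_mass(both, tomo, config=acq) == pytest.approx(
            a + g.compute_dry_mass(m2, tomo, config=acq), rel=1e-9)

    def test_mass_invariant_to_dilation_into_zero_background(self, acq):
        phi = np.zeros((8, 24, 24))
        phi[2:6, 8:16, 8:16] = 0.3
        tomo = g.PhaseTomogram(phi, acq.voxel_um)
        tight = _mask(phi.shape, np.s_[2:6, 8:16, 8:16], acq.voxel_um)
        dilated = _mask(phi.shape, np.s_[1:7, 5:19, 5:19], acq.voxel_um)
        mt = g.compute_dry_mass(tight, tomo, config=acq)
        md = g.compute_dry_mass(dilated, tomo, config=acq)
        assert md == pytest.approx(mt, rel=0.01)

    def test_uniformly_negative_phase_gives_negative_mass(self, acq):
        """Phase-depleted (damaged) cells must yield m < 0, not be clipped."""
        phi = np.zeros((4, 8, 8))
        phi[1:3, 2:6, 2:6] = -0.2
        mask = _mask(phi.shape, np.s_[1:3, 2:6, 2:6], acq.voxel_um)
        m = g.compute_dry_mass(mask, g.PhaseTomogram(phi, acq.voxel_um), config=acq)
        assert m < 0

    def test_slice2d_mode_matches_column_integral(self):
        cfg = g.AcquisitionConfig(voxel_um=(0.5, 0.5, 0.5))
        phi = np.zeros((8, 8, 8))
        phi[4, 2:6, 2:6] = 1.0  # single-slice object
        mask = _mask(phi.shape, np.s_[4, 2:6, 2:6], cfg.voxel_um)
        m = g.compute_dry_mass(mask, g.PhaseTomogram(phi, cfg.voxel_um),
                               config=cfg, axial_norm="slice2d")
        expected = 16 * 1.0 * cfg.wavelength_um / (2 * np.pi) * 0.25 / 0.2
        assert m == pytest.approx(expected, rel=1e-9)

    def test_missing_metadata_raises(self, acq):
        mask = _mask((2, 4, 4), np.s_[:], acq.voxel_um)
        tomo = g.PhaseTomogram(np.zeros((2, 4, 4)), acq.voxel_um)
        with pytest.raises(ValueError, match="metadata"):
            g.compute_dry_mass(mask, tomo)


class TestBuildCellTable:
    def _inputs(self, acq):
        phi = np.zeros((4, 12, 12))
        phi[1:3, 1:4, 1:4] = 0.3
        phi[1:3, 5:8, 5:8] = -0.2   # damaged cell
        phi[1:3, 9:11, 9:11] = 0.2
        tomo = g.PhaseTomogram(phi, acq.voxel_um)
        masks = [
            _mask(phi.shape, np.s_[1:3, 1:4, 1:4], acq.voxel_um, "c1"),
            _mask(phi.shape, np.s_[1:3, 5:8, 5:8], acq.voxel_um, "c2"),
            _mask(phi.shape, np.s_[1:3, 9:11, 9:11], acq.voxel_um, "c3"),
        ]
        groups = pd.DataFrame({
            "cell_id": ["c1", "c2", "c3"],
            "animal_id": ["a1", "a1", "a2"],
            "group": ["day", "day", "night"],
            "Vm_mV": [-85.0, None, -80.0],
        })
        return masks, tomo, groups

    def test_three_masks_three_records(self, acq):
        masks, tomo, groups = self._inputs(acq)
        table = g.build_cell_table(masks, tomo, groups, acq)
        assert len(table) == 3
        assert list(table.cell_id) == ["c1", "c2", "c3"]  # (animal, cell) order
        assert table.loc[1, "damaged"]
        assert not table.loc[0, "damaged"]
        assert table.loc[0, "Vm_mV"] == -85.0

    def test_volume_equals_voxels_times_voxel_volume(self, acq):
        masks, tomo, groups = self._inputs(acq)
        table = g.build_cell_table(masks, tomo, groups, acq)
        dx, dy, dz = acq.voxel_um
        np.testing.assert_allclose(table.volume_um3,
                                   table.n_voxels * dx * dy * dz)

    def test_empty_mask_dropped_with_log(self, acq, caplog):
        masks, tomo, groups = self._inputs(acq)
        empty = _mask(tomo.phi.shape, np.s_[0:0], acq.voxel_um, "c2")
        masks[1] = empty
        with caplog.at_level("WARNING"):
            table = g.build_cell_table(masks, tomo, groups, acq)
        assert len(table) == 2
        assert "c2" in caplog.text

    def test_unjoined_cell_raises_with_offender(self, acq):
        masks, tomo, groups = self._inputs(acq)
        with pytest.raises(KeyError, match="c3"):
            g.build_cell_table(masks, tomo, groups[groups.cell_id != "c3"], acq)


def test_end_to_end_group_recovery_constant_mass():
    """Day/night phantoms at constant dry mass: recovered volumes reproduce
    the injected ratio within 5 points and recovered median masses differ
    by < 5% between groups (≥ 20 cells per group)."""
    def run_group(scale, seeds):
        vols, masses, tvols = [], [], []
        for seed in seeds:
            cfg = g.AcquisitionConfig(seed=seed)
            rng = cfg.rng()
            ph = g.make_phantom((24, 480, 480), 4, config=cfg, rng=rng,
                                volume_scale=scale)
            stack = g.simulate_interferograms(
                g.project_phase(ph, cfg), config=cfg, noise_sd=0.01, rng=rng)
            rec = g.integrate_gradient_hilbert(g.retrieve_phase_gradient(stack))
            traces = g.traces_from_fluorescence(g.fluorescence_channel(ph, rng=rng))
            masks = [g.voxelize_trace(t, rec.phi.shape, cfg.voxel_um)
                     for t in traces]
            tau = g.default_phase_threshold(rec, masks)
            for m in masks:
                r = g.refine_mask(m, rec, tau)
                labs, cnt = np.unique(ph.labels[r.coarse], return_counts=True)
                if not (labs > 0).any():
                    continue
                k = labs[labs > 0][np.argmax(cnt[labs > 0])]
                vols.append(g.compute_volume(r))
                masses.append(g.compute_dry_mass(r, rec, config=cfg))
                tvols.append(ph.cell_truth.loc[ph.cell_truth.label == k,
                                               "volume_um3"].iloc[0])
        return np.array(vols), np.array(masses), np.array(tvols)

    dv, dm, dtv = run_group(1.0, range(100, 105))
    nv, nm, ntv = run_group(0.75, range(200, 205))
    assert len(dv) >= 20 and len(nv) >= 20
    injected = np.median(ntv) / np.median(dtv)
    recovered = np.median(nv) / np.median(dv)
    assert abs(recovered - injected) < 0.05
    mass_diff = abs(np.median(nm) / np.median(dm) - 1)
    assert mass_diff < 0.05
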