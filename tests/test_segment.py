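"""Trace voxelization, phase refinement, fluorescence-derived traces."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

import glimetry as g


def _brute_force_hull_count(points_xyz, grid_shape, voxel_um):
    """Independent oracle: voxel centres inside the convex hull (Delaunay
    membership evaluated point by point over the whole grid)."""
    tri = Delaunay(points_xyz)
    cnt = 0
    dz_, dy_, dx_ = voxel_um[2], voxel_um[1], voxel_um[0]
    for z in range(grid_shape[0]):
        for y in range(grid_shape[1]):
            for x in range(grid_shape[2]):
                if tri.find_simplex((x * dx_, y * dy_, z * dz_)) >= 0:
                    cnt += 1
    return cnt


class TestVoxelizeTrace:
    def test_cube_matches_brute_force_oracle(self, square_trace):
        mask = g.voxelize_trace(square_trace, (12, 14, 14), (1.0, 1.0, 1.0))
        pts = [(x, y, z) for z, xy in square_trace.polygons for x, y in xy]
        oracle = _brute_force_hull_count(np.array(pts, float),
                                         (12, 14, 14), (1.0, 1.0, 1.0))
        assert mask.coarse.sum() == oracle
        # boundary-inclusive centre sampling of a 10×10×9 µm box:
        # between the analytic volume and the (n+1)-per-axis centre count
        assert 900 <= mask.coarse.sum() <= 11 * 11 * 10

    def test_tetrahedron_volume_closed_form(self):
        # tetrahedron (0,0,0)(10,0,0)(0,10,0)(0,0,10): V = 1000/6 µm³; the
        # tip polygon is a tiny triangle so the trace is a valid 3D object
        trace = g.CellTrace("tet", [(0, [(0, 0), (10, 0), (0, 10)]),
                                    (10, [(0, 0), (0.3, 0), (0, 0.3)])])
        mask = g.voxelize_trace(trace, (12, 12, 12), (1.0, 1.0, 1.0))
        pts = [(x, y, z) for z, xy in trace.polygons for x, y in xy]
        oracle = _brute_force_hull_count(np.array(pts, float),
                                         (12, 12, 12), (1.0, 1.0, 1.0))
        assert mask.coarse.sum() == oracle
        # boundary-inclusive counting adds up to ~ one voxel shell (~S/2+edges)
        assert 1000 / 6 <= mask.coarse.sum() <= 1000 / 6 + 130

    def test_anisotropic_voxels_respected(self, square_trace):
        mask = g.voxelize_trace(square_trace, (12, 14, 14), (1.0, 1.0, 0.5))
        # z-extent 0..9 in slices of 0.5 µm: same slice count, thinner volume
        vol = g.compute_volume(g.CellMask("c", mask.coarse, (1.0, 1.0, 0.5),
                                          refined=mask.coarse))
        assert vol == pytest.approx(mask.coarse.sum() * 0.5)

    def test_single_slice_trace_is_degenerate(self):
        with pytest.raises(g.DegenerateTraceError):
            g.CellTrace("flat", [(3, [(0, 0), (5, 0), (0, 5)])])

    def test_collinear_polygon_rejected_at_construction(self):
        # a zero-area "polygon" of collinear vertices is not a simple polygon
        with pytest.raises(ValueError):
            g.CellTrace("line", [(0, [(0, 0), (5, 0), (10, 0)]),
                                 (5, [(0, 0), (5, 0), (10, 0)])])

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValueError, match="self-intersecting"):
            g.CellTrace("bow", [(0, [(0, 0), (5, 5), (5, 0), (0, 5)]),
                                (4, [(0, 0), (5, 0), (5, 5), (0, 5)])])

    def test_volume_monotone_under_trace_dilation(self, square_trace):
        base = g.voxelize_trace(square_trace, (12, 20, 20), (1.0, 1.0, 1.0))
        shifted = g.CellTrace(square_trace.cell_id,
                              [(z, xy + 2) for z, xy in square_trace.polygons])
        grown = g.voxelize_trace(shifted.dilated(2.0), (12, 20, 20), (1.0, 1.0, 1.0))
        assert grown.coarse.sum() > base.coarse.sum()


class TestRefineMask:
    def _mask_and_phase(self, acq):
        coarse = np.zeros((4, 8, 8), dtype=bool)
        coarse[1:3, 2:6, 2:6] = True
        phi = np.zeros((4, 8, 8))
        return coarse, phi

    def test_all_low_phase_empties_mask_with_warning(self, acq):
        coarse, phi = self._mask_and_phase(acq)
        mask = g.CellMask("c", coarse, acq.voxel_um)
        tomo = g.PhaseTomogram(phi, acq.voxel_um)
        with pytest.warns(UserWarning, match="removed every voxel"):
            refined = g.refine_mask(mask, tomo, tau=0.05)
        assert not refined.refined.any()

    def test_constructed_half_split(self, acq):
        coarse, phi = self._mask_and_phase(acq)
        phi[1][coarse[1]] = 0.5          # one z-plane at 0.5 rad
        mask = g.CellMask("c", coarse, acq.voxel_um)
        tomo = g.PhaseTomogram(phi, acq.voxel_um)
        refined = g.refine_mask(mask, tomo, tau=0.05)
        assert refined.refined.sum() == coarse.sum() // 2

    def test_negative_phase_voxels_are_retained(self, acq):
        coarse, phi = self._mask_and_phase(acq)
        phi[coarse] = -0.4
        refined = g.refine_mask(g.CellMask("c", coarse, acq.voxel_um),
                                g.PhaseTomogram(phi, acq.voxel_um), tau=0.05)
        assert refined.refined.sum() == coarse.sum()

    def test_refinement_never_adds_and_is_idempotent(self, phantom_scene):
        ph, recon, acq = (phantom_scene["phantom"], phantom_scene["recon"],
                          phantom_scene["config"])
        traces = g.traces_from_fluorescence(
            g.fluorescence_channel(ph, rng=acq.rng(salt=5)))
        masks = [g.voxelize_trace(t, recon.phi.shape, acq.voxel_um)
                 for t in traces]
        tau = g.default_phase_threshold(recon, masks)
        for m in masks:
            r1 = g.refine_mask(m, recon, tau)
            assert not (r1.refined & ~r1.coarse).any()
            r2 = g.refine_mask(g.CellMask(r1.cell_id, r1.refined, r1.voxel_um),
                               recon, tau)
            np.testing.assert_array_equal(r2.refined, r1.refined)

    def test_phantom_jaccard_at_default_settings(self, phantom_scene):
        ph, recon, acq = (phantom_scene["phantom"], phantom_scene["recon"],
                          phantom_scene["config"])
        traces = g.traces_from_fluorescence(
            g.fluorescence_channel(ph, rng=acq.rng(salt=5)))
        masks = [g.voxelize_trace(t, recon.phi.shape, acq.voxel_um)
                 for t in traces]
        tau = g.default_phase_threshold(recon, masks)
        jaccards = []
        for m in masks:
            r = g.refine_mask(m, recon, tau)
            labs, cnt = np.unique(ph.labels[r.coarse], return_counts=True)
            k = labs[labs > 0][np.argmax(cnt[labs > 0])]
            truth = ph.labels == k
            jaccards.append((r.refined & truth).sum() / (r.refined | truth).sum())
        assert np.median(jaccards) >= 0.8


class TestTracesFromFluorescence:
    def test_blank_channel_gives_no_traces(self):
        assert g.traces_from_fluorescence(np.zeros((8, 32, 32)),
                                          threshold=0.5) == []

    def test_phantom_somata_traced(self, phantom_scene):
        ph, acq = phantom_scene["phantom"], phantom_scene["config"]
        traces = g.traces_from_fluorescence(
            g.fluorescence_channel(ph, rng=acq.rng(salt=5)))
        assert len(traces) == len(ph.cell_truth)
        for t in traces:
            assert len(t.z_indices()) >= 2
            assert t.source == "fluorescence"

    def test_merging_only_reduces_count(self, acq):
        # two touching somata may merge into one component, never split
        chan = np.zeros((10, 40, 40))
        chan[3:7, 5:15, 5:15] = 100.0
        chan[3:7, 14:24, 5:15] = 100.0  # touches the first block
        traces = g.traces_from_fluorescence(chan, threshold=50.0)
        assert len(traces) <= 2


def test_median_volume_error_across_seeds():
    """Refined-mask volumes recover phantom truth: median error ≤ 10%
    over 20 seeded phantoms at default settings."""
    errors = []
    for seed in range(20):
        cfg = g.AcquisitionConfig(seed=seed)
        rng = cfg.rng()
        ph = g.make_phantom((24, 128, 128), 2, config=cfg, rng=rng)
        phase = g.project_phase(ph, cfg)
        traces = g.traces_from_fluorescence(g.fluorescence_channel(ph, rng=rng))
        masks = [g.voxelize_trace(t, phase.phi.shape, cfg.voxel_um)
                 for t in traces]
        tau = g.default_phase_threshold(phase, masks)
        for m in masks:
            r = g.refine_mask(m, phase, tau)
            labs, cnt = np.unique(ph.labels[r.refined], return_counts=True)
            labs, cnt = labs[labs > 0], cnt[labs > 0]
            if len(labs) == 0:
                continue
            k = labs[np.argmax(cnt)]
            truth_vol = ph.cell_truth.loc[ph.cell_truth.label == k,
                                          "volume_um3"].iloc[0]
            errors.append(abs(g.compute_volume(r) - truth_vol) / truth_vol)
    assert np.median(errors) <= 0.10
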