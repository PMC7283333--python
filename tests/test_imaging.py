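"""Segmentation, landmark masks, spot fitting, drift and trace linking."""

import numpy as np
import pytest

from nucleotrace import imaging, phantoms
from nucleotrace.types import ImageStack3D


def jaccard_matched(labels, truth):
    """Mean best-match Jaccard between segmented and planted regions."""
    scores = []
    for t in np.unique(truth):
        tmask = truth == t
        best = 0.0
        overlapping = np.unique(labels[tmask])
        for l in overlapping:
            if l == 0:
                continue
            lmask = labels == l
            inter = (tmask & lmask).sum()
            union = (tmask | lmask).sum()
            best = max(best, inter / union)
        scores.append(best)
    return float(np.mean(scores))


class TestSegmentCells:
    def test_phantom_grid_recovered(self, small_scene):
        phantom, stacks = small_scene
        result = imaging.segment_cells(stacks["membrane"])
        assert result.labels.max() == 9
        for lab, reason in result.excluded.items():
            assert reason in ("edge", "too-small", "too-large")
        # all border cells of the full-tiling 3x3 grid touch the field edge
        border = {int(phantom.label_map[0, 0]), int(phantom.label_map[0, -1]),
                  int(phantom.label_map[-1, 0]), int(phantom.label_map[-1, -1])}
        for lab in border:
            assert result.excluded.get(lab) == "edge"
        assert jaccard_matched(result.labels, phantom.label_map) >= 0.8

    def test_interior_cells_of_denser_grid_retained(self):
        """A 4x4 grid has in-range interior cells that pass every exclusion."""
        phantom, stacks = phantoms.gen_scene(16, fov_shape=(512, 512, 8), seed=2)
        result = imaging.segment_cells(stacks["membrane"])
        retained = result.retained_labels
        assert len(retained) >= 3  # the four interior cells, give or take jitter
        for lab in retained:
            area = (result.labels == lab).sum()
            assert imaging.MIN_CELL_AREA_PX < area < imaging.MAX_CELL_AREA_PX
        assert jaccard_matched(result.labels, phantom.label_map) >= 0.8

    def test_labels_partition_the_field(self, small_scene):
        _, stacks = small_scene
        result = imaging.segment_cells(stacks["membrane"])
        assert result.labels.shape == stacks["membrane"].shape[1:]
        assert result.labels.min() >= 0

    def test_small_cell_excluded_with_reason(self):
        """A planted ~2000 px cell falls below the 2500 px bound.

        The tiny cell's interior must stay wider than twice the 15-px closing
        radius or the closing fills it in entirely.
        """
        rng = np.random.default_rng(0)
        img = np.full((300, 300), 20.0)
        # one tiny box (36 x 46 interior) carved inside a big cell
        img[100, 40:260] = 220.0
        img[240, 40:260] = 220.0
        img[100:240, 40] = 220.0
        img[100:241, 260] = 220.0
        img[130:168, 60] = 220.0
        img[130:168, 107] = 220.0
        img[130, 60:107] = 220.0
        img[167, 60:108] = 220.0
        stack = ImageStack3D(rng.poisson(np.repeat(img[None], 3, axis=0)).astype(float))
        result = imaging.segment_cells(stack)
        small = [l for l, r in result.excluded.items() if r == "too-small"]
        assert small, f"exclusions: {result.excluded}"
        for lab in small:
            assert (result.labels == lab).sum() <= imaging.MIN_CELL_AREA_PX

    def test_uniform_image_rejected(self):
        with pytest.raises(ValueError):
            imaging.segment_cells(ImageStack3D(np.full((3, 64, 64), 7.0)))


class TestNuclearEdgeMask:
    def test_phantom_nucleus_boundary_recovered(self):
        """>= 80% of the analytic ellipsoid boundary lies within 2 voxels of
        the detected edge mask."""
        rng = np.random.default_rng(1)
        nz, ny, nx = 8, 192, 192
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        val = ((zz - 4) / 3.0) ** 2 + ((yy - 96) / 50.0) ** 2 + ((xx - 96) / 50.0) ** 2
        img = np.where(val <= 1.0, 160.0, 10.0)
        stack = ImageStack3D(rng.poisson(img).astype(float))
        mask = imaging.nuclear_edge_mask(stack)
        assert mask.mask.shape == stack.shape
        # analytic boundary voxels on the central plane
        shell = (np.abs(val - 1.0) < 0.05)[4]
        from scipy.ndimage import binary_dilation

        near_mask = binary_dilation(mask.mask[4], iterations=2)
        coverage = (shell & near_mask).sum() / shell.sum()
        assert coverage >= 0.8

    def test_disk_with_hole_gives_two_rings(self):
        # the annulus must stay wider than the 25-px opening element
        rng = np.random.default_rng(2)
        yy, xx = np.mgrid[:256, :256]
        r = np.hypot(yy - 128, xx - 128)
        solid = np.where(r < 90, 150.0, 5.0)
        holed = solid.copy()
        holed[r < 15] = 5.0

        def ring_count(img2d):
            stack = ImageStack3D(rng.poisson(np.repeat(img2d[None], 1, axis=0)).astype(float))
            mask = imaging.nuclear_edge_mask(stack).mask[0]
            # count boundary rings crossed along the central row
            row = mask[128]
            runs = np.diff(row.astype(int))
            return (runs == 1).sum()

        assert ring_count(holed) > ring_count(solid)

    def test_all_zero_plane_is_all_false(self):
        stack = ImageStack3D(np.zeros((2, 64, 64)))
        assert not imaging.nuclear_edge_mask(stack).mask.any()


class TestNucleolusMask:
    def test_phantom_blob_volume(self):
        rng = np.random.default_rng(3)
        nz, ny, nx = 8, 128, 128
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        inside = ((zz - 4) / 2.5) ** 2 + ((yy - 64) / 14.0) ** 2 + ((xx - 64) / 14.0) ** 2 <= 1
        img = np.where(inside, 320.0, 8.0)
        stack = ImageStack3D(rng.poisson(img).astype(float))
        mask = imaging.nucleolus_mask(stack)
        assert abs(mask.mask.sum() - inside.sum()) / inside.sum() <= 0.25

    def test_two_blobs_two_components(self):
        from scipy.ndimage import label

        rng = np.random.default_rng(4)
        nz, ny, nx = 6, 128, 128
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        b1 = ((zz - 3) / 2.0) ** 2 + ((yy - 40) / 10.0) ** 2 + ((xx - 40) / 10.0) ** 2 <= 1
        b2 = ((zz - 3) / 2.0) ** 2 + ((yy - 90) / 10.0) ** 2 + ((xx - 90) / 10.0) ** 2 <= 1
        img = np.where(b1 | b2, 300.0, 8.0)
        stack = ImageStack3D(rng.poisson(img).astype(float))
        mask = imaging.nucleolus_mask(stack)
        _, n = label(mask.mask)
        assert n == 2

    def test_empty_stack_all_false(self):
        mask = imaging.nucleolus_mask(ImageStack3D(np.zeros((3, 64, 64))))
        assert not mask.mask.any()


class TestFitSpots3D:
    def make_spot_stack(self, centers, amp=800.0, bg=10.0, noise=None, shape=(9, 64, 64)):
        nz, ny, nx = shape
        zz, yy, xx = np.mgrid[:nz, :ny, :nx]
        img = np.full(shape, bg)
        for (cx, cy, cz) in centers:
            img += amp * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 1.3**2) - ((zz - cz) ** 2) / (2 * 1.0**2)
            )
        if noise is not None:
            img = np.random.default_rng(noise).poisson(img).astype(float)
        return ImageStack3D(img, voxel_size=(1.0, 1.0, 1.0))  # unit voxels: nm == px

    def test_noiseless_center_recovery(self):
        stack = self.make_spot_stack([(30.3, 27.8, 4.2)])
        fits = imaging.fit_spots_3d(stack, [(30, 28, 4)])
        assert fits[0].success
        assert fits[0].center_nm[0] == pytest.approx(30.3, abs=0.05)
        assert fits[0].center_nm[1] == pytest.approx(27.8, abs=0.05)
        assert fits[0].center_nm[2] == pytest.approx(4.2, abs=0.05)

    def test_flat_background_fails(self):
        stack = ImageStack3D(np.full((9, 64, 64), 10.0), voxel_size=(1.0, 1.0, 1.0))
        fits = imaging.fit_spots_3d(stack, [(30, 30, 4)])
        assert not fits[0].success

    def test_two_nearby_spots_resolved_at_high_snr(self):
        stack = self.make_spot_stack([(25.0, 30.0, 4.0), (35.0, 30.0, 4.0)], amp=2000.0, noise=7)
        fits = imaging.fit_spots_3d(stack, [(25, 30, 4), (35, 30, 4)])
        assert all(f.success for f in fits)
        assert fits[0].center_nm[0] == pytest.approx(25.0, abs=0.5)
        assert fits[1].center_nm[0] == pytest.approx(35.0, abs=0.5)

    def test_clipped_window_fails_alone(self):
        stack = self.make_spot_stack([(30.0, 30.0, 4.0)])
        fits = imaging.fit_spots_3d(stack, [(1, 1, 0), (30, 30, 4)])
        assert not fits[0].success
        assert fits[1].success


class TestEstimateDrift:
    def bead_stacks(self, drift, seed=0, noise=False):
        cb = phantoms.gen_codebook(1, seed=seed)
        _, beads, _, _ = phantoms.gen_merfish_stacks(
            cb, molecules_per_gene=0, drift_truth=drift, bead_count=10,
            seed=seed, noise=noise, fov_shape=(96, 96, 7),
        )
        return beads

    def test_reference_round_is_zero(self):
        table = imaging.estimate_drift(self.bead_stacks(np.zeros((16, 3)))[:3])
        assert table.offsets_nm[0] == (0.0, 0.0, 0.0)

    def test_planted_offsets_recovered_noiseless(self):
        drift = np.zeros((16, 3))
        drift[1] = (2.0, -1.0, 0.0)
        drift[2] = (-3.0, 2.5, 0.0)
        stacks = self.bead_stacks(drift)[:3]
        table = imaging.estimate_drift(stacks, mode="2d")
        # unit-free: phantom voxel size is the default 107.9/107.9/200 nm
        for rnd in (1, 2):
            got = np.array(table.offsets_nm[rnd]) / np.array([107.9, 107.9, 200.0])
            assert np.allclose(got[:2], drift[rnd][:2], atol=0.1)

    def test_outlier_bead_does_not_break_median(self):
        drift = np.zeros((16, 3))
        drift[1] = (2.0, 0.0, 0.0)
        stacks = self.bead_stacks(drift)[:2]
        # corrupt one bead in round 1 by painting an extra bright blob
        vox = stacks[1].voxels.copy()
        vox[3, 10:14, 10:14] += 4000.0
        stacks[1] = ImageStack3D(vox, stacks[1].voxel_size, "beads", 1)
        table = imaging.estimate_drift(stacks, mode="2d")
        got = np.array(table.offsets_nm[1])[:2] / 107.9
        assert np.allclose(got, drift[1][:2], atol=0.15)

    def test_too_few_beads_error(self):
        cb = phantoms.gen_codebook(1, seed=0)
        _, beads, _, _ = phantoms.gen_merfish_stacks(
            cb, 0, bead_count=2, seed=1, noise=False, fov_shape=(96, 96, 7)
        )
        with pytest.raises(ValueError, match="beads"):
            imaging.estimate_drift(beads[:2])

    def test_correction_inverts_planted_drift(self):
        """Corrected bead positions scatter no wider than the fit noise."""
        drift = np.zeros((16, 3))
        drift[1] = (4.0, -3.0, 0.0)
        stacks = self.bead_stacks(drift, noise=True)[:2]
        table = imaging.estimate_drift(stacks, mode="2d")
        got = np.array(table.offsets_nm[1])[:2] / 107.9
        assert np.allclose(got, drift[1][:2], atol=0.2)


class TestLinkTraces:
    def positions_for(self, centers, n_loci, cell=0, rng=None, spread=200.0):
        rng = rng or np.random.default_rng(0)
        out = []
        for copy, center in enumerate(centers):
            for r in range(n_loci):
                p = np.asarray(center) + rng.normal(scale=spread, size=3)
                out.append(
                    {
                        "cell_id": cell, "readout_id": r,
                        "x_nm": p[0], "y_nm": p[1], "z_nm": p[2],
                        "quality": rng.uniform(100, 200),
                        "true_copy": copy,
                    }
                )
        return out

    def test_two_separated_copies_recovered(self):
        rng = np.random.default_rng(1)
        pos = self.positions_for([(0, 0, 0), (8000, 0, 0)], n_loci=20, rng=rng)
        traces = imaging.link_traces(pos, n_loci=20)
        assert len(traces) == 2
        # each recovered trace is pure in planted copy identity
        for t in traces:
            mean_x = np.nanmean(t.positions[:, 0])
            planted = 0 if abs(mean_x) < 4000 else 1
            member_x = t.positions[t.present][:, 0]
            frac = np.mean((member_x > 4000) == bool(planted))
            assert frac >= 0.9

    def test_single_copy_single_trace(self):
        pos = self.positions_for([(0, 0, 0)], n_loci=10)
        traces = imaging.link_traces(pos, n_loci=10)
        assert len(traces) == 1
        assert traces[0].present.sum() == 10

    def test_duplicate_detection_keeps_brightest(self):
        pos = [
            {"cell_id": 0, "readout_id": 0, "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0, "quality": 50.0},
            {"cell_id": 0, "readout_id": 0, "x_nm": 30.0, "y_nm": 0.0, "z_nm": 0.0, "quality": 90.0},
        ]
        traces = imaging.link_traces(pos, n_loci=2)
        assert len(traces) == 1
        assert traces[0].positions[0, 0] == pytest.approx(30.0)
        assert np.isnan(traces[0].positions[1]).all()

    def test_empty_input_no_traces(self):
        assert imaging.link_traces([], n_loci=5) == []
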