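"""Segmentation, the 500-feature registry, and extraction oracles."""

import numpy as np
import pandas as pd
import pytest

from ctcmorph import features as ft
from ctcmorph import registry as reg
from ctcmorph import synthgen as sg
from ctcmorph.texture import glcm_features, granularity_spectrum


def dice(a, b):
    denom = a.sum() + b.sum()
    return 2 * np.logical_and(a, b).sum() / denom if denom else np.nan


class TestRegistry:
    def test_exactly_500_unique_features(self):
        names = reg.feature_names()
        assert len(names) == 500
        assert len(set(names)) == 500

    def test_main_features_exclude_texture_and_granularity(self):
        frame = reg.registry_frame()
        main = frame[frame["main"]]
        assert not main["category"].isin(["granularity", "texture"]).any()
        assert set(reg.main_feature_names()) == set(main["name"])

    def test_ratio_features_present(self):
        names = set(reg.feature_names())
        assert set(reg.RATIO_NAMES) <= names

    def test_registry_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "registry.yaml"
        reg.save_registry(path)
        loaded = reg.load_registry(path)
        assert [f.name for f in loaded] == reg.feature_names()
        assert [f.main for f in loaded] == [
            f.main for f in reg.build_registry()]


class TestSegmentation:
    def test_dice_against_truth_on_noisefree_cells(self, noisefree_cohort):
        """Every component mask matches the generator's truth (Dice ≥ 0.95)."""
        _, cells, _ = noisefree_cohort
        for cell in cells[:12]:
            masks = ft.segment_cell(cell.image, cell.voxel_xy, cell.voxel_z)
            t = cell.truth.true_masks
            assert dice(masks.cell, t.cell) >= 0.95
            assert dice(masks.nucleus, t.nucleus) >= 0.95
            assert dice(masks.densenuc, t.densenuc) >= 0.95
            assert dice(masks.mito, t.mito) >= 0.95

    def test_binary_input_reproduced_exactly(self, small_cohort):
        _, cells, _ = small_cohort
        truth = cells[0].truth.true_masks.cell
        mask = ft.segment_channel(truth.astype(np.float32), "cell")
        np.testing.assert_array_equal(mask, truth)

    def test_all_zero_image_gives_empty_mask(self):
        assert not ft.segment_channel(np.zeros((8, 8, 8)), "cell").any()

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            ft.segment_channel(np.full((4, 4, 4), -1.0), "cell")


class TestCloseHoles:
    def test_solid_ball_unchanged(self):
        z, y, x = np.ogrid[-8:9, -8:9, -8:9]
        ball = z**2 + y**2 + x**2 <= 36
        np.testing.assert_array_equal(ft.close_holes(ball), ball)

    def test_enclosed_cavity_filled(self):
        z, y, x = np.ogrid[-8:9, -8:9, -8:9]
        r2 = z**2 + y**2 + x**2
        shell = (r2 <= 49) & (r2 > 16)
        cavity = r2 <= 16
        closed = ft.close_holes(shell)
        assert closed[cavity].all()
        assert closed.sum() == shell.sum() + cavity.sum()

    def test_empty_and_idempotent(self):
        empty = np.zeros((5, 5, 5), dtype=bool)
        assert not ft.close_holes(empty).any()
        z, y, x = np.ogrid[-8:9, -8:9, -8:9]
        shell = (z**2 + y**2 + x**2 <= 49) & (z**2 + y**2 + x**2 > 16)
        once = ft.close_holes(shell)
        np.testing.assert_array_equal(ft.close_holes(once), once)


class TestComponentFeatures:
    def test_digital_ball_volume(self):
        z, y, x = np.ogrid[-12:13, -12:13, -12:13]
        ball = z**2 + y**2 + x**2 <= 100
        feats = ft.extract_component_features(
            ball, ball.astype(float), "cell", voxel_xy=1.0, voxel_z=1.0)
        assert feats["cell_volume"] == pytest.approx(4188.79, rel=0.03)
        assert feats["cell_surface_area"] == pytest.approx(
            4 * np.pi * 100, rel=0.05)

    def test_empty_mask_propagates_missing_not_zero(self):
        feats = ft.extract_component_features(
            np.zeros((6, 6, 6), dtype=bool), np.zeros((6, 6, 6)),
            "mito", voxel_xy=1.0, voxel_z=1.0)
        assert all(np.isnan(v) for v in feats.values())

    def test_uniform_slice_texture_degenerate(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        img = np.where(mask, 5.0, 0.0)
        tex = glcm_features(img, mask, offsets=(1,), angles_deg=(0,))
        assert tex[("contrast", 1, 0)] == 0.0
        assert np.isnan(tex[("correlation", 1, 0)])

    def test_granularity_separates_speckle_from_blobs(self):
        rng = np.random.default_rng(0)
        mask = np.ones((60, 60), dtype=bool)
        speckle = np.zeros((60, 60))
        idx = rng.choice(3600, size=120, replace=False)
        speckle.ravel()[idx] = 1.0
        blob = np.zeros((60, 60))
        yy, xx = np.mgrid[:60, :60]
        for cy, cx in [(15, 15), (42, 40)]:
            blob[(yy - cy) ** 2 + (xx - cx) ** 2 <= 64] = 1.0
        g_speckle = granularity_spectrum(speckle, mask)
        g_blob = granularity_spectrum(blob, mask)
        assert np.argmax(g_speckle) == 0
        assert np.argmax(g_blob) >= 4


class TestRatios:
    def test_hand_computed_ratio(self):
        partials = {"nucleus_volume": 50.0, "cell_volume": 100.0}
        assert ft.compute_ratios(partials)["ratio_nuc_cell_volume"] == 0.5

    def test_densenuc_nuc_consistent_both_ways(self):
        partials = {"cell_volume": 200.0, "nucleus_volume": 80.0,
                    "densenuc_volume": 20.0}
        r = ft.compute_ratios(partials)
        indirect = r["ratio_densenuc_cell_volume"] / r["ratio_nuc_cell_volume"]
        assert r["ratio_densenuc_nuc_volume"] == pytest.approx(indirect,
                                                               abs=1e-9)

    def test_zero_cell_volume_gives_missing(self):
        r = ft.compute_ratios({"nucleus_volume": 10.0, "cell_volume": 0.0})
        assert np.isnan(r["ratio_nuc_cell_volume"])


class TestOracleEquivalence:
    def test_extraction_recovers_generator_truth(self, noisefree_cohort):
        """Volumes, Nuc/Cell and Mito/Cell ratios agree with ground truth
        across 50 noise-free cells of all three archetypes."""
        _, cells, truth = noisefree_cohort
        assert set(truth["archetype"]) == {"SLR", "SSR", "LSS"}
        table = ft.assemble_feature_table(cells)
        _, matrix = ft.split_meta(table)
        t = truth.set_index("cell_id")
        vol_err = (matrix["cell_volume"] - t["true_cell_volume"]).abs() \
            / t["true_cell_volume"]
        assert (vol_err < 0.03).all()
        assert (matrix["ratio_nuc_cell_volume"]
                - t["true_nuc_cell"]).abs().max() < 0.05
        assert (matrix["ratio_mito_cell_volume"]
                - t["true_mito_cell"]).abs().max() < 0.05


class TestAssembledTable:
    def test_shape_and_metadata(self, small_cohort):
        _, cells, _ = small_cohort
        table = ft.assemble_feature_table(cells[:5])
        assert table.shape == (5, reg.N_FEATURES + 2)
        meta, matrix = ft.split_meta(table)
        assert list(meta.columns) == ["batch", "archetype"]
        assert list(matrix.columns) == reg.feature_names()

    def test_duplicate_cell_id_raises(self, small_cohort):
        _, cells, _ = small_cohort
        twin = sg.VoxelCell(cells[0].cell_id, cells[0].image,
                            cells[0].voxel_xy, cells[0].voxel_z,
                            cells[0].batch, cells[0].truth)
        with pytest.raises(ValueError, match="duplicate"):
            ft.assemble_feature_table([cells[0], twin])

    def test_empty_mito_channel_gives_partial_row(self, small_cohort):
        _, cells, _ = small_cohort
        c = cells[0]
        image = c.image.copy()
        image[2] = 0.0
        cell = sg.VoxelCell("mito_free", image, c.voxel_xy, c.voxel_z,
                            c.batch, c.truth)
        feats = ft.extract_cell_features(cell)
        assert np.isnan(feats["mito_volume"])
        assert np.isnan(feats["ratio_mito_cell_volume"])
        assert np.isfinite(feats["cell_volume"])
        assert np.isfinite(feats["nucleus_volume"])


class TestInvariances:
    def test_intensity_scale_equivariance(self, small_cohort):
        """Doubling intensities: masks and geometry unchanged, integrated
        intensities double."""
        _, cells, _ = small_cohort
        c = cells[1]
        doubled = sg.VoxelCell(c.cell_id, c.image * 2.0, c.voxel_xy,
                               c.voxel_z, c.batch, c.truth)
        f1 = ft.extract_cell_features(c)
        f2 = ft.extract_cell_features(doubled)
        assert f2["cell_volume"] == pytest.approx(f1["cell_volume"])
        assert f2["cell_surface_area"] == pytest.approx(f1["cell_surface_area"])
        assert f2["nucleus_area2d"] == pytest.approx(f1["nucleus_area2d"])
        assert f2["cell_intensity_integrated"] == pytest.approx(
            2 * f1["cell_intensity_integrated"], rel=1e-6)

    def test_inplane_rotation_robustness(self, small_cohort):
        """90° in-plane rotation is a lattice symmetry: geometry features move
        by < 2%."""
        _, cells, _ = small_cohort
        c = cells[2]
        rotated = sg.VoxelCell(
            c.cell_id, np.rot90(c.image, axes=(2, 3)).copy(),
            c.voxel_xy, c.voxel_z, c.batch, c.truth)
        f1 = ft.extract_cell_features(c)
        f2 = ft.extract_cell_features(rotated)
        for name in ("cell_volume", "cell_surface_area", "nucleus_volume",
                     "cell_area2d", "cell_perimeter2d"):
            assert f2[name] == pytest.approx(f1[name], rel=0.02), name


def test_tiff_roundtrip(tmp_path, small_cohort):
    _, cells, _ = small_cohort
    sg.write_cohort(cells[:3], tmp_path)
    loaded = {c.cell_id: c for c in ft.read_cohort_dir(tmp_path)}
    assert len(loaded) == 3
    for orig in cells[:3]:
        got = loaded[orig.cell_id]
        np.testing.assert_array_equal(got.image, orig.image)
        assert got.batch == orig.batch
        assert got.voxel_z == orig.voxel_z
        assert got.truth.archetype == orig.truth.archetype
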