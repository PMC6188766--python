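"""Phantom construction, image-stack round trips and planning-grid
 downsampling."""

import numpy as np
import pytest

from bnctshift.phantom import (AIR_LABEL, HeadROIGeometry, TumorSpec,
                               build_cylinder_phantom, build_head_phantom,
                               read_image_stack, read_manifest,
                               voxelize_to_planning_grid, write_image_stack)


class TestCylinder:
    def test_in_cylinder_voxels_match_bruteforce_inequality(self):
        phantom, _ = build_cylinder_phantom(spacing=(1.0, 1.0, 1.0))
        got = phantom.material_grid == 1
        expected = np.zeros(phantom.shape, dtype=bool)
        for i in range(phantom.shape[0]):
            x = phantom.origin[0] + (i + 0.5) * phantom.spacing[0]
            for j in range(phantom.shape[1]):
                y = phantom.origin[1] + (j + 0.5) * phantom.spacing[1]
                for k in range(phantom.shape[2]):
                    z = phantom.origin[2] + (k + 0.5) * phantom.spacing[2]
                    expected[i, j, k] = (x * x + z * z <= 64.0
                                         and 0.0 <= y <= 20.0)
        assert np.array_equal(got, expected)

    def test_tumor_axis_sits_at_requested_depth(self):
        for depth in (2.5, 6.5):
            phantom, rois = build_cylinder_phantom(
                tumor=TumorSpec(depth=depth))
            idx = np.argwhere(rois["tumor"])
            y = phantom.origin[1] + (idx[:, 1] + 0.5) * phantom.spacing[1]
            # tumor spans depth +/- radius along the beam axis
            assert y.min() >= depth - 1.5 - phantom.spacing[1]
            assert y.max() <= depth + 1.5 + phantom.spacing[1]
            assert abs(y.mean() - depth) < phantom.spacing[1]

    def test_tumor_and_normal_masks_disjoint(self):
        _, rois = build_cylinder_phantom()
        assert not (rois["tumor"] & rois["normal_brain"]).any()

    @pytest.mark.parametrize("kwargs", [
        {"diameter": 0.0},
        {"diameter": -3.0},
        {"spacing": (0.5, -0.5, 0.5)},
        {"tumor": TumorSpec(depth=19.0)},  # pokes out the distal face
        {"tumor": TumorSpec(diameter=3.0, length=17.0)},  # radially outside
    ])
    def test_bad_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_cylinder_phantom(**kwargs)


class TestHead:
    def test_tumor_depth_measured_from_posterior_pole(self):
        phantom, rois = build_head_phantom(tumor=TumorSpec(depth=6.5))
        idx = np.argwhere(rois["tumor"])
        y = phantom.origin[1] + (idx[:, 1] + 0.5) * phantom.spacing[1]
        assert abs(y.mean() - 6.5) < phantom.spacing[1]
        # posterior scalp surface touches the aperture plane y=0
        tissue = np.argwhere(phantom.tissue_mask())
        y_entry = phantom.origin[1] + tissue[:, 1].min() * phantom.spacing[1]
        assert abs(y_entry) <= phantom.spacing[1]

    def test_anterior_structures_beyond_tumor(self):
        phantom, rois = build_head_phantom()
        dy, oy = phantom.spacing[1], phantom.origin[1]

        def mean_depth(name):
            idx = np.argwhere(rois[name])
            return oy + (idx[:, 1].mean() + 0.5) * dy

        tumor_depth = mean_depth("tumor")
        for name in ("lens_L", "lens_R", "eye_L", "eye_R",
                     "optic_nerve_L", "optic_nerve_R"):
            assert mean_depth(name) > tumor_depth

    def test_all_organs_present_and_disjoint_tumor_brain(self):
        _, rois = build_head_phantom()
        for name in ("tumor", "normal_brain", "brainstem", "circle_of_willis",
                     "lens_L", "lens_R", "eye_L", "eye_R",
                     "optic_nerve_L", "optic_nerve_R"):
            assert rois[name].any(), name
        assert not (rois["tumor"] & rois["normal_brain"]).any()

    def test_oversized_tumor_rejected(self):
        with pytest.raises(ValueError):
            build_head_phantom(tumor=TumorSpec(depth=18.0))

    def test_inconsistent_lens_eye_geometry_rejected(self):
        bad = HeadROIGeometry(lens_anterior_offset=1.5)
        with pytest.raises(ValueError):
            build_head_phantom(roi_geometry=bad)

    def test_head_ellipsoid_matches_bruteforce_membership(self):
        phantom, _ = build_head_phantom(spacing=(1.0, 1.0, 1.0))
        got = phantom.tissue_mask()
        ax, ay, az = 8.0, 9.5, 12.0  # (LR, AP, SI) semi-axes
        expected = np.zeros(phantom.shape, dtype=bool)
        for i in range(phantom.shape[0]):
            x = phantom.origin[0] + (i + 0.5) * phantom.spacing[0]
            for j in range(phantom.shape[1]):
                y = phantom.origin[1] + (j + 0.5) * phantom.spacing[1]
                for k in range(phantom.shape[2]):
                    z = phantom.origin[2] + (k + 0.5) * phantom.spacing[2]
                    expected[i, j, k] = ((x / ax) ** 2 + ((y - 9.5) / ay) ** 2
                                         + (z / az) ** 2 <= 1.0)
        assert np.array_equal(got, expected)


class TestImageStack:
    def test_round_trip_is_identity_on_labels_and_masks(self, tmp_path):
        phantom, rois = build_cylinder_phantom(spacing=(1.0, 1.0, 1.0))
        write_image_stack(phantom, rois, tmp_path)
        back, rois_back = read_image_stack(tmp_path)
        assert np.array_equal(back.material_grid, phantom.material_grid)
        assert back.spacing == phantom.spacing
        for name in rois.names():
            assert np.array_equal(rois_back[name], rois[name])

    def test_manifest_records_axial_extent(self, tmp_path):
        # 125 slices of 2 mm -> 25 cm axial extent
        phantom, rois = build_cylinder_phantom(
            diameter=4.0, length=4.0, spacing=(1.0, 1.0, 0.2),
            tumor=TumorSpec(diameter=1.0, length=1.0, depth=2.0),
            lateral_margin=10.5, distal_margin=0.0)
        assert phantom.shape[2] == 125
        write_image_stack(phantom, rois, tmp_path)
        man = read_manifest(tmp_path)
        assert float(man["axial_extent_cm"]) == pytest.approx(25.0)

    def test_corrupt_slice_dimensions_reported_by_name(self, tmp_path):
        import tifffile

        phantom, rois = build_cylinder_phantom(spacing=(1.0, 1.0, 1.0))
        write_image_stack(phantom, rois, tmp_path)
        tifffile.imwrite(tmp_path / "slice_0003.tif",
                         np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError, match="slice_0003"):
            read_image_stack(tmp_path)

    def test_unknown_gray_value_reported_by_slice(self, tmp_path):
        import tifffile

        phantom, rois = build_cylinder_phantom(spacing=(1.0, 1.0, 1.0))
        write_image_stack(phantom, rois, tmp_path)
        nx, ny, _ = phantom.shape
        rogue = np.full((nx, ny), 77, dtype=np.uint8)
        tifffile.imwrite(tmp_path / "slice_0002.tif", rogue)
        with pytest.raises(ValueError, match="slice_0002"):
            read_image_stack(tmp_path)

    def test_missing_manifest_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image_stack(tmp_path)


class TestPlanningGrid:
    def test_identity_when_dims_match_source(self):
        phantom, rois = build_cylinder_phantom(spacing=(1.0, 1.0, 1.0))
        coarse, rois_c = voxelize_to_planning_grid(phantom, rois,
                                                   dims=phantom.shape)
        assert np.array_equal(coarse.material_grid, phantom.material_grid)
        assert np.array_equal(rois_c["tumor"], rois["tumor"])

    def test_uniform_cylinder_gives_two_materials(self):
        phantom, rois = build_cylinder_phantom()
        coarse, _ = voxelize_to_planning_grid(phantom, rois, dims=(21, 21, 21),
                                              n_materials=56)
        assert len(np.unique(coarse.material_grid)) == 2

    def test_physical_extent_preserved(self):
        phantom, rois = build_cylinder_phantom()
        dims = (21, 21, 25)
        coarse, _ = voxelize_to_planning_grid(phantom, rois, dims=dims)
        for a in range(3):
            assert coarse.spacing[a] * dims[a] == pytest.approx(
                phantom.spacing[a] * phantom.shape[a])

    def test_tumor_volume_approximately_conserved(self):
        # voxel-centre membership already biases a 1.5 cm-radius disc by
        # ~13% at 0.5 cm pitch, so conservation is checked against the
        # fine-grid mask and, loosely, against the analytic cylinder
        phantom, rois = build_cylinder_phantom()
        vol_fine = rois["tumor"].sum() * np.prod(phantom.spacing)
        dims = (24, 24, 24)
        coarse, rois_c = voxelize_to_planning_grid(phantom, rois, dims=dims)
        vol_coarse = rois_c["tumor"].sum() * np.prod(coarse.spacing)
        analytic = np.pi * 1.5**2 * 5.0
        assert abs(vol_coarse - vol_fine) <= 0.15 * vol_fine
        assert abs(vol_coarse - analytic) <= 0.25 * analytic

    def test_tiny_roi_keeps_single_nearest_voxel(self):
        phantom, rois = build_head_phantom()
        coarse, rois_c = voxelize_to_planning_grid(phantom, rois,
                                                   dims=(12, 13, 16))
        for name in ("lens_L", "lens_R"):
            assert rois_c[name].sum() >= 1

    def test_masks_stay_disjoint_after_downsampling(self):
        phantom, rois = build_head_phantom()
        _, rois_c = voxelize_to_planning_grid(phantom, rois, dims=(21, 21, 25))
        assert not (rois_c["tumor"] & rois_c["normal_brain"]).any()

    def test_zero_dims_rejected(self):
        phantom, rois = build_cylinder_phantom()
        with pytest.raises(ValueError):
            voxelize_to_planning_grid(phantom, rois, dims=(0, 21, 25))
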