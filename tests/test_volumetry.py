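import numpy as np
import pytest

import ctlungvol as cv
from ctlungvol.errors import AlignmentError, DegenerateInputError, SeedError
from ctlungvol.image import CTVolume, Mask3D, RegionLabelMap, DEFAULT_LABELS
from ctlungvol.volumetry import (
    VolumeReport,
    compute_volumes,
    exclude_airways,
    extract_body_mask,
    extract_lung_mask,
    resample_slices,
)


def cube_volume(hu, shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.full(shape, hu, dtype=np.float32), spacing)


class TestBodyMask:
    def test_all_air_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            extract_body_mask(cube_volume(-1000.0))

    def test_cylinder_with_air_holes_fills_to_cylinder(self):
        """Soft-tissue cylinder containing air ellipsoids -> filled cylinder."""
        spec = cv.PhantomSpec.compact(trachea_radius_mm=None)
        ct, _, _ = cv.make_lung_phantom(spec)
        body = extract_body_mask(ct)
        # analytic cylinder membership at voxel centers
        nz, ny, nx = ct.shape
        z = (np.arange(nz) + 0.5)[:, None, None]
        y = (np.arange(ny) + 0.5)[None, :, None]
        x = (np.arange(nx) + 0.5)[None, None, :]
        cy, cx = spec.body_center_yx
        expected = (
            ((y - cy) ** 2 + (x - cx) ** 2 <= spec.body_radius_mm**2)
            & (z >= spec.body_z_mm[0])
            & (z <= spec.body_z_mm[1])
        )
        assert np.array_equal(body.data, np.broadcast_to(expected, ct.shape))

    def test_largest_component_wins(self):
        hu = np.full((10, 10, 30), -1000.0, dtype=np.float32)
        hu[2:8, 2:8, 2:10] = 40.0   # large blob
        hu[4:6, 4:6, 20:24] = 40.0  # small blob
        body = extract_body_mask(CTVolume(hu, (1, 1, 1)))
        assert body.data[:, :, 2:10].sum() == 6 * 6 * 8
        assert body.data[:, :, 20:24].sum() == 0


class TestLungMask:
    def test_uniform_tissue_gives_empty_mask(self):
        ct = cube_volume(40.0)
        body = Mask3D(np.ones(ct.shape, bool), ct.spacing)
        with pytest.warns(UserWarning, match="empty lung mask"):
            lung = extract_lung_mask(ct, body)
        assert not lung.data.any()

    def test_matches_voxelwise_predicate_on_phantom(self, compact_phantom):
        """Oracle: in-range AND inside-body AND in-a-retained-component."""
        spec, ct, labels, _ = compact_phantom
        body = extract_body_mask(ct)
        lung = extract_lung_mask(ct, body)
        predicate = (
            (ct.intensities >= -1000) & (ct.intensities <= 0) & body.data
        )
        # phantom lobes + trachea column all exceed the 1-mL speck floor,
        # so the retained-component filter keeps every predicate voxel
        assert np.array_equal(lung.data, predicate)

    def test_threshold_excluding_lobe_hu_gives_empty(self):
        ct, _, _ = cv.make_lung_phantom(
            cv.PhantomSpec.compact(trachea_radius_mm=None)
        )
        body = extract_body_mask(ct)
        with pytest.warns(UserWarning):
            lung = extract_lung_mask(ct, body, hu_low=-1000, hu_high=-900)
        assert not lung.data.any()

    def test_threshold_monotonicity(self, compact_phantom):
        """Widening the HU window never decreases any region volume."""
        spec, ct, labels, _ = compact_phantom
        body = extract_body_mask(ct)
        narrow = extract_lung_mask(ct, body, -900, -100)
        wide = extract_lung_mask(ct, body, -1000, 0)
        v_narrow = compute_volumes(narrow, labels)
        v_wide = compute_volumes(wide, labels)
        for region, v in v_narrow.volumes_ml.items():
            assert v_wide[region] >= v

    def test_speck_filter_drops_small_components(self):
        hu = np.full((30, 30, 30), 40.0, dtype=np.float32)
        hu[5:25, 5:25, 5:25] = 40.0
        hu[10, 10, 10] = -500.0  # single-voxel speck: 0.001 mL
        hu[15:20, 15:20, 15:20] = -500.0  # 125 voxels = 0.125 mL < 1 mL
        ct = CTVolume(hu, (1, 1, 1))
        body = Mask3D(np.ones(ct.shape, bool), ct.spacing)
        with pytest.warns(UserWarning):
            lung = extract_lung_mask(ct, body, min_component_ml=1.0)
        assert not lung.data.any()


class TestAirwayExclusion:
    def test_label_map_mode_is_set_difference(self, compact_phantom):
        spec, ct, labels, _ = compact_phantom
        body = extract_body_mask(ct)
        lung = extract_lung_mask(ct, body)
        out = exclude_airways(lung, ct, labels)
        expected = lung.data & ~labels.mask_for("airway")
        assert np.array_equal(out.data, expected)

    def test_seed_growth_removes_exactly_the_tube(self, compact_phantom):
        """Tracheal tube of known voxel count is removed voxel for voxel."""
        spec, ct, labels, _ = compact_phantom
        body = extract_body_mask(ct)
        lung = extract_lung_mask(ct, body)
        tube_voxels = int((lung.data & labels.mask_for("airway")).sum())
        assert tube_voxels > 0
        out = exclude_airways(lung, ct, None)
        removed = int(lung.data.sum() - out.data.sum())
        assert removed == tube_voxels

    def test_no_airway_present_is_noop(self):
        spec = cv.PhantomSpec.compact(trachea_radius_mm=None)
        ct, labels, _ = cv.make_lung_phantom(spec)
        body = extract_body_mask(ct)
        lung = extract_lung_mask(ct, body)
        out = exclude_airways(lung, ct, None)
        assert np.array_equal(out.data, lung.data)

    def test_seed_outside_air_range_raises(self, compact_phantom):
        spec, ct, labels, _ = compact_phantom
        body = extract_body_mask(ct)
        lung = extract_lung_mask(ct, body)
        with pytest.raises(SeedError):
            exclude_airways(lung, ct, (0, 0, 0) if ct.intensities[0, 0, 0] > 0
                            else (70, 3, 3))


class TestResampleSlices:
    def test_identity_at_native_spacing(self, compact_phantom):
        _, ct, _, _ = compact_phantom
        out = resample_slices(ct, ct.spacing[0])
        assert np.array_equal(out.intensities, ct.intensities)
        assert out.spacing == ct.spacing

    def test_constant_volume_stays_constant(self):
        ct = cube_volume(-300.0, shape=(40, 8, 8), spacing=(0.5, 1, 1))
        out = resample_slices(ct, 5.0)
        assert np.allclose(out.intensities, -300.0)
        assert out.spacing[0] == 5.0

    def test_mean_pooling_values(self):
        hu = np.zeros((4, 2, 2), dtype=np.float32)
        hu[0] = 0; hu[1] = 100; hu[2] = 200; hu[3] = 300
        out = resample_slices(CTVolume(hu, (1, 1, 1)), 2.0)
        assert out.shape == (2, 2, 2)
        assert np.allclose(out.intensities[0], 50.0)
        assert np.allclose(out.intensities[1], 250.0)

    def test_rejects_bad_thickness(self, compact_phantom):
        _, ct, _, _ = compact_phantom
        with pytest.raises(ValueError):
            resample_slices(ct, -1.0)
        with pytest.raises(ValueError):
            resample_slices(ct, float("nan"))
        with pytest.raises(ValueError):
            resample_slices(ct, 0.1)  # below native spacing


class TestComputeVolumes:
    def test_empty_lung_mask_gives_zero_everywhere(self, compact_phantom):
        _, ct, labels, _ = compact_phantom
        lung = Mask3D(np.zeros(ct.shape, bool), ct.spacing)
        rep = compute_volumes(lung, labels)
        assert all(v == 0.0 for v in rep.volumes_ml.values())

    def test_unit_conversion_thousand_voxels_is_one_ml(self):
        shape = (10, 10, 10)
        labels = RegionLabelMap(
            np.full(shape, DEFAULT_LABELS["right_upper_lobe"], dtype=np.int16),
            (1, 1, 1),
        )
        lung = Mask3D(np.ones(shape, bool), (1, 1, 1))
        rep = compute_volumes(lung, labels)
        assert rep["right_upper_lobe"] == pytest.approx(1.0)
        assert rep["right_lung"] == pytest.approx(1.0)
        assert rep["total_lung"] == pytest.approx(1.0)

    def test_ellipsoid_volume_within_2pct_of_analytic(self, compact_phantom):
        spec, ct, labels, truth = compact_phantom
        rep = cv.run_volumetry(ct, labels)
        for lobe, true_ml in truth.lobes_ml.items():
            assert rep[lobe] == pytest.approx(true_ml, rel=0.02)

    def test_additivity_is_exact(self, compact_phantom):
        spec, ct, labels, _ = compact_phantom
        rep = cv.run_volumetry(ct, labels)
        lobes = [rep[l] for l in cv.LOBE_NAMES]
        assert rep["total_lung"] == pytest.approx(sum(lobes), abs=1e-9)
        assert rep["right_lung"] == pytest.approx(
            rep["right_upper_lobe"] + rep["right_middle_lobe"]
            + rep["right_lower_lobe"], abs=1e-9)
        assert rep["left_lung"] == pytest.approx(
            rep["left_upper_lobe"] + rep["left_lower_lobe"], abs=1e-9)
        assert rep["upper_lobes"] == pytest.approx(
            rep["right_upper_lobe"] + rep["left_upper_lobe"], abs=1e-9)
        assert rep["lower_lobes"] == pytest.approx(
            rep["right_lower_lobe"] + rep["left_lower_lobe"], abs=1e-9)

    def test_nearest_lobe_fallback_for_unlabeled_voxels(self):
        shape = (10, 10, 20)
        lab = np.zeros(shape, dtype=np.int16)
        lab[:, :, :8] = DEFAULT_LABELS["right_upper_lobe"]
        lab[:, :, 12:] = DEFAULT_LABELS["left_upper_lobe"]
        labels = RegionLabelMap(lab, (1, 1, 1))
        lung = Mask3D(np.ones(shape, bool), (1, 1, 1))
        rep = compute_volumes(lung, labels)
        # the unlabeled middle band splits to the nearest lobes
        assert rep["total_lung"] == pytest.approx(2.0)
        assert rep["right_upper_lobe"] == pytest.approx(1.0)
        assert rep["left_upper_lobe"] == pytest.approx(1.0)

    def test_shape_mismatch_raises(self, compact_phantom):
        _, ct, labels, _ = compact_phantom
        lung = Mask3D(np.zeros((5, 5, 5), bool), (1, 1, 1))
        with pytest.raises(AlignmentError):
            compute_volumes(lung, labels)


class TestGeometricInvariances:
    def test_translation_invariance(self):
        """Shifting the phantom by whole voxels changes no reported volume."""
        base = cv.PhantomSpec.compact()
        shifted_lobes = {
            name: cv.synthetic.Ellipsoid(
                (e.center[0] + 3.0, e.center[1] + 2.0, e.center[2] - 4.0),
                e.half_axes,
            )
            for name, e in base.lobes.items()
        }
        shifted = cv.PhantomSpec.compact(
            lobes=shifted_lobes,
            body_center_yx=(72.0, 66.0),
            body_z_mm=(23.0, 138.0),
            trachea_yx=(72.0, 66.0),
            trachea_z_mm=(3.0, 58.0),
            extent_mm=(143.0, 142.0, 140.0),
        )
        rep0 = cv.run_volumetry(*cv.make_lung_phantom(base)[:2])
        rep1 = cv.run_volumetry(*cv.make_lung_phantom(shifted)[:2])
        for region in rep0.volumes_ml:
            assert rep0[region] == pytest.approx(rep1[region], abs=1e-9)

    def test_resolution_convergence(self):
        """Relative volume error decreases as spacing shrinks (2, 1, 0.5 mm).

        Voxel-center counting error oscillates with the grid phase, so the
        error is averaged over sub-voxel placements of the same phantom.
        """
        mean_errors = []
        for s in (2.0, 1.0, 0.5):
            errs = []
            for shift in (0.0, 0.3, 0.7):
                lobes = {
                    name: cv.synthetic.Ellipsoid(
                        (e.center[0] + shift * s, e.center[1] + shift * s,
                         e.center[2]),
                        e.half_axes,
                    )
                    for name, e in cv.synthetic._compact_lobes().items()
                }
                spec = cv.PhantomSpec.compact(spacing=(s, s, s), lobes=lobes)
                ct, labels, truth = cv.make_lung_phantom(spec)
                rep = cv.run_volumetry(ct, labels)
                errs.append(max(abs(rep[l] / truth.lobes_ml[l] - 1.0)
                                for l in cv.LOBE_NAMES))
            mean_errors.append(np.mean(errs))
        assert mean_errors[0] > mean_errors[1] > mean_errors[2]
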