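"""Synthetic phantom generator: closed-form truth, determinism,
artifacts and resampling."""

import numpy as np
import pytest

from legquant.phantom import (
    ArtifactSpec,
    PhantomSpec,
    analytic_slice_areas,
    analytic_volumes,
    generate_phantom,
    inject_artifact,
    resample_phantom,
    sample_desk_cohort,
)
from tests.conftest import tiny_spec


def constant_radius_spec(**overrides):
    defaults = dict(
        grid_shape=(160, 80, 200),
        spacing_mm=(2.0, 2.0, 5.0),
        sft_radius_knots=((-1.0, 40.0), (1.5, 40.0)),
        sct_thickness_knots=((-1.0, 10.0), (1.5, 10.0)),
        noise_sd=0.0,
        bias_field_amplitude=0.0,
        seed=3,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


class TestClosedForm:
    def test_constant_annulus_slice_areas(self):
        spec = constant_radius_spec()
        for z in (100.0, 400.0, 700.0):
            areas = analytic_slice_areas(spec, z, "right")
            assert areas["SFT"] == pytest.approx(np.pi * 40.0**2)
            assert areas["SCT"] == pytest.approx(np.pi * (50.0**2 - 40.0**2))

    def test_symmetric_spec_has_equal_sides(self):
        vols = analytic_volumes(constant_radius_spec())
        assert vols[("left", "SCT")] == pytest.approx(vols[("right", "SCT")], abs=1e-12)
        assert vols[("left", "SFT")] == pytest.approx(vols[("right", "SFT")], abs=1e-12)

    def test_asymmetry_factor_scales_left_annulus_only(self):
        base = analytic_volumes(constant_radius_spec())
        asym = analytic_volumes(constant_radius_spec(asymmetry_factor=1.5))
        # annulus with thickness 15 instead of 10: (55^2-40^2)/(50^2-40^2)
        expected_ratio = (55.0**2 - 40.0**2) / (50.0**2 - 40.0**2)
        assert asym[("left", "SCT")] == pytest.approx(
            base[("left", "SCT")] * expected_ratio, rel=1e-9
        )
        assert asym[("right", "SCT")] == pytest.approx(base[("right", "SCT")])
        # right SFT shifts marginally: the torso bridge narrows as the
        # left outer radius grows
        assert asym[("right", "SFT")] == pytest.approx(base[("right", "SFT")], rel=0.005)

    def test_voxel_counts_converge_to_analytic(self, noiseless_phantom):
        truth = noiseless_phantom
        spec = truth.spec
        lab = truth.labels.data
        xs = truth.labels.axis_coords(0)
        zs = truth.labels.slice_zs
        keep = zs <= max(spec.femoral_head_z_mm.values())
        dx, dy, dz = spec.spacing_mm
        for side, sel in (("left", xs < 0), ("right", xs >= 0)):
            for tissue, code in (("SCT", 1), ("SFT", 2)):
                vox_l = (lab[sel][:, :, keep] == code).sum() * dx * dy * dz / 1e6
                ana = truth.analytic_volumes_l[(side, tissue)]
                assert vox_l == pytest.approx(ana, rel=0.02)

    def test_labels_partition_grid(self, noiseless_phantom):
        lab = noiseless_phantom.labels.data
        counts = np.bincount(lab.ravel(), minlength=3)
        assert counts.sum() == lab.size
        assert counts[1] > 0 and counts[2] > 0


class TestGeneration:
    def test_same_seed_bit_identical(self):
        spec = tiny_spec(seed=9)
        a = generate_phantom(spec)
        b = generate_phantom(tiny_spec(seed=9))
        np.testing.assert_array_equal(a.volume.data, b.volume.data)
        np.testing.assert_array_equal(a.labels.data, b.labels.data)

    def test_different_seed_different_noise(self):
        a = generate_phantom(tiny_spec(seed=1))
        b = generate_phantom(tiny_spec(seed=2))
        assert not np.array_equal(a.volume.data, b.volume.data)
        np.testing.assert_array_equal(a.labels.data, b.labels.data)

    def test_landmarks_inside_grid(self):
        truth = generate_phantom(tiny_spec())
        zs = truth.volume.slice_zs
        for name in ("ankle", "knee", "femoral_head"):
            for side in ("left", "right"):
                assert zs[0] <= truth.landmarks.z(name, side) <= zs[-1]

    @pytest.mark.parametrize(
        "overrides, dim",
        [
            (dict(grid_shape=(16, 48, 48)), "x"),
            (dict(grid_shape=(48, 12, 48)), "y"),
            (dict(grid_shape=(48, 48, 20)), "z"),
        ],
    )
    def test_too_small_grid_names_dimension(self, overrides, dim):
        with pytest.raises(ValueError, match=dim):
            generate_phantom(tiny_spec(**overrides))

    def test_invalid_landmark_order_rejected(self):
        with pytest.raises(ValueError, match="ordering"):
            tiny_spec(knee_z_mm=5.0)

    def test_cohort_specs_are_valid_and_varied(self):
        specs = sample_desk_cohort(8, seed=3, asymmetric_fraction=0.5)
        truths = [generate_phantom(s) for s in specs[:2]]
        assert truths[0].volume.shape == (64, 64, 136)
        knees = {round(s.knee_z_mm["left"], 1) for s in specs}
        assert len(knees) > 4  # anatomy actually varies


class TestArtifacts:
    def test_empty_slab_is_noop(self, desk_phantom):
        out = inject_artifact(
            desk_phantom, ArtifactSpec("water_fat_swap", 300.0, 300.0)
        )
        np.testing.assert_array_equal(out.volume.data, desk_phantom.volume.data)
        assert out.corrupted_slabs == []

    def test_water_fat_swap_exchanges_label_means(self, desk_phantom):
        art = ArtifactSpec("water_fat_swap", 300.0, 450.0)
        out = inject_artifact(desk_phantom, art)
        zs = desk_phantom.volume.slice_zs
        in_slab = (zs >= 300.0) & (zs <= 450.0)
        lab = desk_phantom.labels.data[:, :, in_slab]
        before = desk_phantom.volume.data[:, :, in_slab]
        after = out.volume.data[:, :, in_slab]
        m_sct_before = before[lab == 1].mean()
        m_sft_before = before[lab == 2].mean()
        assert after[lab == 1].mean() == pytest.approx(m_sft_before, rel=0.05)
        assert after[lab == 2].mean() == pytest.approx(m_sct_before, rel=0.15)
        # labels untouched: the corruption degrades the image, not the truth
        np.testing.assert_array_equal(out.labels.data, desk_phantom.labels.data)
        assert out.corrupted_slabs[0]["kind"] == "water_fat_swap"

    def test_blur_sigma_zero_is_noop(self, desk_phantom):
        out = inject_artifact(
            desk_phantom,
            ArtifactSpec("partial_volume_blur", 300.0, 450.0, sigma_mm=0.0),
        )
        np.testing.assert_array_equal(out.volume.data, desk_phantom.volume.data)

    def test_blur_smooths_only_the_slab(self, desk_phantom):
        out = inject_artifact(
            desk_phantom,
            ArtifactSpec("partial_volume_blur", 300.0, 450.0, sigma_mm=10.0),
        )
        zs = desk_phantom.volume.slice_zs
        in_slab = (zs >= 300.0) & (zs <= 450.0)
        far = zs > 520.0
        assert not np.array_equal(
            out.volume.data[:, :, in_slab], desk_phantom.volume.data[:, :, in_slab]
        )
        np.testing.assert_array_equal(
            out.volume.data[:, :, far], desk_phantom.volume.data[:, :, far]
        )

    def test_slab_outside_grid_fails(self, desk_phantom):
        with pytest.raises(ValueError, match="outside"):
            inject_artifact(
                desk_phantom, ArtifactSpec("water_fat_swap", 5000.0, 6000.0)
            )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ArtifactSpec("ghosting", 0.0, 10.0)


class TestResampling:
    def test_identity_spacing_copies(self, desk_phantom):
        out = resample_phantom(desk_phantom, desk_phantom.volume.spacing)
        np.testing.assert_array_equal(out.volume.data, desk_phantom.volume.data)
        assert out.volume.data is not desk_phantom.volume.data

    def test_halved_z_resolution_preserves_volumes(self, noiseless_phantom):
        spec = noiseless_phantom.spec
        out = resample_phantom(noiseless_phantom, (2.0, 2.0, 10.0))
        assert out.analytic_volumes_l == noiseless_phantom.analytic_volumes_l
        zs = out.labels.slice_zs
        keep = zs <= max(spec.femoral_head_z_mm.values())
        vox = (out.labels.data[:, :, keep] == 1).sum() * 2.0 * 2.0 * 10.0 / 1e6
        total_sct = sum(
            v for (s, t), v in out.analytic_volumes_l.items() if t == "SCT"
        )
        assert vox == pytest.approx(total_sct, rel=0.02)

    def test_inplane_downsampling_keeps_slice_areas(self, noiseless_phantom):
        out = resample_phantom(noiseless_phantom, (4.0, 4.0, 5.0))
        spec = noiseless_phantom.spec
        k = 80  # a mid-calf slice
        z = out.labels.slice_zs[k]
        xs = out.labels.axis_coords(0)
        area_vox = (out.labels.data[xs >= 0][:, :, k] == 1).sum() * 16.0
        area_ana = analytic_slice_areas(spec, float(z), "right")["SCT"]
        assert area_vox == pytest.approx(area_ana, rel=0.03)

    def test_landmarks_unchanged_in_mm(self, desk_phantom):
        out = resample_phantom(desk_phantom, (10.0, 10.0, 10.0))
        assert out.landmarks.symphysis_z == desk_phantom.landmarks.symphysis_z
        assert out.landmarks.ankle_z == desk_phantom.landmarks.ankle_z
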