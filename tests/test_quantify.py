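"""Quantification: per-slice areas, volumes, asymmetry, longitudinal
deltas and report emission."""

import json

import numpy as np
import pandas as pd
import pytest

from legquant.phantom import PhantomSpec, generate_phantom
from legquant.profiles import TissueProfile
from legquant.quantify import (
    asymmetry,
    compute_profile,
    longitudinal_delta,
    render_report,
)
from legquant.segmentation import split_legs


@pytest.fixture(scope="module")
def annulus_truth():
    """Constant-radius annulus phantom: volumes are fully closed-form."""
    spec = PhantomSpec(
        grid_shape=(160, 80, 200),
        spacing_mm=(2.0, 2.0, 5.0),
        sft_radius_knots=((-1.0, 40.0), (1.5, 40.0)),
        sct_thickness_knots=((-1.0, 10.0), (1.5, 10.0)),
        noise_sd=0.0,
        bias_field_amplitude=0.0,
        seed=2,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="module")
def annulus_profile(annulus_truth):
    left, right = split_legs(annulus_truth.labels)
    return compute_profile(left, right, annulus_truth.landmarks)


class TestComputeProfile:
    def test_mass_conservation_native_axis(self, annulus_profile):
        dz = annulus_profile.spacing_mm[2]
        for (leg, tissue), vol in annulus_profile.volumes_l.items():
            sub = annulus_profile.native[
                (annulus_profile.native["leg"] == leg)
                & (annulus_profile.native["tissue"] == tissue)
            ]
            integral = float(sub["area_cm2"].sum() * dz / 10.0 / 1000.0)
            assert vol == pytest.approx(integral, rel=1e-3)

    def test_volumes_match_closed_form(self, annulus_truth, annulus_profile):
        for key, analytic in annulus_truth.analytic_volumes_l.items():
            assert annulus_profile.volumes_l[key] == pytest.approx(analytic, rel=0.02)

    def test_empty_segmentation_gives_zero(self, annulus_truth):
        empty = annulus_truth.labels.with_data(
            np.zeros_like(annulus_truth.labels.data)
        )
        prof = compute_profile(empty, empty, annulus_truth.landmarks)
        assert (prof.native["area_cm2"] == 0).all()
        assert all(v == 0.0 for v in prof.volumes_l.values())

    def test_no_landmarks_native_only(self, annulus_truth):
        left, right = split_legs(annulus_truth.labels)
        prof = compute_profile(left, right, None)
        assert prof.normalized is None
        assert prof.volumes_l[("left", "SFT")] > 0

    def test_crop_excludes_superior_slices(self, annulus_truth, annulus_profile):
        z_max = annulus_truth.landmarks.max_femoral_head_z
        assert annulus_profile.native["z_mm"].max() <= z_max


class TestAsymmetry:
    def test_identical_legs_have_zero_asymmetric_volume(self, annulus_profile):
        rep = asymmetry(annulus_profile)
        for tissue, v in rep.asymmetric_volume_l.items():
            assert v == pytest.approx(0.0, abs=0.02)

    def test_scaled_left_leg_algebra(self, annulus_profile):
        prof = annulus_profile
        scaled = prof.normalized.copy()
        left_sct = (scaled["leg"] == "left") & (scaled["tissue"] == "SCT")
        scaled.loc[left_sct, "area_cm2"] *= 1.5
        prof2 = TissueProfile(
            native=prof.native, normalized=scaled,
            volumes_l=dict(prof.volumes_l), spacing_mm=prof.spacing_mm,
            meta=prof.meta,
        )
        rep = asymmetry(prof2)
        # excess = 0.5 x right SCT profile -> half the right SCT volume
        expected = 0.5 * prof.volumes_l[("right", "SCT")]
        assert rep.asymmetric_volume_l["SCT"] == pytest.approx(expected, rel=0.03)
        sct_rows = rep.table[rep.table["tissue"] == "SCT"]
        attributed = sct_rows.loc[sct_rows["excess_cm2"] > 0.1, "excess_side"]
        assert (attributed == "left").all()

    def test_one_leg_missing_fails(self, annulus_profile):
        only_left = annulus_profile.normalized[
            annulus_profile.normalized["leg"] == "left"
        ]
        prof = TissueProfile(
            native=annulus_profile.native, normalized=only_left,
            volumes_l=annulus_profile.volumes_l,
            spacing_mm=annulus_profile.spacing_mm, meta=annulus_profile.meta,
        )
        with pytest.raises(ValueError, match="right"):
            asymmetry(prof)

    def test_shared_plus_excess_equals_max(self, annulus_profile):
        rep = asymmetry(annulus_profile)
        wide = annulus_profile.normalized.pivot_table(
            index=["norm_pos", "tissue"], columns="leg", values="area_cm2"
        ).reset_index()
        mx = np.maximum(wide["left"], wide["right"])
        np.testing.assert_allclose(
            rep.table["shared_cm2"] + rep.table["excess_cm2"], mx, atol=1e-9
        )


class TestLongitudinal:
    def _shrunk_below_knee(self, factor=0.8):
        base = PhantomSpec(
            grid_shape=(120, 60, 192),
            spacing_mm=(2.5, 2.5, 5.0),
            leg_center_offset_mm=70.0,
            sft_radius_knots=((-1.0, 25.0), (0.0, 40.0), (1.045, 50.0), (1.5, 50.0)),
            sct_thickness_knots=((-1.0, 8.0), (0.0, 12.0), (1.045, 18.0), (1.5, 18.0)),
            noise_sd=0.0, bias_field_amplitude=0.0, seed=7,
        )
        followup = PhantomSpec(
            **{
                **{k: getattr(base, k) for k in (
                    "grid_shape", "spacing_mm", "leg_center_offset_mm",
                    "sft_radius_knots", "noise_sd",
                    "bias_field_amplitude", "seed",
                )},
                "sct_thickness_knots": (
                    (-1.0, 8.0 * factor), (0.0, 12.0),
                    (1.045, 18.0), (1.5, 18.0),
                ),
            }
        )
        return base, followup

    def _profile_of(self, spec):
        truth = generate_phantom(spec)
        left, right = split_legs(truth.labels)
        return truth, compute_profile(left, right, truth.landmarks)

    def test_identical_scans_zero_delta(self, annulus_profile):
        delta = longitudinal_delta(annulus_profile, annulus_profile)
        assert np.allclose(delta.table["delta_cm2"], 0.0)
        assert all(v == 0.0 for v in delta.volume_change_l.values())

    def test_below_knee_shrinkage_is_localized_and_quantified(self):
        base_spec, fol_spec = self._shrunk_below_knee()
        truth_b, prof_b = self._profile_of(base_spec)
        truth_f, prof_f = self._profile_of(fol_spec)
        delta = longitudinal_delta(prof_b, prof_f)
        sct = delta.table[(delta.table["tissue"] == "SCT")
                          & (delta.table["leg"] == "right")]
        below = sct[sct["norm_pos"] < -0.1]["delta_cm2"]
        above = sct[sct["norm_pos"] > 0.3]["delta_cm2"]
        assert below.mean() > 5 * max(above.abs().mean(), 0.01)
        expected = (
            truth_b.analytic_volumes_l[("right", "SCT")]
            - truth_f.analytic_volumes_l[("right", "SCT")]
        )
        assert delta.volume_change_l[("right", "SCT")] == pytest.approx(
            expected, rel=0.05
        )

    def test_unnormalized_profiles_rejected(self, annulus_profile):
        bare = TissueProfile(
            native=annulus_profile.native, normalized=None,
            volumes_l=annulus_profile.volumes_l,
            spacing_mm=annulus_profile.spacing_mm,
        )
        with pytest.raises(ValueError, match="normalized"):
            longitudinal_delta(bare, annulus_profile)


class TestRenderReport:
    def test_emits_csv_json_and_figures(self, annulus_profile, tmp_path):
        rep = asymmetry(annulus_profile)
        files = render_report(annulus_profile, tmp_path, asym=rep)
        for key in ("native_csv", "normalized_csv", "summary_json",
                    "figure_svg", "figure_png"):
            assert key in files

    def test_json_volumes_match_profile_exactly(self, annulus_profile, tmp_path):
        files = render_report(annulus_profile, tmp_path)
        with open(files["summary_json"]) as fh:
            summary = json.load(fh)
        for (leg, tissue), v in annulus_profile.volumes_l.items():
            assert summary["volumes_l_exact"][f"{leg}|{tissue}"] == v
            assert summary["volumes_l"][f"{leg}|{tissue}"] == round(v, 1)

    def test_symmetric_phantom_renders_equal_widths(self, annulus_profile, tmp_path):
        files = render_report(annulus_profile, tmp_path)
        table = pd.read_csv(files["normalized_csv"])
        wide = table.pivot_table(
            index=["norm_pos", "tissue"], columns="leg", values="area_cm2"
        )
        np.testing.assert_allclose(wide["left"], wide["right"], atol=0.5)
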