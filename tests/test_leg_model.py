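"""Canonical leg coordinate system: slice targets, landmark recovery,
profile normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from legquant.leg_model import (
    LandmarkSet,
    LegModel,
    SlicePositionTarget,
    build_slice_targets,
    crop_superior_to_femoral_heads,
    evaluate_landmarks,
    landmarks_from_position_curve,
    normalize_profile,
    normalized_volumes_l,
)
from legquant.profiles import TissueProfile
from legquant.volume import Volume3D


def simple_landmarks(ankle=0.0, knee=400.0, sym=820.0, fh=890.0) -> LandmarkSet:
    return LandmarkSet(
        ankle_z={"left": ankle, "right": ankle},
        knee_z={"left": knee, "right": knee},
        femoral_head_z={"left": fh, "right": fh},
        symphysis_z=sym,
    )


class TestBuildSliceTargets:
    def test_positions_at_landmarks_are_canonical(self):
        lm = simple_landmarks()
        t = build_slice_targets(lm, [0.0, 400.0, 820.0, 890.0])
        np.testing.assert_allclose(t.positions[:, 0], [-1.0, 0.0, 1.045, 1.220])
        np.testing.assert_allclose(t.positions[:, 1], [-1.0, 0.0, 1.045, 1.220])

    def test_linear_interpolation_between_landmarks(self):
        lm = simple_landmarks()
        t = build_slice_targets(lm, [200.0, 610.0])
        assert t.positions[0, 0] == pytest.approx(-0.5)
        # hand-computed: 0 + 1.045 * (610 - 400) / (820 - 400)
        assert t.positions[1, 0] == pytest.approx(0.5225)

    def test_extrapolation_uses_nearest_segment_slope(self):
        lm = simple_landmarks()
        t = build_slice_targets(lm, [-400.0, 960.0])
        assert t.positions[0, 0] == pytest.approx(-2.0)
        # above femoral head: slope (1.220 - 1.045) / 70 per mm
        assert t.positions[1, 0] == pytest.approx(1.220 + 0.175 / 70.0 * 70.0)

    def test_landmark_ordering_violation_names_side(self):
        lm = simple_landmarks()
        lm.knee_z["left"] = -5.0
        with pytest.raises(ValueError, match="left"):
            build_slice_targets(lm, [0.0, 100.0])

    @given(
        ankle=st.floats(0, 50),
        leg=st.floats(300, 500),
        dz=st.floats(2.0, 8.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_z(self, ankle, leg, dz):
        lm = simple_landmarks(ankle, ankle + leg, ankle + 2.05 * leg, ankle + 2.22 * leg)
        zs = np.arange(0.0, ankle + 2.4 * leg, dz)
        t = build_slice_targets(lm, zs)
        assert np.all(np.diff(t.positions[:, 0]) >= -1e-12)


class TestLandmarkRecovery:
    def test_noiseless_round_trip_within_half_slice(self):
        lm = simple_landmarks(10.0, 413.0, 830.0, 902.0)
        zs = np.arange(0.0, 950.0, 2.5)
        targets = build_slice_targets(lm, zs)
        rec = landmarks_from_position_curve(targets)
        ev = evaluate_landmarks(rec, lm)
        assert ev.n_missing == 0
        assert ev.table["dz_mm"].max() <= 1.25 + 1e-9

    def test_constant_curve_flags_not_detected(self):
        zs = np.arange(0.0, 900.0, 5.0)
        targets = SlicePositionTarget(zs, np.full((len(zs), 2), 0.3))
        rec = landmarks_from_position_curve(targets)
        assert rec.ankle_z["left"] is None
        assert rec.knee_z["right"] is None
        # the 0.3 level itself is never crossed either
        assert rec.symphysis_z is None

    def test_noisy_recovery_mean_error_below_5mm(self):
        lm = simple_landmarks(10.0, 410.0, 828.0, 898.0)
        zs = np.arange(0.0, 950.0, 2.5)
        clean = build_slice_targets(lm, zs)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = SlicePositionTarget(
                zs, clean.positions + rng.normal(0, 0.01, clean.positions.shape)
            )
            rec = landmarks_from_position_curve(noisy)
            ev = evaluate_landmarks(rec, lm)
            assert ev.n_missing == 0
            errs.append(ev.mean_dz_mm)
        assert float(np.mean(errs)) < 5.0


class TestEvaluateLandmarks:
    def test_identity_gives_zero_and_full_fraction(self):
        lm = simple_landmarks()
        ev = evaluate_landmarks(lm, lm)
        assert ev.mean_dz_mm == 0.0
        assert ev.fraction_within == 1.0

    def test_uniform_shift(self):
        lm = simple_landmarks()
        shifted = simple_landmarks(7.0, 407.0, 827.0, 897.0)
        ev = evaluate_landmarks(shifted, lm, threshold_mm=10.0)
        assert ev.mean_dz_mm == pytest.approx(7.0)
        assert ev.fraction_within == 1.0

    def test_mixed_shifts_fraction(self):
        lm = simple_landmarks()
        mixed = simple_landmarks()
        # shift ankles by 2 mm, knees by 12 mm; others exact
        for side in ("left", "right"):
            mixed.ankle_z[side] += 2.0
            mixed.knee_z[side] += 12.0
        ev = evaluate_landmarks(mixed, lm, threshold_mm=10.0)
        by_lm = ev.table.set_index(["landmark", "side"])["dz_mm"]
        assert by_lm[("ankle", "left")] == pytest.approx(2.0)
        assert by_lm[("knee", "left")] == pytest.approx(12.0)
        assert ev.fraction_within == pytest.approx(5.0 / 7.0)

    def test_missing_prediction_counted_separately(self):
        lm = simple_landmarks()
        pred = simple_landmarks()
        pred.ankle_z["left"] = None
        ev = evaluate_landmarks(pred, lm)
        assert ev.n_missing == 1
        assert ev.mean_dz_mm == 0.0


class TestCrop:
    def test_femoral_heads_at_top_removes_nothing(self):
        vol = Volume3D(np.ones((4, 4, 10)), (10, 10, 10))
        lm = simple_landmarks(fh=90.0)
        cropped, zrange = crop_superior_to_femoral_heads(vol, lm)
        assert cropped.shape == vol.shape
        assert zrange == (0.0, 90.0)

    def test_slices_above_femoral_heads_removed(self):
        vol = Volume3D(np.ones((4, 4, 400)), (1, 1, 2.5))
        lm = simple_landmarks(fh=890.0)
        cropped, _ = crop_superior_to_femoral_heads(vol, lm)
        assert np.all(cropped.slice_zs <= 890.0)
        assert cropped.shape[2] == 357  # slices at 0, 2.5, ..., 890

    def test_profile_rows_dropped_consistently(self):
        df = pd.DataFrame({"z_mm": np.arange(0, 1000, 2.5), "area_cm2": 1.0})
        lm = simple_landmarks(fh=890.0)
        out, _ = crop_superior_to_femoral_heads(df, lm)
        assert out["z_mm"].max() <= 890.0
        assert len(out) == 357

    def test_femoral_heads_outside_volume_fail(self):
        vol = Volume3D(np.ones((4, 4, 10)), (10, 10, 10))
        lm = simple_landmarks(fh=500.0)
        with pytest.raises(ValueError, match="outside"):
            crop_superior_to_femoral_heads(vol, lm)


class TestNormalizeProfile:
    def _profile(self, zs, areas_by_leg):
        rows = []
        for leg, areas in areas_by_leg.items():
            for tissue in ("SCT", "SFT"):
                for k, (z, a) in enumerate(zip(zs, areas)):
                    rows.append(
                        {"slice_index": k, "z_mm": z, "leg": leg,
                         "tissue": tissue, "area_cm2": a}
                    )
        native = pd.DataFrame(rows)
        volumes = {}
        dz = zs[1] - zs[0]
        for (leg, tissue), sub in native.groupby(["leg", "tissue"]):
            volumes[(leg, tissue)] = float(sub["area_cm2"].sum() * dz / 10.0 / 1000.0)
        return TissueProfile(native, None, volumes, (1.0, 1.0, dz), {})

    def test_constant_area_stays_constant(self):
        zs = np.arange(0.0, 900.0, 5.0)
        prof = self._profile(zs, {"left": np.full(len(zs), 30.0),
                                  "right": np.full(len(zs), 30.0)})
        lm = simple_landmarks(10.0, 410.0, 828.0, 898.0)
        out = normalize_profile(prof, lm, n_grid=128)
        assert np.allclose(out.normalized["area_cm2"], 30.0)

    def test_normalized_volume_matches_native(self):
        zs = np.arange(0.0, 900.0, 5.0)
        areas = 30.0 + 20.0 * np.sin(zs / 120.0) ** 2
        prof = self._profile(zs, {"left": areas, "right": areas})
        lm = simple_landmarks(10.0, 410.0, 828.0, 898.0)
        out = normalize_profile(prof, lm, n_grid=256)
        vols = normalized_volumes_l(out)
        for key, v in vols.items():
            # native profile extends slightly beyond the canonical range;
            # compare against the native integral restricted to it
            sub = prof.native[
                (prof.native["leg"] == key[0]) & (prof.native["tissue"] == key[1])
            ]
            zsel = (sub["z_mm"] >= 10.0) & (sub["z_mm"] <= 898.0)
            native_v = float(sub.loc[zsel, "area_cm2"].sum() * 5.0 / 10.0 / 1000.0)
            assert v == pytest.approx(native_v, rel=0.01)

    def test_missing_side_is_omitted_with_warning(self):
        zs = np.arange(0.0, 900.0, 5.0)
        prof = self._profile(zs, {"left": np.full(len(zs), 30.0),
                                  "right": np.full(len(zs), 30.0)})
        lm = simple_landmarks(10.0, 410.0, 828.0, 898.0)
        lm.knee_z["right"] = None
        out = normalize_profile(prof, lm, n_grid=64)
        assert set(out.normalized["leg"]) == {"left"}
        assert any("right" in w for w in out.meta["normalize_warnings"])

    def test_leg_length_scaling_invariance(self):
        lm_short = simple_landmarks(10.0, 410.0, 828.0, 898.0)
        lm_long = simple_landmarks(10.0, 490.0, 991.6, 1075.6)  # x1.2 leg
        zs_s = np.arange(0.0, 910.0, 5.0)
        zs_l = np.arange(0.0, 1090.0, 5.0)
        pos_s = build_slice_targets(lm_short, zs_s).positions[:, 0]
        pos_l = build_slice_targets(lm_long, zs_l).positions[:, 0]
        shape = lambda p: 30.0 + 20.0 * np.exp(-(p**2))  # noqa: E731
        prof_s = self._profile(zs_s, {"left": shape(pos_s), "right": shape(pos_s)})
        prof_l = self._profile(zs_l, {"left": shape(pos_l), "right": shape(pos_l)})
        out_s = normalize_profile(prof_s, lm_short, n_grid=128)
        out_l = normalize_profile(prof_l, lm_long, n_grid=128)
        a_s = out_s.normalized.query("leg == 'left' and tissue == 'SCT'")["area_cm2"]
        a_l = out_l.normalized.query("leg == 'left' and tissue == 'SCT'")["area_cm2"]
        np.testing.assert_allclose(a_s.to_numpy(), a_l.to_numpy(), rtol=0.01, atol=0.2)


def test_leg_model_rejects_bad_canonical_positions():
    with pytest.raises(ValueError):
        LegModel(canonical_positions={"ankle": -1.0, "knee": 0.5,
                                     "symphysis": 0.4, "femoral_head": 1.2})
    with pytest.raises(ValueError):
        LegModel(canonical_positions={"ankle": -0.9, "knee": 0.0,
                                     "symphysis": 1.045, "femoral_head": 1.22})
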