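"""Standardized leg coordinate system.

Each axial slice of a lower-extremity scan is assigned a relative
foot--head position per leg within a canonical leg model: ankles at
``-1``, knees at ``0``, symphysis at ``1.045`` and femoral heads at
``1.220``.  Positions between landmarks are linearly interpolated, so a
slice position is independent of leg length, slice thickness and
patient position on the table.  Everything superior to the femoral
heads is excluded from analysis.

The canonical positions are fixed constants of the package.  The cohort
mean landmark distances from which they were originally derived are
retained as provenance metadata only and are never used to recompute
them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from sklearn.isotonic import IsotonicRegression

from .volume import Volume3D

__all__ = [
    "CANONICAL_POSITIONS",
    "REFERENCE_DISTANCES_CM",
    "LegModel",
    "LandmarkSet",
    "SlicePositionTarget",
    "LandmarkEvaluation",
    "build_slice_targets",
    "crop_superior_to_femoral_heads",
    "landmarks_from_position_curve",
    "normalize_profile",
    "evaluate_landmarks",
]

#: Canonical relative positions of the four landmark classes.
CANONICAL_POSITIONS: dict[str, float] = {
    "ankle": -1.0,
    "knee": 0.0,
    "symphysis": 1.045,
    "femoral_head": 1.220,
}

#: Cohort mean landmark distances (provenance metadata only).
REFERENCE_DISTANCES_CM: dict[str, float] = {
    "ankle_knee": 95.0,
    "knee_symphysis": 99.1,
    "symphysis_femoral_head": 16.7,
}

LANDMARK_NAMES = ("ankle", "knee", "symphysis", "femoral_head")
SIDES = ("left", "right")

#: Span of the normalized analysis axis.
NORMALIZED_RANGE = (CANONICAL_POSITIONS["ankle"], CANONICAL_POSITIONS["femoral_head"])


@dataclass(frozen=True)
class LegModel:
    """The canonical leg coordinate system (a fixed constant object)."""

    canonical_positions: Mapping[str, float] = field(
        default_factory=lambda: dict(CANONICAL_POSITIONS)
    )
    reference_distances_cm: Mapping[str, float] = field(
        default_factory=lambda: dict(REFERENCE_DISTANCES_CM)
    )

    def __post_init__(self) -> None:
        pos = self.canonical_positions
        vals = [pos[n] for n in LANDMARK_NAMES]
        if not all(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError("canonical positions must be strictly increasing")
        if pos["ankle"] != -1.0 or pos["knee"] != 0.0:
            raise ValueError("leg model must have ankle at -1 and knee at 0")


DEFAULT_LEG_MODEL = LegModel()


@dataclass
class LandmarkSet:
    """Craniocaudal landmark positions, per side where applicable.

    ``ankle_z``, ``knee_z`` and ``femoral_head_z`` map side -> z in mm
    (RAS, superior positive); the symphysis is a single midline value.
    A ``None`` entry means the landmark was not detected.  Optional
    in-plane coordinates are keyed ``(name, side)`` (side ``""`` for
    the symphysis).
    """

    ankle_z: dict[str, float | None]
    knee_z: dict[str, float | None]
    femoral_head_z: dict[str, float | None]
    symphysis_z: float | None
    xy_mm: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    provenance: str = "manual"

    def z(self, name: str, side: str = "") -> float | None:
        if name == "symphysis":
            return self.symphysis_z
        return getattr(self, f"{name}_z").get(side)

    def side_anchors(self, side: str) -> dict[str, float | None]:
        """Landmark z per class for one side (symphysis is shared)."""
        return {
            "ankle": self.ankle_z.get(side),
            "knee": self.knee_z.get(side),
            "symphysis": self.symphysis_z,
            "femoral_head": self.femoral_head_z.get(side),
        }

    def has_side(self, side: str) -> bool:
        return all(v is not None for v in self.side_anchors(side).values())

    def validate(self) -> None:
        for side in SIDES:
            a = self.side_anchors(side)
            if not all(v is not None for v in a.values()):
                continue
            if not (a["ankle"] < a["knee"] < a["femoral_head"]):
                raise ValueError(f"landmark ordering violated on {side} side: {a}")
            if not (a["knee"] < a["symphysis"] < a["femoral_head"]):
                raise ValueError(
                    f"symphysis z {a['symphysis']} not between knee and femoral head "
                    f"on {side} side"
                )

    @property
    def max_femoral_head_z(self) -> float:
        zs = [z for z in self.femoral_head_z.values() if z is not None]
        if not zs:
            raise ValueError("no femoral head landmark available")
        return max(zs)

    @property
    def min_ankle_z(self) -> float:
        zs = [z for z in self.ankle_z.values() if z is not None]
        if not zs:
            raise ValueError("no ankle landmark available")
        return min(zs)

    def to_json(self, path=None) -> str:
        payload = {
            "units": "mm",
            "frame": "RAS, z superior-positive",
            "provenance": self.provenance,
            "ankle_z": self.ankle_z,
            "knee_z": self.knee_z,
            "femoral_head_z": self.femoral_head_z,
            "symphysis_z": self.symphysis_z,
            "xy_mm": {f"{n}|{s}": list(v) for (n, s), v in self.xy_mm.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LandmarkSet":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        xy = {
            tuple(k.split("|")): tuple(v) for k, v in payload.get("xy_mm", {}).items()
        }
        return cls(
            ankle_z=dict(payload["ankle_z"]),
            knee_z=dict(payload["knee_z"]),
            femoral_head_z=dict(payload["femoral_head_z"]),
            symphysis_z=payload["symphysis_z"],
            xy_mm=xy,  # type: ignore[arg-type]
            provenance=payload.get("provenance", "manual"),
        )


@dataclass
class SlicePositionTarget:
    """Per-axial-slice relative leg-model positions for both legs."""

    slice_zs: np.ndarray          # (n,) z in mm, ascending
    positions: np.ndarray         # (n, 2) columns (left, right) in leg-model units

    def side_positions(self, side: str) -> np.ndarray:
        return self.positions[:, SIDES.index(side)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slice_index": np.arange(len(self.slice_zs)),
                "z_mm": self.slice_zs,
                "pos_left": self.positions[:, 0],
                "pos_right": self.positions[:, 1],
            }
        )


@dataclass
class LandmarkEvaluation:
    """Absolute craniocaudal deviations between two landmark sets."""

    table: pd.DataFrame           # columns: landmark, side, dz_mm (NaN = missing)
    mean_dz_mm: float
    sd_dz_mm: float
    fraction_within: float
    threshold_mm: float
    n_missing: int


def _side_position_of_z(anchors: dict[str, float], zs: np.ndarray) -> np.ndarray:
    """Piecewise-linear slice position through the four landmark anchors.

    Outside [ankle, femoral head] the nearest segment's slope is
    extended linearly (the regression CNN needs a target for every
    slice; quantification later crops to the canonical range).
    """
    anchor_z = np.array([anchors[n] for n in LANDMARK_NAMES], dtype=float)
    anchor_p = np.array([CANONICAL_POSITIONS[n] for n in LANDMARK_NAMES])
    pos = np.interp(zs, anchor_z, anchor_p)
    lo_slope = (anchor_p[1] - anchor_p[0]) / (anchor_z[1] - anchor_z[0])
    hi_slope = (anchor_p[-1] - anchor_p[-2]) / (anchor_z[-1] - anchor_z[-2])
    below = zs < anchor_z[0]
    above = zs > anchor_z[-1]
    pos[below] = anchor_p[0] + lo_slope * (zs[below] - anchor_z[0])
    pos[above] = anchor_p[-1] + hi_slope * (zs[above] - anchor_z[-1])
    return pos


def build_slice_targets(
    landmarks: LandmarkSet, slice_zs: Iterable[float]
) -> SlicePositionTarget:
    """Assign each axial slice its (left, right) leg-model position."""
    zs = np.asarray(list(slice_zs), dtype=float)
    if np.any(np.diff(zs) < 0):
        raise ValueError("slice_zs must be sorted ascending")
    landmarks.validate()
    cols = []
    for side in SIDES:
        anchors = landmarks.side_anchors(side)
        if any(v is None for v in anchors.values()):
            raise ValueError(f"landmarks incomplete on {side} side")
        cols.append(_side_position_of_z(anchors, zs))  # type: ignore[arg-type]
    return SlicePositionTarget(slice_zs=zs, positions=np.stack(cols, axis=1))


def crop_superior_to_femoral_heads(obj, landmarks: LandmarkSet):
    """Remove axial content superior to the femoral heads.

    Accepts a :class:`~legquant.volume.Volume3D` or a per-slice
    DataFrame with a ``z_mm`` column; returns ``(cropped, (z_lo, z_hi))``
    where the range covers the retained slice centres.
    """
    z_max = landmarks.max_femoral_head_z
    if isinstance(obj, Volume3D):
        zs = obj.slice_zs
        if z_max < zs[0] or z_max > zs[-1] + obj.spacing[2]:
            raise ValueError(
                f"femoral head z {z_max} mm outside volume z-range "
                f"[{zs[0]}, {zs[-1]}] mm"
            )
        keep = zs <= z_max
        cropped = Volume3D(
            obj.data[:, :, keep],
            obj.spacing,
            (obj.origin[0], obj.origin[1], float(zs[keep][0])),
        )
        return cropped, (float(zs[keep][0]), float(zs[keep][-1]))
    if isinstance(obj, pd.DataFrame):
        keep = obj["z_mm"] <= z_max
        out = obj.loc[keep].reset_index(drop=True)
        return out, (float(out["z_mm"].min()), float(out["z_mm"].max()))
    raise TypeError(f"cannot crop object of type {type(obj)!r}")


def _crossings(zs: np.ndarray, curve: np.ndarray, level: float) -> list[float]:
    """Sub-slice z positions where a curve crosses a level (linear interp)."""
    out = []
    d = curve - level
    hits = np.nonzero(d == 0)[0]
    out.extend(float(zs[i]) for i in hits)
    sign_change = np.nonzero(d[:-1] * d[1:] < 0)[0]
    for i in sign_change:
        frac = d[i] / (d[i] - d[i + 1])
        out.append(float(zs[i] + frac * (zs[i + 1] - zs[i])))
    return sorted(out)


def landmarks_from_position_curve(
    targets_predicted: SlicePositionTarget,
    model: LegModel = DEFAULT_LEG_MODEL,
    median_window: int = 5,
) -> LandmarkSet:
    """Recover landmark z positions from per-slice position predictions.

    The per-slice curve is smoothed with a running median, then each
    canonical position is located as the level crossing of the smoothed
    curve (linear interpolation between bracketing slices).  When noise
    produces several crossings, the one closest to the crossing of an
    isotonic (monotone non-decreasing) fit is taken; a canonical value
    never bracketed is reported as not detected rather than fabricated.
    """
    zs = targets_predicted.slice_zs
    result = LandmarkSet(
        ankle_z={}, knee_z={}, femoral_head_z={}, symphysis_z=None,
        provenance="regression",
    )
    sym_estimates = []
    for side in SIDES:
        raw = targets_predicted.side_positions(side)
        curve = median_filter(raw, size=median_window, mode="nearest")
        iso = IsotonicRegression(increasing=True).fit_transform(zs, curve)
        for name in LANDMARK_NAMES:
            level = model.canonical_positions[name]
            xs = _crossings(zs, curve, level)
            if not xs:
                z_hat = None
            elif len(xs) == 1:
                z_hat = xs[0]
            else:
                iso_xs = _crossings(zs, iso, level)
                ref = iso_xs[0] if iso_xs else float(np.mean(xs))
                z_hat = min(xs, key=lambda x: abs(x - ref))
            if name == "symphysis":
                if z_hat is not None:
                    sym_estimates.append(z_hat)
            else:
                getattr(result, f"{name}_z")[side] = z_hat
    result.symphysis_z = float(np.mean(sym_estimates)) if sym_estimates else None
    return result


def normalize_profile(profile, landmarks: LandmarkSet, model: LegModel = DEFAULT_LEG_MODEL,
                      n_grid: int = 256):
    """Resample a per-slice area profile onto the normalized leg axis.

    Areas are interpolated from native slice z onto ``n_grid`` uniform
    points over the canonical range [-1, 1.220] per side.  Sides with
    missing landmarks are omitted and recorded in
    ``profile.meta['normalize_warnings']``.  Volume integrated on the
    normalized axis (area x local mm-per-unit x grid step) matches the
    native-axis volume to within interpolation error.
    """
    from .profiles import TissueProfile  # local import to avoid cycle

    if not isinstance(profile, TissueProfile):
        raise TypeError("normalize_profile expects a TissueProfile")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    lo, hi = NORMALIZED_RANGE
    grid = np.linspace(lo, hi, n_grid)
    rows = []
    warnings = list(profile.meta.get("normalize_warnings", []))
    for side in SIDES:
        anchors = landmarks.side_anchors(side)
        if any(v is None for v in anchors.values()):
            warnings.append(f"landmarks missing for {side} side; omitted")
            continue
        native_side = profile.native[profile.native["leg"] == side]
        if native_side.empty:
            continue
        for tissue, sub in native_side.groupby("tissue"):
            zs = sub["z_mm"].to_numpy(dtype=float)
            area = sub["area_cm2"].to_numpy(dtype=float)
            order = np.argsort(zs)
            pos = _side_position_of_z(anchors, zs[order])  # type: ignore[arg-type]
            resampled = np.interp(grid, pos, area[order])
            # hold the edge value up to one slice beyond the native
            # range (the canonical endpoints usually fall between
            # slice centres), zero further out
            tol = 1.5 * float(np.median(np.diff(pos))) if len(pos) > 1 else 0.0
            resampled[(grid < pos[0] - tol) | (grid > pos[-1] + tol)] = 0.0
            rows.append(
                pd.DataFrame(
                    {
                        "norm_pos": grid,
                        "leg": side,
                        "tissue": tissue,
                        "area_cm2": resampled,
                    }
                )
            )
    normalized = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["norm_pos", "leg", "tissue", "area_cm2"])
    )
    meta = dict(profile.meta)
    meta["normalize_warnings"] = warnings
    meta["n_grid"] = n_grid
    meta["mm_per_unit"] = {
        side: _mm_per_unit(landmarks, side, grid)
        for side in SIDES
        if landmarks.has_side(side)
    }
    out = TissueProfile(
        native=profile.native.copy(),
        normalized=normalized,
        volumes_l=dict(profile.volumes_l),
        spacing_mm=profile.spacing_mm,
        meta=meta,
    )
    return out


def _mm_per_unit(landmarks: LandmarkSet, side: str, grid: np.ndarray) -> np.ndarray:
    """Local dz/dposition (mm per leg-model unit) along the normalized grid."""
    anchors = landmarks.side_anchors(side)
    anchor_p = np.array([CANONICAL_POSITIONS[n] for n in LANDMARK_NAMES])
    anchor_z = np.array([anchors[n] for n in LANDMARK_NAMES], dtype=float)
    seg_slope = np.diff(anchor_z) / np.diff(anchor_p)
    idx = np.clip(np.searchsorted(anchor_p, grid, side="right") - 1, 0, len(seg_slope) - 1)
    return seg_slope[idx]


def normalized_volumes_l(profile) -> dict[tuple[str, str], float]:
    """Integrate the normalized profile back to litres (consistency check)."""
    out: dict[tuple[str, str], float] = {}
    if profile.normalized is None or profile.normalized.empty:
        return out
    mmpu = profile.meta.get("mm_per_unit", {})
    for (side, tissue), sub in profile.normalized.groupby(["leg", "tissue"]):
        if side not in mmpu:
            continue
        grid = sub["norm_pos"].to_numpy(dtype=float)
        area = sub["area_cm2"].to_numpy(dtype=float)
        dz_mm = mmpu[side] * np.gradient(grid)
        out[(side, tissue)] = float(np.sum(area * dz_mm / 10.0) / 1000.0)
    return out


def evaluate_landmarks(
    predicted: LandmarkSet, truth: LandmarkSet, threshold_mm: float = 10.0
) -> LandmarkEvaluation:
    """Per-landmark |dz| between predicted and reference positions.

    Missing predictions are counted separately and excluded from the
    mean; the fraction-within statistic is computed over the detected
    landmarks only.
    """
    records = []
    for name in LANDMARK_NAMES:
        sides = ("",) if name == "symphysis" else SIDES
        for side in sides:
            t = truth.z(name, side)
            if t is None:
                continue
            p = predicted.z(name, side)
            dz = abs(p - t) if p is not None else np.nan
            records.append({"landmark": name, "side": side, "dz_mm": dz})
    table = pd.DataFrame(records)
    dz = table["dz_mm"].to_numpy(dtype=float)
    ok = ~np.isnan(dz)
    n_missing = int(np.sum(~ok))
    if ok.any():
        mean = float(np.mean(dz[ok]))
        sd = float(np.std(dz[ok]))
        frac = float(np.mean(dz[ok] < threshold_mm))
    else:
        mean = sd = float("nan")
        frac = 0.0
    return LandmarkEvaluation(
        table=table,
        mean_dz_mm=mean,
        sd_dz_mm=sd,
        fraction_within=frac,
        threshold_mm=float(threshold_mm),
        n_missing=n_missing,
    )
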