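"""Synthetic DIXON-water-like lower-extremity phantoms.

Each phantom is a two-legged water-image volume with known geometry:
per leg, a bright subfascial core (muscle/bone, SFT) of radius
``r(z)`` surrounded by a dark subcutaneous fat annulus (SCT) of
thickness ``t(z)``, both defined as piecewise-linear profiles along
the *canonical leg axis* so that phantoms of different leg lengths
share the same anatomy.  Above the symphysis the two legs are joined
by a midline subfascial bridge slab (a minimal pelvis stand-in) so the
foreground becomes a single merged body, as it does in real scans.

Because the geometry is analytic, every phantom carries closed-form
per-leg tissue volumes (piecewise-quadratic area profiles integrated
exactly with per-segment Simpson quadrature), exact landmark
positions, and exact voxel label maps — ground truth for every stage
of the pipeline, with no data download.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .leg_model import CANONICAL_POSITIONS, LandmarkSet, _side_position_of_z
from .volume import Volume3D, resample_volume, save_nifti

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "ArtifactSpec",
    "generate_phantom",
    "inject_artifact",
    "resample_phantom",
    "desk_spec",
    "sample_desk_cohort",
    "write_phantom",
]

LABELS = {"background": 0, "SCT": 1, "SFT": 2}
TISSUES = ("SCT", "SFT")
SIDES = ("left", "right")


def _per_side(value) -> dict[str, float]:
    if isinstance(value, dict):
        return {s: float(value[s]) for s in SIDES}
    return {s: float(value) for s in SIDES}


@dataclass
class ArtifactSpec:
    """A localized image corruption within an axial slab.

    ``water_fat_swap`` exchanges the SCT and SFT intensity statistics
    inside the slab (the label truth is untouched — the corruption
    degrades the image, not the reference); ``partial_volume_blur``
    applies an isotropic Gaussian blur of ``sigma_mm`` inside the slab.
    """

    kind: str  # "water_fat_swap" | "partial_volume_blur"
    z_lo_mm: float
    z_hi_mm: float
    sigma_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("water_fat_swap", "partial_volume_blur"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")


@dataclass
class PhantomSpec:
    """Full geometric and intensity description of one phantom.

    Radius/thickness knots are ``(canonical position, mm)`` pairs on
    the leg-model axis; in-plane sizes are in mm.  ``asymmetry_factor``
    multiplies the left leg's subcutaneous thickness.
    """

    grid_shape: tuple[int, int, int] = (320, 160, 384)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.5)
    leg_center_offset_mm: float = 80.0
    ankle_z_mm: dict[str, float] | float = 10.0
    knee_z_mm: dict[str, float] | float = 410.0
    symphysis_z_mm: float = 828.0
    femoral_head_z_mm: dict[str, float] | float = 898.0
    sft_radius_knots: tuple = ((-1.0, 25.0), (0.0, 40.0), (1.045, 52.0), (1.5, 52.0))
    sct_thickness_knots: tuple = ((-1.0, 8.0), (0.0, 12.0), (1.045, 18.0), (1.5, 18.0))
    asymmetry_factor: float = 1.0
    bridge_height_fraction: float = 0.6
    bridge_ramp_mm: float = 30.0  # pelvis width grows smoothly above the symphysis
    intensity_means: dict[str, float] = field(
        default_factory=lambda: {"background": 0.0, "SCT": 0.2, "SFT": 1.0}
    )
    noise_sd: float = 0.05
    bias_field_amplitude: float = 0.1
    joint_features: bool = True
    artifact_spec: ArtifactSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.ankle_z_mm = _per_side(self.ankle_z_mm)
        self.knee_z_mm = _per_side(self.knee_z_mm)
        self.femoral_head_z_mm = _per_side(self.femoral_head_z_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        for side in SIDES:
            a, k, f = (self.ankle_z_mm[side], self.knee_z_mm[side],
                       self.femoral_head_z_mm[side])
            s = self.symphysis_z_mm
            if not (a < k < s < f):
                raise ValueError(
                    f"landmark ordering violated on {side}: "
                    f"ankle {a} < knee {k} < symphysis {s} < femoral head {f} required"
                )
        if any(r <= 0 for _, r in self.sft_radius_knots):
            raise ValueError("sft_radius must be positive")
        if any(t < 0 for _, t in self.sct_thickness_knots):
            raise ValueError("sct_thickness must be non-negative")

    # -- geometry helpers ------------------------------------------------
    def landmarks(self) -> LandmarkSet:
        xy = {}
        for side, sgn in (("left", -1.0), ("right", 1.0)):
            for name in ("ankle", "knee", "femoral_head"):
                xy[(name, side)] = (sgn * self.leg_center_offset_mm, 0.0)
        xy[("symphysis", "")] = (0.0, 0.0)
        return LandmarkSet(
            ankle_z=dict(self.ankle_z_mm),
            knee_z=dict(self.knee_z_mm),
            femoral_head_z=dict(self.femoral_head_z_mm),
            symphysis_z=float(self.symphysis_z_mm),
            xy_mm=xy,
            provenance="manual",
        )

    def _anchors(self, side: str) -> dict[str, float]:
        return {
            "ankle": self.ankle_z_mm[side],
            "knee": self.knee_z_mm[side],
            "symphysis": self.symphysis_z_mm,
            "femoral_head": self.femoral_head_z_mm[side],
        }

    def position_of_z(self, z, side: str) -> np.ndarray:
        return _side_position_of_z(self._anchors(side), np.atleast_1d(np.asarray(z, float)))

    def z_of_position(self, pos: float, side: str) -> float:
        """Inverse of the piecewise-linear slice-position mapping."""
        a = self._anchors(side)
        names = ("ankle", "knee", "symphysis", "femoral_head")
        ps = np.array([CANONICAL_POSITIONS[n] for n in names])
        zsv = np.array([a[n] for n in names])
        if pos <= ps[0]:
            slope = (zsv[1] - zsv[0]) / (ps[1] - ps[0])
            return float(zsv[0] + slope * (pos - ps[0]))
        if pos >= ps[-1]:
            slope = (zsv[-1] - zsv[-2]) / (ps[-1] - ps[-2])
            return float(zsv[-1] + slope * (pos - ps[-1]))
        return float(np.interp(pos, ps, zsv))

    def sft_radius_mm(self, z, side: str) -> np.ndarray:
        pos = self.position_of_z(z, side)
        kp, kv = zip(*self.sft_radius_knots)
        return np.interp(pos, kp, kv)

    def sct_thickness_mm(self, z, side: str) -> np.ndarray:
        pos = self.position_of_z(z, side)
        kp, kv = zip(*self.sct_thickness_knots)
        t = np.interp(pos, kp, kv)
        if side == "left":
            t = t * self.asymmetry_factor
        return t

    def outer_radius_mm(self, z, side: str) -> np.ndarray:
        return self.sft_radius_mm(z, side) + self.sct_thickness_mm(z, side)

    def spec_hash(self) -> str:
        def default(o):
            if isinstance(o, ArtifactSpec):
                return o.__dict__
            return str(o)

        blob = json.dumps(self.__dict__, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PhantomTruth:
    """A generated phantom with its exact ground truth."""

    volume: Volume3D
    labels: Volume3D
    landmarks: LandmarkSet
    analytic_volumes_l: dict[tuple[str, str], float]
    spec: PhantomSpec
    corrupted_slabs: list = field(default_factory=list)


# -- closed-form volumes -------------------------------------------------

def _segment_breakpoints(spec: PhantomSpec, side: str, lo: float, hi: float) -> np.ndarray:
    """z values where the per-slice area stops being a single quadratic."""
    pts = {lo, hi, spec.symphysis_z_mm, spec.symphysis_z_mm + spec.bridge_ramp_mm}
    pts.update(spec._anchors(side).values())
    for knots in (spec.sft_radius_knots, spec.sct_thickness_knots):
        for p, _ in knots:
            pts.add(spec.z_of_position(p, side))
    arr = np.array(sorted(p for p in pts if lo - 1e-9 <= p <= hi + 1e-9))
    return np.clip(arr, lo, hi)


def _integrate_quadratic(f, breakpoints: np.ndarray) -> float:
    """Exact integral of a piecewise-quadratic via per-segment Simpson."""
    total = 0.0
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        if b <= a:
            continue
        m = 0.5 * (a + b)
        total += (b - a) / 6.0 * (f(a) + 4.0 * f(m) + f(b))
    return total


def _bridge_height_mm(spec: PhantomSpec, z: float) -> float:
    """Half-height of the bridge slab, ramping in above the symphysis."""
    if z < spec.symphysis_z_mm:
        return 0.0
    ramp = 1.0
    if spec.bridge_ramp_mm > 0:
        ramp = min(1.0, (z - spec.symphysis_z_mm) / spec.bridge_ramp_mm)
    return ramp * spec.bridge_height_fraction * min(
        float(spec.sft_radius_mm(z, "left")[0]), float(spec.sft_radius_mm(z, "right")[0])
    )


def _bridge_half_area_mm2(spec: PhantomSpec, z: float) -> float:
    """Half (one side's share) of the torso bridge cross-section at z."""
    h = _bridge_height_mm(spec, z)
    if h <= 0:
        return 0.0
    out_l = float(spec.outer_radius_mm(z, "left")[0])
    out_r = float(spec.outer_radius_mm(z, "right")[0])
    width = 2.0 * spec.leg_center_offset_mm - out_l - out_r
    if width <= 0:
        return 0.0
    return 0.5 * width * 2.0 * h


def analytic_volumes(spec: PhantomSpec) -> dict[tuple[str, str], float]:
    """Closed-form per-(leg, tissue) volumes in litres.

    Integration runs from each side's ankle to the superior crop plane
    (the higher femoral head), matching the analysis range used by the
    quantification stage.
    """
    z_top = max(spec.femoral_head_z_mm.values())
    out: dict[tuple[str, str], float] = {}
    for side in SIDES:
        lo = spec.ankle_z_mm[side]
        bps = _segment_breakpoints(spec, side, lo, z_top)

        def sct_area(z, side=side):
            r = float(spec.sft_radius_mm(z, side)[0])
            t = float(spec.sct_thickness_mm(z, side)[0])
            return np.pi * ((r + t) ** 2 - r**2)

        def sft_area(z, side=side):
            r = float(spec.sft_radius_mm(z, side)[0])
            return np.pi * r**2 + _bridge_half_area_mm2(spec, z)

        out[(side, "SCT")] = _integrate_quadratic(sct_area, bps) / 1e6
        out[(side, "SFT")] = _integrate_quadratic(sft_area, bps) / 1e6
    return out


def analytic_slice_areas(spec: PhantomSpec, z: float, side: str) -> dict[str, float]:
    """Exact cross-sectional areas (mm^2) of one leg at height z."""
    if z < spec.ankle_z_mm[side]:
        return {"SCT": 0.0, "SFT": 0.0}
    r = float(spec.sft_radius_mm(z, side)[0])
    t = float(spec.sct_thickness_mm(z, side)[0])
    return {
        "SCT": np.pi * ((r + t) ** 2 - r**2),
        "SFT": np.pi * r**2 + _bridge_half_area_mm2(spec, z),
    }


# -- voxelization --------------------------------------------------------

def _grid_coords(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.spacing_mm
    xs = (np.arange(nx) - (nx - 1) / 2.0) * dx
    ys = (np.arange(ny) - (ny - 1) / 2.0) * dy
    zs = np.arange(nz) * dz
    return xs, ys, zs


def _check_grid_fits(spec: PhantomSpec) -> None:
    xs, ys, zs = _grid_coords(spec)
    z_probe = np.linspace(zs[0], zs[-1], 257)
    max_outer = max(
        float(np.max(spec.outer_radius_mm(z_probe, side))) for side in SIDES
    )
    need_x = spec.leg_center_offset_mm + max_outer
    if need_x > xs[-1]:
        raise ValueError(
            f"grid too small along x: need half-extent {need_x:.1f} mm, "
            f"have {xs[-1]:.1f} mm"
        )
    if max_outer > ys[-1]:
        raise ValueError(
            f"grid too small along y: need half-extent {max_outer:.1f} mm, "
            f"have {ys[-1]:.1f} mm"
        )
    if max(spec.femoral_head_z_mm.values()) > zs[-1]:
        raise ValueError(
            f"grid too small along z: femoral head at "
            f"{max(spec.femoral_head_z_mm.values()):.1f} mm, grid ends at {zs[-1]:.1f} mm"
        )


def _label_volume(spec: PhantomSpec) -> np.ndarray:
    xs, ys, zs = _grid_coords(spec)
    nx, ny, nz = spec.grid_shape
    labels = np.zeros((nx, ny, nz), dtype=np.int8)
    X = xs[:, None]
    Y = ys[None, :]
    for k, z in enumerate(zs):
        sl = labels[:, :, k]
        for side, sgn in (("left", -1.0), ("right", 1.0)):
            if z < spec.ankle_z_mm[side]:
                continue
            r = float(spec.sft_radius_mm(z, side)[0])
            t = float(spec.sct_thickness_mm(z, side)[0])
            d2 = (X - sgn * spec.leg_center_offset_mm) ** 2 + Y**2
            sl[d2 < (r + t) ** 2] = LABELS["SCT"]
            sl[d2 < r**2] = LABELS["SFT"]
        h = _bridge_height_mm(spec, z)
        if h > 0:
            out_l = float(spec.outer_radius_mm(z, "left")[0])
            out_r = float(spec.outer_radius_mm(z, "right")[0])
            in_bridge = (
                (X > -spec.leg_center_offset_mm + out_l)
                & (X < spec.leg_center_offset_mm - out_r)
                & (np.abs(Y) < h)
            )
            sl[in_bridge & (sl == 0)] = LABELS["SFT"]
    return labels


def _apply_joint_features(spec: PhantomSpec, labels: np.ndarray, img: np.ndarray) -> None:
    """Intensity-only joint structures inside the subfascial core.

    Emulates the anatomy the landmark CNNs key on in real scans: a dark
    knee joint, a bright femoral-head ball per side, and a bright
    symphysis node on the midline.  Labels and closed-form volumes are
    untouched — only voxels already labelled SFT are modulated.
    """
    xs, ys, zs = _grid_coords(spec)
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    sft = labels == LABELS["SFT"]

    def modulate(cx, cy, cz, radius, factor):
        d2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
        ball = (d2 < radius**2) & sft
        img[ball] *= factor

    for side, sgn in (("left", -1.0), ("right", 1.0)):
        cx = sgn * spec.leg_center_offset_mm
        knee_z = spec.knee_z_mm[side]
        r_knee = 0.5 * float(spec.sft_radius_mm(knee_z, side)[0])
        modulate(cx, 0.0, knee_z, r_knee, 0.4)
        fh_z = spec.femoral_head_z_mm[side]
        r_fh = 0.4 * float(spec.sft_radius_mm(fh_z, side)[0])
        modulate(cx, 0.0, fh_z, r_fh, 1.6)
    # midline node sits where the ramped bridge is thick enough to hold it
    modulate(0.0, 0.0, spec.symphysis_z_mm + 18.0, 12.0, 1.6)


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Low-order in-plane multiplicative field, |deviation| <= amplitude."""
    nx, ny, _ = spec.grid_shape
    if spec.bias_field_amplitude == 0:
        return np.ones((nx, ny), dtype=np.float32)
    xh = np.linspace(-1, 1, nx)[:, None]
    yh = np.linspace(-1, 1, ny)[None, :]
    basis = [xh + 0 * yh, yh + 0 * xh, xh * yh, xh**2 - 1 / 3, yh**2 - 1 / 3]
    coef = rng.normal(size=len(basis))
    p = sum(c * b for c, b in zip(coef, basis))
    p = p / max(np.max(np.abs(p)), 1e-12)
    return (1.0 + spec.bias_field_amplitude * p).astype(np.float32)


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Voxelize a phantom: exact labels, simulated water image, truth.

    Deterministic given ``spec.seed``; the intensity image is
    per-tissue mean x in-plane bias field + additive Gaussian noise,
    clipped at zero (MRI magnitude images are non-negative).
    """
    _check_grid_fits(spec)
    rng = np.random.default_rng(spec.seed)
    labels = _label_volume(spec)
    means = np.array(
        [spec.intensity_means["background"], spec.intensity_means["SCT"],
         spec.intensity_means["SFT"]],
        dtype=np.float32,
    )
    img = means[labels]
    if spec.joint_features:
        _apply_joint_features(spec, labels, img)
    img *= _bias_field(spec, rng)[:, :, None]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
    np.clip(img, 0.0, None, out=img)
    xs, ys, zs = _grid_coords(spec)
    origin = (float(xs[0]), float(ys[0]), float(zs[0]))
    truth = PhantomTruth(
        volume=Volume3D(img.astype(np.float32), spec.spacing_mm, origin),
        labels=Volume3D(labels, spec.spacing_mm, origin),
        landmarks=spec.landmarks(),
        analytic_volumes_l=analytic_volumes(spec),
        spec=spec,
    )
    if spec.artifact_spec is not None:
        truth = inject_artifact(truth, spec.artifact_spec)
    return truth


def inject_artifact(truth: PhantomTruth, artifact: ArtifactSpec) -> PhantomTruth:
    """Corrupt the image (not the labels) inside an axial slab."""
    zs = truth.volume.slice_zs
    if artifact.z_hi_mm <= artifact.z_lo_mm:
        return replace(truth, volume=truth.volume.with_data(truth.volume.data.copy()))
    if artifact.z_hi_mm < zs[0] or artifact.z_lo_mm > zs[-1]:
        raise ValueError(
            f"artifact slab [{artifact.z_lo_mm}, {artifact.z_hi_mm}] mm outside "
            f"grid z-range [{zs[0]}, {zs[-1]}] mm"
        )
    in_slab = (zs >= artifact.z_lo_mm) & (zs <= artifact.z_hi_mm)
    img = truth.volume.data.astype(np.float32).copy()
    if artifact.kind == "water_fat_swap":
        slab = img[:, :, in_slab]
        lab = truth.labels.data[:, :, in_slab]
        sct = lab == LABELS["SCT"]
        sft = lab == LABELS["SFT"]
        if sct.any() and sft.any():
            m_sct = float(slab[sct].mean())
            m_sft = float(slab[sft].mean())
            slab[sct] += m_sft - m_sct
            slab[sft] += m_sct - m_sft
            img[:, :, in_slab] = slab
    else:  # partial_volume_blur
        if artifact.sigma_mm > 0:
            sigma_vox = [artifact.sigma_mm / s for s in truth.volume.spacing]
            lo, hi = np.nonzero(in_slab)[0][[0, -1]]
            # blur with context so the slab edges are physical, then paste
            pad = int(np.ceil(4 * sigma_vox[2]))
            a, b = max(0, lo - pad), min(img.shape[2], hi + 1 + pad)
            blurred = ndimage.gaussian_filter(img[:, :, a:b], sigma=sigma_vox)
            img[:, :, lo : hi + 1] = blurred[:, :, lo - a : hi + 1 - a]
    np.clip(img, 0.0, None, out=img)
    slab_rec = {
        "kind": artifact.kind,
        "z_lo_mm": float(artifact.z_lo_mm),
        "z_hi_mm": float(artifact.z_hi_mm),
        "sigma_mm": float(artifact.sigma_mm),
    }
    return PhantomTruth(
        volume=truth.volume.with_data(img),
        labels=truth.labels,
        landmarks=truth.landmarks,
        analytic_volumes_l=dict(truth.analytic_volumes_l),
        spec=truth.spec,
        corrupted_slabs=truth.corrupted_slabs + [slab_rec],
    )


def resample_phantom(truth: PhantomTruth, new_spacing_mm) -> PhantomTruth:
    """Resample image (trilinear) and labels (nearest) to a new spacing.

    Analytic volumes and landmark mm coordinates are spacing-independent
    and carried over unchanged.
    """
    new_spacing = tuple(float(s) for s in new_spacing_mm)
    if any(s <= 0 for s in new_spacing):
        raise ValueError("new spacing must be positive")
    old = truth.volume
    if new_spacing == old.spacing:
        return copy.deepcopy(truth)
    return PhantomTruth(
        volume=resample_volume(old, new_spacing, order=1),
        labels=resample_volume(truth.labels, new_spacing, order=0),
        landmarks=truth.landmarks,
        analytic_volumes_l=dict(truth.analytic_volumes_l),
        spec=truth.spec,
        corrupted_slabs=list(truth.corrupted_slabs),
    )


# -- cohort factories ----------------------------------------------------

def desk_spec(
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (64, 64, 136),
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 7.5),
    **overrides,
) -> PhantomSpec:
    """A small-matrix phantom for CPU-scale training experiments.

    Same anatomy as the full-resolution default, sampled on a 64x64
    in-plane matrix (5 mm pixels, 7.5 mm slices); all other parameters
    as in :class:`PhantomSpec`.
    """
    return PhantomSpec(grid_shape=grid_shape, spacing_mm=spacing_mm, seed=seed,
                       **overrides)


def sample_desk_cohort(
    n: int,
    seed: int = 0,
    asymmetric_fraction: float = 0.3,
    artifact_fraction: float = 0.0,
    noise_sd: float = 0.05,
    bias_field_amplitude: float = 0.1,
) -> list[PhantomSpec]:
    """Randomized desk-scale cohort with varied anatomy.

    Per phantom: leg length scaled U(0.9, 1.1), subfascial radii scaled
    U(0.85, 1.15), subcutaneous thickness scaled U(0.8, 1.3), small
    independent per-side landmark jitter, and optionally an asymmetric
    left leg or an injected artifact slab.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        length = rng.uniform(0.88, 1.06)
        r_scale = rng.uniform(0.85, 1.15)
        t_scale = rng.uniform(0.8, 1.3)
        jit = {s: rng.uniform(-5.0, 5.0) for s in SIDES}
        ankle = {s: 10.0 + rng.uniform(0.0, 10.0) for s in SIDES}
        knee = {s: ankle[s] + 400.0 * length + jit[s] for s in SIDES}
        mean_knee = float(np.mean(list(knee.values())))
        symphysis = mean_knee + 418.0 * length
        fh = {s: symphysis + 70.0 * length + rng.uniform(-4.0, 4.0) for s in SIDES}
        asym = 1.0
        if rng.uniform() < asymmetric_fraction:
            asym = rng.uniform(1.15, 1.6)
        # keep the legs geometrically separate below the symphysis:
        # cap the outer radius at (leg offset - 6 mm) by shrinking the
        # subcutaneous thickness scale when the draw is too large
        offset = 80.0
        r_max = max(r for _, r in PhantomSpec.sft_radius_knots) * r_scale
        t_max = max(t for _, t in PhantomSpec.sct_thickness_knots) * t_scale * asym
        budget = offset - 6.0 - r_max
        if t_max > budget:
            t_scale *= budget / t_max
        artifact = None
        if rng.uniform() < artifact_fraction:
            kind = "water_fat_swap" if rng.uniform() < 0.5 else "partial_volume_blur"
            z_lo = rng.uniform(ankle["left"] + 60.0, symphysis - 160.0)
            artifact = ArtifactSpec(
                kind=kind,
                z_lo_mm=z_lo,
                z_hi_mm=z_lo + rng.uniform(60.0, 120.0),
                sigma_mm=rng.uniform(6.0, 12.0),
            )
        specs.append(
            desk_spec(
                seed=int(rng.integers(0, 2**31 - 1)),
                leg_center_offset_mm=80.0,
                ankle_z_mm=ankle,
                knee_z_mm=knee,
                symphysis_z_mm=symphysis,
                femoral_head_z_mm=fh,
                sft_radius_knots=tuple(
                    (p, r * r_scale) for p, r in PhantomSpec.sft_radius_knots
                ),
                sct_thickness_knots=tuple(
                    (p, t * t_scale) for p, t in PhantomSpec.sct_thickness_knots
                ),
                asymmetry_factor=asym,
                noise_sd=noise_sd,
                bias_field_amplitude=bias_field_amplitude,
                artifact_spec=artifact,
            )
        )
    return specs


def write_phantom(truth: PhantomTruth, out_dir, stem: str = "phantom") -> dict:
    """Write a phantom to disk (NIfTI volumes, JSON truth) and return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out / f"{stem}_water.nii.gz",
        "labels": out / f"{stem}_labels.nii.gz",
        "landmarks": out / f"{stem}_landmarks.json",
        "truth": out / f"{stem}_truth.json",
    }
    save_nifti(truth.volume, paths["volume"])
    save_nifti(truth.labels, paths["labels"])
    truth.landmarks.to_json(paths["landmarks"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "analytic_volumes_l": {
                    f"{leg}|{tissue}": v
                    for (leg, tissue), v in truth.analytic_volumes_l.items()
                },
                "corrupted_slabs": truth.corrupted_slabs,
                "seed": truth.spec.seed,
                "spec_hash": truth.spec.spec_hash(),
            },
            fh,
            indent=2,
        )
    return {k: str(v) for k, v in paths.items()}
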