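"""CNN-based landmark detection.

Two complementary detectors localize the ankles, knees, femoral heads
and symphysis:

1. *Slice-position regression*: a 2.5D encoder predicts, for every
   axial slice, the slice's relative (left, right) position in the
   canonical leg model; landmark heights are recovered as the level
   crossings of the resulting position curve.
2. *Keypoint detection*: a 2.5D encoder-decoder predicts one Gaussian
   heatmap per landmark on a coronal reconstruction of the body
   (2.5 mm isotropic, each axial slice recentred in the
   anterior-posterior direction, cropped to a 50 mm AP slab).

Both are trained with patient-level k-fold cross-validation and
applied as ensembles; their landmark estimates are fused by an
inverse-variance weighted mean (plain averaging when no reliability
weights are available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from . import nn
from .leg_model import (
    SIDES,
    LandmarkSet,
    SlicePositionTarget,
    landmarks_from_position_curve,
)
from .volume import Volume3D, resample_volume

__all__ = [
    "TrainConfig",
    "EnsembleModel",
    "CoronalRecon",
    "compute_body_mask",
    "make_slice_stacks",
    "build_coronal_recon",
    "heatmap_targets",
    "decode_heatmap",
    "train_position_regressor",
    "train_keypoint_detector",
    "predict_positions",
    "predict_keypoints",
    "fuse_landmarks",
    "with_coord_channels",
    "KEYPOINT_CLASSES",
]

#: landmark instances recovered by the keypoint detector
KEYPOINT_CLASSES: tuple = (
    ("ankle", "left"), ("ankle", "right"),
    ("knee", "left"), ("knee", "right"),
    ("femoral_head", "left"), ("femoral_head", "right"),
    ("symphysis", ""),
)

#: heatmap channel order: side-agnostic classes.  Each anatomical class
#: is locally distinctive, so detection is translation-equivariant
#: template matching; the left/right instance is resolved afterwards
#: from the peak's x position.  This is far more sample-efficient than
#: separate per-side channels, which would force the network to encode
#: absolute position.
HEATMAP_CLASSES: tuple = ("ankle", "knee", "femoral_head", "symphysis")

CORONAL_SPACING_MM = 2.5
AP_SLAB_HALF_MM = 25.0
CHANNEL_GAP_MM = 5.0


@dataclass
class TrainConfig:
    """Hyperparameters for the desk-scale CNN training runs."""

    n_folds: int = 5
    epochs: int = 6            # position regressor
    kp_epochs: int = 8         # keypoint detector
    seg_epochs: int = 9        # tissue segmentation
    batch_size: int = 16
    reg_batch_size: int = 16
    kp_batch_size: int = 8
    lr: float = 3e-3
    base_channels: int = 8
    seed: int = 0
    heatmap_sigma_vox: float = 2.0
    kp_crops_per_image: int = 8
    kp_crop_rows: int = 144


@dataclass
class EnsembleModel:
    """Cross-validated fold models applied with mean aggregation."""

    members: list
    kind: str  # "regressor" | "keypoint" | "segmenter"
    fold_metrics: pd.DataFrame | None = None
    config: TrainConfig | None = None
    norm: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    def predict(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Mean of member outputs, computed in mini-batches."""
        outs = None
        for m in self.members:
            m.set_train(False)
            pieces = [
                m.forward(np.ascontiguousarray(x[i : i + batch_size], dtype=np.float32))
                for i in range(0, len(x), batch_size)
            ]
            o = np.concatenate(pieces, axis=0)
            outs = o if outs is None else outs + o
        return outs / len(self.members)


# -- body mask -----------------------------------------------------------

def compute_body_mask(volume: Volume3D) -> Volume3D:
    """Foreground body mask: thresholding + closing + hole filling.

    The volume is despeckled with a 3-voxel median filter (edge
    preserving, so thin fat rims survive), thresholded at the lowest
    multi-Otsu boundary (3 classes, so the dark subcutaneous fat stays
    inside the mask even though the water image is strongly bimodal
    within tissue), then closed and hole-filled; components below 1%
    of the foreground are dropped.  Deterministic.
    """
    data = volume.data
    if np.min(data) < 0:
        raise ValueError("body mask expects non-negative intensities")
    if not np.any(data > 0):
        raise ValueError("volume is empty; cannot compute body mask")
    smooth = ndimage.median_filter(data.astype(np.float32), size=3)
    try:
        thr = float(threshold_multiotsu(smooth, classes=3)[0])
    except ValueError:  # fewer than 3 grey levels
        thr = float(threshold_otsu(smooth))
    mask = smooth > thr
    struct = _ball(2)
    mask = ndimage.binary_closing(mask, structure=struct)
    mask = ndimage.binary_fill_holes(mask)
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("body mask is empty after thresholding")
    counts = np.bincount(lab.ravel())[1:]
    keep = np.nonzero(counts >= 0.01 * counts.sum())[0] + 1
    mask = np.isin(lab, keep)
    return volume.with_data(mask)


def _ball(radius: int) -> np.ndarray:
    r = radius
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= r**2


# -- 2.5D axial stacks ---------------------------------------------------

def make_slice_stacks(
    volume: Volume3D, body_mask: Volume3D | None = None
) -> tuple[np.ndarray, dict]:
    """One 3-channel stack per axial slice (z-5 mm, z, z+5 mm).

    The neighbour offset is 5 mm rounded to the nearest slice index
    (at least one slice); out-of-volume neighbours are edge-replicated.
    Intensities are z-normalized with body-mask statistics.  Returns
    ``(stacks, record)`` with stacks shaped (n_slices, 3, nx, ny).
    """
    if body_mask is None:
        body_mask = compute_body_mask(volume)
    dz = volume.spacing[2]
    offset = max(1, int(round(CHANNEL_GAP_MM / dz)))
    fg = volume.data[body_mask.data > 0]
    mean = float(fg.mean()) if fg.size else 0.0
    sd = float(fg.std()) if fg.size else 1.0
    sd = max(sd, 1e-6)
    data = ((volume.data.astype(np.float32) - mean) / sd).transpose(2, 0, 1)
    nz = data.shape[0]
    lo = np.clip(np.arange(nz) - offset, 0, nz - 1)
    hi = np.clip(np.arange(nz) + offset, 0, nz - 1)
    stacks = np.stack([data[lo], data, data[hi]], axis=1)
    record = {
        "mean": mean, "sd": sd, "offset_slices": offset, "dz_mm": dz,
        "single_slice": nz == 1,
    }
    return np.ascontiguousarray(stacks), record


# -- coronal reconstruction ----------------------------------------------

@dataclass
class CoronalRecon:
    """AP-straightened coronal reconstruction at 2.5 mm isotropic.

    ``channels`` are three coronal planes 5 mm apart centred in the
    50 mm AP slab, image axes (row = z index, col = x index), padded to
    a multiple of 4.  The per-axial-slice AP shifts and grid origins
    are retained so image coordinates map back to scanner mm.
    """

    channels: np.ndarray  # (3, H, W) float32, normalized
    x0_mm: float
    z0_mm: float
    spacing_mm: float
    shifts_vox: np.ndarray
    valid_shape: tuple[int, int]  # (n_z, n_x) before padding
    norm: dict
    warnings: list = field(default_factory=list)

    def to_image(self, x_mm: float, z_mm: float) -> tuple[float, float]:
        """(x, z) in mm -> fractional (row, col)."""
        return (
            (z_mm - self.z0_mm) / self.spacing_mm,
            (x_mm - self.x0_mm) / self.spacing_mm,
        )

    def from_image(self, row: float, col: float) -> tuple[float, float]:
        """Fractional (row, col) -> (x, z) in mm."""
        return (
            self.x0_mm + col * self.spacing_mm,
            self.z0_mm + row * self.spacing_mm,
        )

    def contains(self, row: float, col: float) -> bool:
        return 0 <= row < self.valid_shape[0] and 0 <= col < self.valid_shape[1]


def _pad_to_multiple(img: np.ndarray, m: int = 4) -> np.ndarray:
    h, w = img.shape[-2:]
    ph = (-h) % m
    pw = (-w) % m
    if ph == 0 and pw == 0:
        return img
    pad = [(0, 0)] * (img.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(img, pad)


def build_coronal_recon(
    volume: Volume3D, body_mask: Volume3D | None = None
) -> CoronalRecon:
    """Resample to 2.5 mm isotropic, recentre each axial slice in AP,
    crop to the +-25 mm AP slab and extract the 3-channel coronal input."""
    if body_mask is None:
        body_mask = compute_body_mask(volume)
    iso = resample_volume(volume, (CORONAL_SPACING_MM,) * 3, order=1)
    mask_iso = resample_volume(body_mask, (CORONAL_SPACING_MM,) * 3, order=0)
    nx, ny, nz = iso.shape
    warnings: list = []

    counts = mask_iso.data.sum(axis=(0, 1))
    centroid = np.full(nz, np.nan)
    nonempty = counts > 0
    if not nonempty.any():
        raise ValueError("body mask empty on every axial slice")
    ys = np.arange(ny, dtype=float)
    centroid[nonempty] = (
        (mask_iso.data.sum(axis=0) * ys[:, None]).sum(axis=0)[nonempty]
        / counts[nonempty]
    )
    if (~nonempty).any():
        warnings.append(
            f"{int((~nonempty).sum())} axial slices had an empty body mask; "
            "AP shift interpolated from neighbours"
        )
        ks = np.arange(nz)
        centroid[~nonempty] = np.interp(
            ks[~nonempty], ks[nonempty], centroid[nonempty]
        )
    center = (ny - 1) / 2.0
    shifts = np.round(center - centroid).astype(int)

    shifted = np.empty_like(iso.data)
    for k in range(nz):
        shifted[:, :, k] = np.roll(iso.data[:, :, k], shifts[k], axis=1)
    half = int(round(AP_SLAB_HALF_MM / CORONAL_SPACING_MM))
    c = int(round(center))
    lo_y = max(0, c - half)
    hi_y = min(ny, c + half)
    slab = shifted[:, lo_y:hi_y, :]
    mid = slab.shape[1] // 2
    gap = max(1, int(round(CHANNEL_GAP_MM / CORONAL_SPACING_MM)))
    idxs = np.clip([mid - gap, mid, mid + gap], 0, slab.shape[1] - 1)
    # coronal image: rows = z, cols = x
    channels = np.stack([slab[:, j, :].T for j in idxs], axis=0)

    fg = channels[channels > 0]
    mean = float(fg.mean()) if fg.size else 0.0
    sd = max(float(fg.std()) if fg.size else 1.0, 1e-6)
    channels = ((channels - mean) / sd).astype(np.float32)
    valid = channels.shape[1:]
    channels = _pad_to_multiple(channels, 4)
    return CoronalRecon(
        channels=np.ascontiguousarray(channels),
        x0_mm=iso.origin[0],
        z0_mm=iso.origin[2],
        spacing_mm=CORONAL_SPACING_MM,
        shifts_vox=shifts,
        valid_shape=valid,
        norm={"mean": mean, "sd": sd},
        warnings=warnings,
    )


# -- heatmaps ------------------------------------------------------------

def with_coord_channels(channels: np.ndarray) -> np.ndarray:
    """Append normalized row/column coordinate channels.

    The heatmap decoder must assign locally identical structures (the
    two ankles, the two femoral heads) to distinct output channels; a
    translation-equivariant CNN cannot do that from appearance alone,
    so the absolute position is made an explicit input feature.
    """
    c, h, w = channels.shape
    rows = np.linspace(-1, 1, h, dtype=np.float32)[:, None]
    cols = np.linspace(-1, 1, w, dtype=np.float32)[None, :]
    rmap = np.broadcast_to(rows, (h, w))
    cmap = np.broadcast_to(cols, (h, w))
    return np.concatenate([channels, rmap[None], cmap[None]], axis=0)


def heatmap_targets(
    recon: CoronalRecon, landmarks: LandmarkSet, sigma_vox: float = 2.0
) -> tuple[np.ndarray, list]:
    """Per-landmark Gaussian target maps (peak normalized to 1).

    Landmarks without in-plane coordinates default to the midline
    (x = 0).  Landmarks falling outside the reconstruction are
    returned in the skipped list (all-zero map).
    """
    h, w = recon.channels.shape[1:]
    maps = np.zeros((len(HEATMAP_CLASSES), h, w), dtype=np.float32)
    rows = np.arange(h, dtype=np.float32)[:, None]
    cols = np.arange(w, dtype=np.float32)[None, :]
    skipped = []
    for name, side in KEYPOINT_CLASSES:
        z = landmarks.z(name, side)
        if z is None:
            skipped.append((name, side))
            continue
        x = landmarks.xy_mm.get((name, side), (0.0, 0.0))[0]
        r0, c0 = recon.to_image(x, z)
        if not recon.contains(r0, c0):
            skipped.append((name, side))
            continue
        g = np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sigma_vox**2))
        i = HEATMAP_CLASSES.index(name)
        maps[i] = np.maximum(maps[i], g / g.max())
    return maps, skipped


def decode_heatmap(
    heatmap: np.ndarray, min_peak: float = 0.1
) -> tuple[float, float] | None:
    """Sub-voxel peak via centre-of-mass of the >= 0.5 x max region
    connected to the argmax; ``None`` when no sufficient peak exists."""
    peaks = decode_peaks(heatmap, n_peaks=1, min_peak=min_peak)
    return peaks[0] if peaks else None


def decode_peaks(
    heatmap: np.ndarray,
    n_peaks: int = 2,
    min_peak: float = 0.1,
    min_separation: int = 8,
) -> list[tuple[float, float]]:
    """Up to ``n_peaks`` sub-voxel maxima, strongest first.

    Each peak is refined to the centre-of-mass of its connected
    >= 0.5 x peak region; subsequent peaks must be at least
    ``min_separation`` voxels from the ones already accepted.
    """
    work = heatmap.astype(np.float32).copy()
    out: list[tuple[float, float]] = []
    rr, cc = np.indices(heatmap.shape)
    for _ in range(n_peaks):
        peak = float(work.max())
        if peak < min_peak:
            break
        argmax = np.unravel_index(int(np.argmax(work)), work.shape)
        region = heatmap >= 0.5 * peak
        lab, _ = ndimage.label(region)
        region = lab == lab[argmax]
        weights = np.where(region, heatmap, 0.0)
        com = ndimage.center_of_mass(weights)
        out.append((float(com[0]), float(com[1])))
        suppress = (rr - argmax[0]) ** 2 + (cc - argmax[1]) ** 2 < min_separation**2
        work[suppress | region] = 0.0
    return out


# -- training ------------------------------------------------------------

def kfold_indices(ids: list, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic phantom/patient-level fold assignment.

    Raises when the same id appears twice (train/validation leakage)
    or when there are fewer subjects than folds.
    """
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in cohort; refusing leaky split")
    if len(ids) < n_folds:
        raise ValueError(f"{len(ids)} subjects cannot be split into {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return [order[f::n_folds] for f in range(n_folds)]


def train_position_regressor(
    stacks_per_subject: list[np.ndarray],
    targets_per_subject: list[np.ndarray],
    config: TrainConfig = TrainConfig(),
    ids: list | None = None,
) -> EnsembleModel:
    """Cross-validated training of the slice-position regressor.

    Each subject contributes per-slice 3-channel stacks and (left,
    right) position targets; folds are split at subject level, the
    loss is mean squared error, and the per-fold validation MAE is
    reported in ``fold_metrics``.
    """
    ids = ids if ids is not None else list(range(len(stacks_per_subject)))
    folds = kfold_indices(ids, config.n_folds, config.seed)
    members, metrics = [], []
    for f, val_idx in enumerate(folds):
        val_set = set(val_idx.tolist())
        tr = [i for i in range(len(ids)) if i not in val_set]
        X = np.concatenate([stacks_per_subject[i] for i in tr], axis=0)
        Y = np.concatenate([targets_per_subject[i] for i in tr], axis=0).astype(
            np.float32
        )
        model = nn.SliceRegressor(
            in_channels=3, n_outputs=2, base=config.base_channels,
            seed=config.seed + 1000 * f,
        )
        nn.fit(
            model, X, Y, nn.mse_loss, epochs=config.epochs,
            batch_size=config.reg_batch_size, lr=config.lr, seed=config.seed + f,
        )
        Xv = np.concatenate([stacks_per_subject[i] for i in val_idx], axis=0)
        Yv = np.concatenate([targets_per_subject[i] for i in val_idx], axis=0)
        pred = _batched_forward(model, Xv, config.batch_size)
        mae = float(np.mean(np.abs(pred - Yv)))
        metrics.append({"fold": f, "val_mae_units": mae, "n_val_slices": len(Xv)})
        members.append(model)
    return EnsembleModel(
        members=members, kind="regressor",
        fold_metrics=pd.DataFrame(metrics), config=config,
    )


def _batched_forward(model, X, batch_size):
    model.set_train(False)
    return np.concatenate(
        [
            model.forward(np.ascontiguousarray(X[i : i + batch_size], np.float32))
            for i in range(0, len(X), batch_size)
        ],
        axis=0,
    )


def _fit_heatmap_with_crops(
    model,
    X: np.ndarray,
    Y: np.ndarray,
    epochs: int,
    crops_per_image: int,
    crop_rows: int,
    batch_size: int,
    lr: float,
    seed: int,
) -> list[float]:
    """Heatmap training on random row-crops of the coronal images.

    The network is fully convolutional, so crops are valid training
    units; random crop offsets both augment the data and multiply the
    number of gradient steps an epoch provides, which is what makes
    from-scratch heatmap regression feasible in a handful of epochs.
    Coordinate channels stay attached to the full-image grid so
    absolute position information survives cropping.
    """
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model, lr=lr)
    n, _, h, _ = X.shape
    crop_rows = min(crop_rows, h)
    model.set_train(True)
    history = []
    r_max = h - crop_rows
    for _ in range(epochs):
        # stratified offsets: anchor a share of crops at the caudal and
        # cranial ends so border landmarks (ankles, femoral heads) are
        # seen as often as mid-leg ones
        pairs = []
        for i in range(n):
            for j in range(crops_per_image):
                u = rng.uniform()
                if u < 0.25:
                    r0 = rng.integers(0, max(1, crop_rows // 8))
                elif u < 0.5:
                    r0 = r_max - rng.integers(0, max(1, crop_rows // 8))
                else:
                    r0 = rng.integers(0, r_max + 1)
                pairs.append((i, int(r0)))
        pairs = np.array(pairs)
        rng.shuffle(pairs)
        losses = []
        for start in range(0, len(pairs), batch_size):
            chunk = pairs[start : start + batch_size]
            xb = np.stack([X[i, :, r0 : r0 + crop_rows] for i, r0 in chunk])
            yb = np.stack([Y[i, :, r0 : r0 + crop_rows] for i, r0 in chunk])
            out = model.forward(np.ascontiguousarray(xb))
            loss, dout = nn.weighted_mse_loss(out, yb)
            model.backward(dout)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    model.set_train(False)
    return history


def train_keypoint_detector(
    recons: list[CoronalRecon],
    landmark_sets: list[LandmarkSet],
    config: TrainConfig = TrainConfig(),
    ids: list | None = None,
) -> EnsembleModel:
    """Cross-validated training of the coronal heatmap detector."""
    ids = ids if ids is not None else list(range(len(recons)))
    folds = kfold_indices(ids, config.n_folds, config.seed)
    shapes = {r.channels.shape for r in recons}
    if len(shapes) != 1:
        raise ValueError(f"coronal recon shapes differ across cohort: {shapes}")
    X_all = np.stack([with_coord_channels(r.channels) for r in recons], axis=0)
    maps, n_skipped = [], 0
    for r, lm in zip(recons, landmark_sets):
        m, skipped = heatmap_targets(r, lm, config.heatmap_sigma_vox)
        n_skipped += len(skipped)
        maps.append(m)
    Y_all = np.stack(maps, axis=0)
    members, metrics = [], []
    for f, val_idx in enumerate(folds):
        val_set = set(val_idx.tolist())
        tr = [i for i in range(len(ids)) if i not in val_set]
        model = nn.UNet2p5(
            in_channels=5, out_channels=len(HEATMAP_CLASSES),
            base=max(4, config.base_channels // 2), seed=config.seed + 2000 * f,
            zero_head=True,
        )
        _fit_heatmap_with_crops(
            model, X_all[tr], Y_all[tr], epochs=config.kp_epochs,
            crops_per_image=config.kp_crops_per_image,
            crop_rows=config.kp_crop_rows, batch_size=config.kp_batch_size,
            lr=config.lr, seed=config.seed + 100 + f,
        )
        pred = _batched_forward(model, X_all[val_idx], 4)
        mse = float(np.mean((pred - Y_all[val_idx]) ** 2))
        metrics.append({"fold": f, "val_mse": mse, "n_val": len(val_idx)})
        members.append(model)
    return EnsembleModel(
        members=members, kind="keypoint",
        fold_metrics=pd.DataFrame(metrics), config=config,
        norm={"n_excluded_landmarks": n_skipped},
    )


# -- inference -----------------------------------------------------------

def predict_positions(
    volume: Volume3D, ensemble: EnsembleModel, body_mask: Volume3D | None = None
) -> SlicePositionTarget:
    """Per-slice (left, right) position curve for a whole volume.

    Slices without body-mask foreground carry no positional
    information and are excluded from the returned curve.
    """
    if body_mask is None:
        body_mask = compute_body_mask(volume)
    stacks, _ = make_slice_stacks(volume, body_mask)
    keep = body_mask.data.sum(axis=(0, 1)) > 0
    pred = ensemble.predict(stacks[keep])
    return SlicePositionTarget(slice_zs=volume.slice_zs[keep], positions=pred)


def predict_landmarks_regression(
    volume: Volume3D, ensemble: EnsembleModel, body_mask: Volume3D | None = None
) -> LandmarkSet:
    targets = predict_positions(volume, ensemble, body_mask)
    return landmarks_from_position_curve(targets)


def predict_keypoints(
    volume: Volume3D, ensemble: EnsembleModel, body_mask: Volume3D | None = None,
    min_peak: float = 0.1,
) -> LandmarkSet:
    recon = build_coronal_recon(volume, body_mask)
    return predict_keypoints_from_recon(recon, ensemble, min_peak=min_peak)


def predict_keypoints_from_recon(
    recon: CoronalRecon, ensemble: EnsembleModel, min_peak: float = 0.1
) -> LandmarkSet:
    x = with_coord_channels(recon.channels)
    maps = ensemble.predict(x[None], batch_size=1)[0]
    # padded margin carries no anatomy; decode in the valid region only
    maps = maps[:, : recon.valid_shape[0], : recon.valid_shape[1]]
    result = LandmarkSet(
        ankle_z={}, knee_z={}, femoral_head_z={}, symphysis_z=None,
        provenance="keypoint",
    )
    mid_col = recon.valid_shape[1] / 2.0
    for i, name in enumerate(HEATMAP_CLASSES):
        if name == "symphysis":
            peak = decode_heatmap(maps[i], min_peak=min_peak)
            if peak is not None:
                x_mm, z_mm = recon.from_image(*peak)
                result.symphysis_z = float(z_mm)
                result.xy_mm[(name, "")] = (float(x_mm), 0.0)
            continue
        peaks = decode_peaks(maps[i], n_peaks=2, min_peak=min_peak)
        store = getattr(result, f"{name}_z")
        store["left"] = store["right"] = None
        if len(peaks) == 2:
            # the left leg lies at smaller x in the canonical frame
            by_col = sorted(peaks, key=lambda p: p[1])
            pairs = zip(("left", "right"), by_col)
        elif len(peaks) == 1:
            side = "left" if peaks[0][1] < mid_col else "right"
            pairs = [(side, peaks[0])]
        else:
            pairs = []
        for side, peak in pairs:
            x_mm, z_mm = recon.from_image(*peak)
            store[side] = float(z_mm)
            result.xy_mm[(name, side)] = (float(x_mm), 0.0)
    return result


def fuse_landmarks(
    reg: LandmarkSet,
    kp: LandmarkSet,
    weights: dict | None = None,
) -> LandmarkSet:
    """Combine the two methods' landmark estimates into an ensemble.

    Without ``weights`` the available estimates are averaged.  When
    per-landmark-class precision weights are supplied — keyed
    ``(method, landmark_name)`` with method in {"regression",
    "keypoint"} — the combination is the inverse-variance weighted
    mean, the minimum-variance way to pool two unbiased estimators;
    the weights are estimated on cross-validation folds, never on test
    data.  A landmark one method missed is taken from the other.
    """

    def _fuse(name, a, b):
        w_a = w_b = 1.0
        if weights is not None:
            w_a = weights.get(("regression", name), 1.0)
            w_b = weights.get(("keypoint", name), 1.0)
        num = den = 0.0
        for v, w in ((a, w_a), (b, w_b)):
            if v is not None:
                num += w * v
                den += w
        return num / den if den > 0 else None

    fused = LandmarkSet(
        ankle_z={
            s: _fuse("ankle", reg.ankle_z.get(s), kp.ankle_z.get(s)) for s in SIDES
        },
        knee_z={
            s: _fuse("knee", reg.knee_z.get(s), kp.knee_z.get(s)) for s in SIDES
        },
        femoral_head_z={
            s: _fuse("femoral_head", reg.femoral_head_z.get(s),
                     kp.femoral_head_z.get(s))
            for s in SIDES
        },
        symphysis_z=_fuse("symphysis", reg.symphysis_z, kp.symphysis_z),
        provenance="ensemble",
    )
    return fused
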