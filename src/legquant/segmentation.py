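"""2.5D semantic segmentation of subcutaneous and subfascial tissue.

A U-Net-style encoder-decoder consumes three neighbouring axial
slices (5 mm apart) and predicts per-voxel probabilities over
{background, SCT, SFT}.  Training uses patient-level five-fold
cross-validation with a soft-Dice + cross-entropy loss; at test time
the fold models are applied as an ensemble by averaging their softmax
outputs.  Axial-only inference is the product path: a multi-view
variant adds nothing for this task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .landmarks import EnsembleModel, TrainConfig, _batched_forward, kfold_indices, make_slice_stacks
from .volume import Volume3D

__all__ = [
    "CLASS_NAMES",
    "ProbabilityMap",
    "SegmentationResult",
    "train_segmenter",
    "predict_ensemble",
    "split_legs",
    "dice_score",
]

#: class order; background first so that argmax ties resolve to background.
CLASS_NAMES = ("background", "SCT", "SFT")
LABELS = {name: i for i, name in enumerate(CLASS_NAMES)}


@dataclass
class ProbabilityMap:
    """Per-voxel class probabilities on the input grid, (nx, ny, nz, 3)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        if self.data.ndim != 4 or self.data.shape[-1] != len(CLASS_NAMES):
            raise ValueError(f"expected (nx, ny, nz, 3) probabilities, got {self.data.shape}")
        total = self.data.sum(axis=-1)
        if not np.allclose(total, 1.0, atol=1e-4):
            raise ValueError("class probabilities do not sum to 1")

    def argmax_labels(self) -> np.ndarray:
        return np.argmax(self.data, axis=-1).astype(np.int8)


@dataclass
class SegmentationResult:
    labels: Volume3D
    probabilities: ProbabilityMap
    left_labels: Volume3D
    right_labels: Volume3D
    provenance: dict


def train_segmenter(
    stacks_per_subject: list[np.ndarray],
    labels_per_subject: list[np.ndarray],
    config: TrainConfig = TrainConfig(),
    ids: list | None = None,
) -> EnsembleModel:
    """Cross-validated training of the tissue segmentation network.

    ``labels_per_subject[i]`` holds integer class maps (n_slices, nx, ny)
    aligned with the subject's slice stacks.  Per-fold validation Dice
    per tissue class is reported in ``fold_metrics``.
    """
    ids = ids if ids is not None else list(range(len(stacks_per_subject)))
    present = np.unique(np.concatenate([np.unique(l) for l in labels_per_subject]))
    for name, code in LABELS.items():
        if code not in present:
            raise ValueError(f"class {name!r} absent from training labels")
    folds = kfold_indices(ids, config.n_folds, config.seed)
    members, metrics = [], []
    for f, val_idx in enumerate(folds):
        val_set = set(val_idx.tolist())
        tr = [i for i in range(len(ids)) if i not in val_set]
        X = np.concatenate([stacks_per_subject[i] for i in tr], axis=0)
        Y = np.concatenate([labels_per_subject[i] for i in tr], axis=0).astype(np.int64)
        model = nn.UNet2p5(
            in_channels=3, out_channels=len(CLASS_NAMES),
            base=config.base_channels, seed=config.seed + 3000 * f,
        )
        nn.fit(
            model, X, Y, nn.softmax_ce_dice_loss, epochs=config.seg_epochs,
            batch_size=config.batch_size, lr=config.lr, seed=config.seed + 200 + f,
        )
        Xv = np.concatenate([stacks_per_subject[i] for i in val_idx], axis=0)
        Yv = np.concatenate([labels_per_subject[i] for i in val_idx], axis=0)
        logits = _batched_forward(model, Xv, config.batch_size)
        pred = np.argmax(logits, axis=1)
        row = {"fold": f, "n_val_slices": len(Xv)}
        for name in ("SCT", "SFT"):
            row[f"dice_{name.lower()}"] = dice_arrays(pred, Yv, LABELS[name])
        metrics.append(row)
        members.append(model)
    return EnsembleModel(
        members=members, kind="segmenter",
        fold_metrics=pd.DataFrame(metrics), config=config,
    )


def predict_ensemble(
    volume: Volume3D,
    ensemble: EnsembleModel,
    body_mask: Volume3D | None = None,
    batch_size: int = 16,
) -> SegmentationResult:
    """Ensemble inference: voxelwise mean of member softmax outputs.

    Labels are the argmax of the averaged probabilities with ties
    resolved toward background; the tissue foreground is split into
    left and right legs afterwards.
    """
    stacks, record = make_slice_stacks(volume, body_mask)
    prob_sum = None
    for m in ensemble.members:
        logits = _batched_forward(m, stacks, batch_size)
        p = nn.softmax_probs(logits, axis=1)
        prob_sum = p if prob_sum is None else prob_sum + p
    probs = prob_sum / len(ensemble.members)  # (nz, 3, nx, ny)
    probs = probs.transpose(2, 3, 0, 1)  # (nx, ny, nz, 3)
    pmap = ProbabilityMap(probs, volume.spacing, volume.origin)
    labels = Volume3D(pmap.argmax_labels(), volume.spacing, volume.origin)
    left, right = split_legs(labels)
    return SegmentationResult(
        labels=labels,
        probabilities=pmap,
        left_labels=left,
        right_labels=right,
        provenance={
            "n_members": len(ensemble.members),
            "normalization": record,
        },
    )


def split_legs(labels: Volume3D) -> tuple[Volume3D, Volume3D]:
    """Assign tissue foreground to the left and right leg.

    The body midline is the median foreground x over the whole volume.
    Per axial slice, each connected foreground component goes to the
    side of its centroid; components straddling both legs (merged
    torso) are cut at the midline plane.  In the canonical RAS frame
    x increases toward the patient's right.
    """
    from scipy import ndimage

    data = labels.data
    fg = data > 0
    if not fg.any():
        empty = labels.with_data(np.zeros_like(data))
        return empty, labels.with_data(np.zeros_like(data))

    # midline: average midpoint between the two leg centroids on slices
    # where the legs are separate; fall back to median foreground x.
    midpoints = []
    per_slice_components = []
    for k in range(data.shape[2]):
        sl = fg[:, :, k]
        if not sl.any():
            per_slice_components.append(None)
            continue
        comp, n = ndimage.label(sl)
        per_slice_components.append(comp)
        if n < 2:
            continue
        sizes = ndimage.sum_labels(sl, comp, index=np.arange(1, n + 1))
        big = np.argsort(sizes)[-2:] + 1
        if sizes[big - 1].min() < 0.1 * sizes.sum():
            continue
        cents = [np.nonzero(comp == c)[0].mean() for c in big]
        midpoints.append(0.5 * (cents[0] + cents[1]))
    midline = float(np.mean(midpoints)) if midpoints else float(
        np.median(np.nonzero(fg)[0])
    )

    left_mask = np.zeros_like(fg)
    x_index = np.arange(data.shape[0])[:, None]
    for k, comp in enumerate(per_slice_components):
        if comp is None:
            continue
        for c in range(1, comp.max() + 1):
            m = comp == c
            xs_c = np.nonzero(m)[0]
            if xs_c.max() < midline:
                left_mask[:, :, k] |= m
            elif xs_c.min() >= midline:
                pass  # right
            else:  # merged component: cut at the midline plane
                left_mask[:, :, k] |= m & (x_index < midline)
    left = np.where(left_mask, data, 0)
    right = np.where(fg & ~left_mask, data, 0)
    return labels.with_data(left), labels.with_data(right)


def dice_arrays(a: np.ndarray, b: np.ndarray, code: int) -> float:
    am = a == code
    bm = b == code
    sa, sb = int(am.sum()), int(bm.sum())
    if sa + sb == 0:
        return 1.0
    return float(2.0 * np.logical_and(am, bm).sum() / (sa + sb))


def dice_score(a: Volume3D, b: Volume3D, class_name: str) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) for one tissue class
    (defined as 1.0 when the class is absent from both)."""
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    return dice_arrays(a.data, b.data, LABELS[class_name])
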