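"""Entropy-based segmentation quality control.

The voxelwise Shannon entropy of the segmentation probability map is a
cheap uncertainty signal: confident (near one-hot) predictions have
entropy near 0, ambiguous ones approach ln 3.  A linear regression of
true Dice on mean entropy — fitted on cross-validation predictions —
then predicts segmentation quality for unseen scans, either for the
whole 3D volume or slice by slice; the slice-wise variant localizes
degradation caused by artifacts such as water-fat swaps or partial
volume effects.

Only slices between the ankles and femoral heads whose segmented area
exceeds 10% of the image section take part (an absolute cm^2 override
is available), and the regression targets the SCT class by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .leg_model import LandmarkSet
from .segmentation import LABELS, ProbabilityMap, SegmentationResult, dice_arrays
from .volume import Volume3D

__all__ = [
    "QCModel",
    "entropy_map",
    "eligible_slices",
    "qc_records",
    "fit_qc_model",
    "predict_quality",
]

MAX_ENTROPY = float(np.log(len(LABELS)))


@dataclass
class QCModel:
    """Linear map from mean probability-map entropy to expected Dice."""

    slope: float
    intercept: float
    scope: str  # "volume" | "slice"
    pearson_r: float
    p_value: float
    n: int
    tissue: str = "SCT"

    def predict_dice(self, entropy: float) -> float:
        return float(np.clip(self.intercept + self.slope * entropy, 0.0, 1.0))

    def to_json_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept, "scope": self.scope,
            "pearson_r": self.pearson_r, "p_value": self.p_value, "n": self.n,
            "tissue": self.tissue,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "QCModel":
        return cls(
            slope=d["slope"], intercept=d["intercept"], scope=d["scope"],
            pearson_r=d["pearson_r"], p_value=d["p_value"], n=d["n"],
            tissue=d.get("tissue", "SCT"),
        )


def entropy_map(probabilities: ProbabilityMap) -> Volume3D:
    """Voxelwise Shannon entropy H = -sum_c p_c ln p_c in nats
    (0 ln 0 := 0); bounded by ln(n_classes)."""
    p = probabilities.data
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    h = terms.sum(axis=-1)
    return Volume3D(
        h.astype(np.float32), probabilities.spacing, probabilities.origin
    )


def eligible_slices(
    seg: SegmentationResult,
    landmarks: LandmarkSet,
    min_fraction: float = 0.10,
    min_area_cm2: float | None = None,
) -> np.ndarray:
    """Indices of axial slices that take part in quality control.

    A slice is eligible iff its z lies between the (lowest) ankle and
    the (highest) femoral head and its segmented tissue area exceeds
    ``min_fraction`` of the in-plane image section (or the absolute
    ``min_area_cm2`` when given).
    """
    labels = seg.labels
    zs = labels.slice_zs
    dx, dy, _ = labels.spacing
    nx, ny = labels.shape[:2]
    tissue_vox = (labels.data > 0).sum(axis=(0, 1))
    area_cm2 = tissue_vox * dx * dy / 100.0
    if min_area_cm2 is not None:
        area_ok = area_cm2 > min_area_cm2
    else:
        area_ok = area_cm2 > min_fraction * (nx * ny * dx * dy / 100.0)
    z_ok = (zs >= landmarks.min_ankle_z) & (zs <= landmarks.max_femoral_head_z)
    return np.nonzero(area_ok & z_ok)[0]


def qc_records(
    seg: SegmentationResult,
    landmarks: LandmarkSet,
    truth_labels: Volume3D | None = None,
    scope: str = "slice",
    tissue: str = "SCT",
    min_fraction: float = 0.10,
    subject_id=None,
) -> pd.DataFrame:
    """QC feature table: mean entropy (and true Dice when available)
    per eligible unit (the whole volume, or each eligible slice)."""
    if scope not in ("volume", "slice"):
        raise ValueError(f"scope must be 'volume' or 'slice', got {scope!r}")
    h = entropy_map(seg.probabilities).data
    code = LABELS[tissue]
    idx = eligible_slices(seg, landmarks, min_fraction=min_fraction)
    zs = seg.labels.slice_zs
    rows = []
    if scope == "volume":
        if len(idx):
            ent = float(h[:, :, idx].mean())
            d = (
                dice_arrays(seg.labels.data[:, :, idx],
                            truth_labels.data[:, :, idx], code)
                if truth_labels is not None
                else np.nan
            )
            rows.append(
                {"subject": subject_id, "scope": "volume", "slice_index": -1,
                 "z_mm": np.nan, "entropy": ent, "dice_true": d, "eligible": True}
            )
    else:
        for k in idx:
            d = (
                dice_arrays(seg.labels.data[:, :, k],
                            truth_labels.data[:, :, k], code)
                if truth_labels is not None
                else np.nan
            )
            rows.append(
                {"subject": subject_id, "scope": "slice", "slice_index": int(k),
                 "z_mm": float(zs[k]), "entropy": float(h[:, :, k].mean()),
                 "dice_true": d, "eligible": True}
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "scope", "slice_index", "z_mm", "entropy",
                 "dice_true", "eligible"],
    )


def fit_qc_model(records: pd.DataFrame, scope: str, tissue: str = "SCT") -> QCModel:
    """Ordinary least squares of true Dice on mean entropy."""
    sub = records[(records["scope"] == scope) & records["eligible"]]
    sub = sub.dropna(subset=["dice_true", "entropy"])
    if len(sub) < 3:
        raise ValueError(f"need >= 3 records with ground truth, got {len(sub)}")
    x = sub["entropy"].to_numpy(dtype=float)
    y = sub["dice_true"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero entropy variance: degenerate regression")
    res = stats.linregress(x, y)
    return QCModel(
        slope=float(res.slope), intercept=float(res.intercept), scope=scope,
        pearson_r=float(res.rvalue), p_value=float(res.pvalue), n=len(sub),
        tissue=tissue,
    )


def predict_quality(
    seg: SegmentationResult,
    model: QCModel,
    landmarks: LandmarkSet,
    flag_threshold: float = 0.95,
    min_fraction: float = 0.10,
    subject_id=None,
) -> pd.DataFrame:
    """Predicted Dice per eligible unit; units below ``flag_threshold``
    are flagged for human review."""
    records = qc_records(
        seg, landmarks, truth_labels=None, scope=model.scope,
        tissue=model.tissue, min_fraction=min_fraction, subject_id=subject_id,
    )
    raw = model.intercept + model.slope * records["entropy"]
    records["dice_pred"] = raw.clip(0.0, 1.0)
    records["clamped"] = (raw < 0.0) | (raw > 1.0)
    records["flagged"] = records["dice_pred"] < flag_threshold
    return records
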