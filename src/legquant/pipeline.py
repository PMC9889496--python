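"""End-to-end orchestration: localize -> crop -> segment -> QC -> quantify.

Ties the stages together for whole-scan processing: body mask,
slice-position regression, coronal keypoint detection, landmark
fusion, cropping superior to the femoral heads, ensemble tissue
segmentation, entropy-based quality control and standardized
quantification.  Also provides cohort-level training and evaluation
used by the command-line interface and the synthetic validation
suite.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from .landmarks import (
    EnsembleModel,
    TrainConfig,
    build_coronal_recon,
    compute_body_mask,
    fuse_landmarks,
    make_slice_stacks,
    predict_keypoints,
    predict_keypoints_from_recon,
    predict_landmarks_regression,
    kfold_indices,
    train_keypoint_detector,
    train_position_regressor,
)
from .leg_model import LandmarkSet, build_slice_targets, evaluate_landmarks
from .nn.models import load_model, save_model
from .phantom import PhantomTruth
from .quantify import asymmetry, compute_profile, render_report
from .segmentation import dice_score, predict_ensemble, train_segmenter
from .volume import Volume3D, load_nifti, save_nifti

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "CohortData",
    "prepare_cohort",
    "train_all",
    "save_models",
    "load_models",
    "run_pipeline",
    "evaluate_cohort",
    "slab_flag_recall",
]


@dataclass
class PipelineConfig:
    """Serializable configuration for a pipeline run."""

    checkpoint_dir: str = "models"
    seed: int = 0
    qc_flag_threshold: float = 0.95
    qc_min_fraction: float = 0.10
    n_grid: int = 256
    save_probability_maps: bool = False
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        _validate_config(raw)
        train = TrainConfig(**raw.pop("train", {}))
        return cls(train=train, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _validate_config(raw: dict) -> None:
    allowed = {
        "checkpoint_dir", "seed", "qc_flag_threshold", "qc_min_fraction",
        "n_grid", "save_probability_maps", "train",
    }
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")


class RunManifest:
    """Append-only, machine-readable record of a pipeline run."""

    def __init__(self, config_hash: str):
        self.records: list[dict] = []
        self.config_hash = config_hash

    def add(self, stage: str, status: str, **info) -> None:
        self.records.append(
            {"stage": stage, "status": status, "config_hash": self.config_hash,
             **info}
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")

    def stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                status = "ok" if exc_type is None else "failed"
                manifest.add(
                    name, status, wall_time_s=round(time.time() - self.t0, 3),
                    **({"error": str(exc)} if exc else {}),
                )
                return False

        return _Timer()


# -- cohort data preparation --------------------------------------------

@dataclass
class CohortData:
    """Per-subject tensors ready for the three training tasks."""

    ids: list
    reg_stacks: list[np.ndarray]
    reg_targets: list[np.ndarray]
    seg_stacks: list[np.ndarray]
    seg_labels: list[np.ndarray]
    recons: list
    landmark_sets: list[LandmarkSet]
    truths: list[PhantomTruth]
    masks: list[Volume3D] = field(default_factory=list)


def prepare_cohort(
    truths: list[PhantomTruth],
    seed: int = 0,
    reg_slices_per_subject: int = 24,
    seg_slices_per_subject: int = 12,
) -> CohortData:
    """Build training tensors from ground-truth phantoms.

    Axial slices are subsampled per subject to keep CPU-scale training
    tractable: uniformly among tissue-bearing slices for segmentation;
    for position regression, half the slices are drawn near the
    landmark heights (the position curve is read off at its crossings
    of the canonical levels, so accuracy there is what matters) and
    half uniformly over the tissue-bearing range.
    """
    rng = np.random.default_rng(seed)
    data = CohortData([], [], [], [], [], [], [], truths, [])
    for i, truth in enumerate(truths):
        mask = compute_body_mask(truth.volume)
        stacks, _ = make_slice_stacks(truth.volume, mask)
        zs = truth.volume.slice_zs
        targets = build_slice_targets(
            truth.landmarks, zs
        ).positions.astype(np.float32)
        nz = stacks.shape[0]
        fg = np.nonzero((truth.labels.data > 0).any(axis=(0, 1)))[0]
        pool = fg if len(fg) else np.arange(nz)
        # empty slices carry no positional or tissue information
        landmark_zs = [
            z
            for name in ("ankle", "knee", "femoral_head")
            for z in getattr(truth.landmarks, f"{name}_z").values()
            if z is not None
        ] + ([truth.landmarks.symphysis_z] if truth.landmarks.symphysis_z else [])
        near = np.array(
            [k for k in pool if any(abs(zs[k] - lz) <= 40.0 for lz in landmark_zs)]
        )
        n_reg = min(reg_slices_per_subject, len(pool))
        n_near = min(n_reg // 2, len(near))
        reg_idx = rng.choice(near, size=n_near, replace=False)
        rest_pool = np.setdiff1d(pool, reg_idx)
        reg_idx = np.sort(
            np.concatenate(
                [reg_idx,
                 rng.choice(rest_pool, size=min(n_reg - n_near, len(rest_pool)),
                            replace=False)]
            )
        )
        seg_idx = np.sort(
            rng.choice(pool, size=min(seg_slices_per_subject, len(pool)),
                       replace=False)
        )
        labels_zxy = truth.labels.data.transpose(2, 0, 1).astype(np.int64)
        data.ids.append(i)
        data.reg_stacks.append(stacks[reg_idx])
        data.reg_targets.append(targets[reg_idx])
        data.seg_stacks.append(stacks[seg_idx])
        data.seg_labels.append(labels_zxy[seg_idx])
        data.recons.append(build_coronal_recon(truth.volume, mask))
        data.landmark_sets.append(truth.landmarks)
        data.masks.append(mask)
    return data


def train_all(
    cohort: CohortData, config: TrainConfig = TrainConfig()
) -> dict:
    """Train the three cross-validated ensembles and fit QC models.

    The QC regressions are fitted on the validation-fold predictions
    of the segmentation models (each subject predicted by the one fold
    model that did not see it).
    """
    reg = train_position_regressor(
        cohort.reg_stacks, cohort.reg_targets, config, ids=cohort.ids
    )
    kp = train_keypoint_detector(
        cohort.recons, cohort.landmark_sets, config, ids=cohort.ids
    )
    seg = train_segmenter(cohort.seg_stacks, cohort.seg_labels, config,
                          ids=cohort.ids)

    folds = kfold_indices(cohort.ids, config.n_folds, config.seed)
    records = []
    lm_sq_err: dict[tuple[str, str], list[float]] = {}
    for f, val_idx in enumerate(folds):
        member = EnsembleModel(members=[seg.members[f]], kind="segmenter")
        for i in val_idx:
            truth = cohort.truths[i]
            mask = cohort.masks[i] if cohort.masks else None
            res = predict_ensemble(truth.volume, member, mask)
            for scope in ("volume", "slice"):
                records.append(
                    qc_mod.qc_records(
                        res, truth.landmarks, truth_labels=truth.labels,
                        scope=scope, subject_id=i,
                    )
                )
    # Fusion weights: each method's FULL ensemble is scored on the
    # development cohort.  Single fold members would misrepresent the
    # keypoint branch, whose accuracy comes from averaging the member
    # heatmaps; both methods are assessed identically and the result is
    # eight scalars, so the in-sample optimism is negligible.
    for i in cohort.ids:
        truth = cohort.truths[i]
        mask = cohort.masks[i] if cohort.masks else None
        lm_reg = predict_landmarks_regression(truth.volume, reg, mask)
        lm_kp = predict_keypoints_from_recon(cohort.recons[i], kp)
        for method, lm in (("regression", lm_reg), ("keypoint", lm_kp)):
            ev = evaluate_landmarks(lm, truth.landmarks)
            for row in ev.table.itertuples():
                err = row.dz_mm if np.isfinite(row.dz_mm) else 200.0
                lm_sq_err.setdefault((method, row.landmark), []).append(err**2)
    # inverse-variance weights; the 1 mm^2 floor keeps them finite
    fusion_weights = {
        key: 1.0 / (float(np.mean(v)) + 1.0) for key, v in lm_sq_err.items()
    }
    qc_table = pd.concat(records, ignore_index=True)
    qc_models = {}
    for scope in ("volume", "slice"):
        try:
            qc_models[scope] = qc_mod.fit_qc_model(qc_table, scope)
        except ValueError:
            qc_models[scope] = None
    return {
        "regressor": reg, "keypoint": kp, "segmenter": seg,
        "qc_models": qc_models, "qc_training_records": qc_table,
        "fusion_weights": fusion_weights,
    }


# -- persistence ---------------------------------------------------------

def save_models(models: dict, checkpoint_dir) -> None:
    ckpt = Path(checkpoint_dir)
    ckpt.mkdir(parents=True, exist_ok=True)
    for key in ("regressor", "keypoint", "segmenter"):
        ens: EnsembleModel = models[key]
        sub = ckpt / key
        sub.mkdir(exist_ok=True)
        for i, m in enumerate(ens.members):
            save_model(m, sub / f"fold{i}.npz")
        if ens.fold_metrics is not None:
            ens.fold_metrics.to_csv(sub / "fold_metrics.csv", index=False)
    for scope, model in models.get("qc_models", {}).items():
        if model is not None:
            with open(ckpt / f"qc_{scope}.json", "w") as fh:
                json.dump(model.to_json_dict(), fh, indent=2)
    if models.get("fusion_weights"):
        with open(ckpt / "fusion_weights.json", "w") as fh:
            json.dump(
                {f"{m}|{lm}": w for (m, lm), w in models["fusion_weights"].items()},
                fh, indent=2,
            )


def load_models(checkpoint_dir) -> dict:
    ckpt = Path(checkpoint_dir)
    out: dict = {"qc_models": {}}
    for key in ("regressor", "keypoint", "segmenter"):
        sub = ckpt / key
        paths = sorted(sub.glob("fold*.npz"))
        if not paths:
            raise FileNotFoundError(f"missing checkpoints for {key!r} in {ckpt}")
        members = [load_model(p) for p in paths]
        metrics_path = sub / "fold_metrics.csv"
        metrics = pd.read_csv(metrics_path) if metrics_path.exists() else None
        out[key] = EnsembleModel(members=members, kind=key, fold_metrics=metrics)
    for scope in ("volume", "slice"):
        p = ckpt / f"qc_{scope}.json"
        if p.exists():
            with open(p) as fh:
                out["qc_models"][scope] = qc_mod.QCModel.from_json_dict(json.load(fh))
    fw = ckpt / "fusion_weights.json"
    if fw.exists():
        with open(fw) as fh:
            out["fusion_weights"] = {
                tuple(k.split("|")): v for k, v in json.load(fh).items()
            }
    return out


# -- end-to-end ----------------------------------------------------------

def run_pipeline(volume_path, config: PipelineConfig, out_dir) -> Path:
    """Process one scan from NIfTI to report; every stage is logged.

    Fails before any compute when checkpoints are missing; a stage
    failure halts the run with the partial manifest preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.config_hash())
    models = load_models(config.checkpoint_dir)  # fail-fast on checkpoints
    try:
        with manifest.stage("load"):
            volume = (
                volume_path
                if isinstance(volume_path, Volume3D)
                else load_nifti(volume_path)
            )
            digest = hashlib.sha256(
                np.ascontiguousarray(volume.data).tobytes()
            ).hexdigest()[:12]
            manifest.add("input", "ok", digest=digest)
        with manifest.stage("body_mask"):
            mask = compute_body_mask(volume)
        with manifest.stage("position_regression"):
            lm_reg = predict_landmarks_regression(volume, models["regressor"], mask)
        with manifest.stage("keypoint_detection"):
            lm_kp = predict_keypoints(volume, models["keypoint"], mask)
        with manifest.stage("landmark_fusion"):
            landmarks = fuse_landmarks(
                lm_reg, lm_kp, weights=models.get("fusion_weights")
            )
            landmarks.to_json(out / "landmarks.json")
            missing = [
                (n, s)
                for n in ("ankle", "knee", "femoral_head")
                for s in ("left", "right")
                if landmarks.z(n, s) is None
            ]
            if missing:
                manifest.add(
                    "landmark_fusion", "warning",
                    not_detected=[f"{n}/{s}" for n, s in missing],
                )
        with manifest.stage("segmentation"):
            seg = predict_ensemble(volume, models["segmenter"], mask)
            save_nifti(seg.labels, out / "segmentation_labels.nii.gz")
            if config.save_probability_maps:
                for c, name in enumerate(("background", "SCT", "SFT")):
                    save_nifti(
                        Volume3D(
                            seg.probabilities.data[..., c],
                            volume.spacing, volume.origin,
                        ),
                        out / f"probability_{name}.nii.gz",
                    )
        have_crop_landmarks = any(
            z is not None for z in landmarks.femoral_head_z.values()
        ) and any(z is not None for z in landmarks.ankle_z.values())
        with manifest.stage("quality_control"):
            qc_tables = []
            if not have_crop_landmarks:
                manifest.add(
                    "quality_control", "warning",
                    reason="landmarks unavailable; slice eligibility undefined",
                )
            for scope, model in models["qc_models"].items():
                if model is None or not have_crop_landmarks:
                    continue
                t = qc_mod.predict_quality(
                    seg, model, landmarks,
                    flag_threshold=config.qc_flag_threshold,
                    min_fraction=config.qc_min_fraction,
                )
                qc_tables.append(t)
                n_flagged = int(t["flagged"].sum())
                if n_flagged:
                    manifest.add(
                        "quality_control", "warning", scope=scope,
                        flagged_units=n_flagged,
                    )
            if qc_tables:
                pd.concat(qc_tables, ignore_index=True).to_csv(
                    out / "qc.csv", index=False
                )
        with manifest.stage("quantification"):
            left, right = seg.left_labels, seg.right_labels
            if not have_crop_landmarks:
                manifest.add(
                    "quantification", "warning",
                    reason="landmarks unavailable; native-axis profile only",
                )
            profile = compute_profile(
                left, right,
                landmarks if have_crop_landmarks else None,
                n_grid=config.n_grid,
            )
            report_files = {}
            try:
                asym = asymmetry(profile)
            except ValueError:
                asym = None
            report_files = render_report(profile, out, asym=asym)
            manifest.add("report", "ok", files=report_files)
    finally:
        manifest.write(out / "manifest.jsonl")
    return out


def evaluate_cohort(
    test_truths: list[PhantomTruth],
    models: dict,
    qc_on_truth: bool = True,
) -> dict:
    """Held-out evaluation: landmark deviations, Dice, volume errors.

    Test subjects must be disjoint from training (enforced upstream by
    the fold construction; identical volumes here raise).
    """
    digests = [
        hashlib.sha256(np.ascontiguousarray(t.volume.data).tobytes()).hexdigest()
        for t in test_truths
    ]
    if len(set(digests)) != len(digests):
        raise ValueError("duplicate volumes in test cohort")
    lm_rows, dice_rows, vol_rows, qc_records_all = [], [], [], []
    for i, truth in enumerate(test_truths):
        mask = compute_body_mask(truth.volume)
        lm_reg = predict_landmarks_regression(truth.volume, models["regressor"], mask)
        lm_kp = predict_keypoints(truth.volume, models["keypoint"], mask)
        fused = fuse_landmarks(lm_reg, lm_kp, weights=models.get("fusion_weights"))
        for name, lm in (("regression", lm_reg), ("keypoint", lm_kp),
                         ("ensemble", fused)):
            ev = evaluate_landmarks(lm, truth.landmarks)
            lm_rows.append(
                {"subject": i, "method": name, "mean_dz_mm": ev.mean_dz_mm,
                 "sd_dz_mm": ev.sd_dz_mm, "fraction_within_10mm": ev.fraction_within,
                 "n_missing": ev.n_missing}
            )
        seg = predict_ensemble(truth.volume, models["segmenter"], mask)
        for tissue in ("SCT", "SFT"):
            dice_rows.append(
                {"subject": i, "tissue": tissue,
                 "dice": dice_score(seg.labels, truth.labels, tissue)}
            )
        profile = compute_profile(seg.left_labels, seg.right_labels, fused)
        for (leg, tissue), v in profile.volumes_l.items():
            truth_v = truth.analytic_volumes_l[(leg, tissue)]
            vol_rows.append(
                {"subject": i, "leg": leg, "tissue": tissue, "volume_l": v,
                 "analytic_l": truth_v,
                 "rel_error_pct": 100.0 * (v - truth_v) / truth_v}
            )
        if qc_on_truth:
            for scope in ("volume", "slice"):
                qc_records_all.append(
                    qc_mod.qc_records(
                        seg, truth.landmarks, truth_labels=truth.labels,
                        scope=scope, subject_id=i,
                    )
                )
    out = {
        "landmarks": pd.DataFrame(lm_rows),
        "dice": pd.DataFrame(dice_rows),
        "volumes": pd.DataFrame(vol_rows),
    }
    if qc_records_all:
        out["qc_records"] = pd.concat(qc_records_all, ignore_index=True)
    return out


def slab_flag_recall(
    qc_table: pd.DataFrame, slabs: list[dict]
) -> tuple[float, float]:
    """(recall, precision) of flagged slices against corrupted slabs.

    Recall: fraction of eligible slices inside any slab that were
    flagged.  Precision: fraction of flagged slices that lie inside a
    slab.  NaN when the denominator is empty.
    """
    if qc_table.empty:
        return float("nan"), float("nan")
    z = qc_table["z_mm"].to_numpy(dtype=float)
    in_slab = np.zeros(len(z), dtype=bool)
    for slab in slabs:
        in_slab |= (z >= slab["z_lo_mm"]) & (z <= slab["z_hi_mm"])
    flagged = qc_table["flagged"].to_numpy(dtype=bool)
    recall = (
        float(np.mean(flagged[in_slab])) if in_slab.any() else float("nan")
    )
    precision = (
        float(np.mean(in_slab[flagged])) if flagged.any() else float("nan")
    )
    return recall, precision
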