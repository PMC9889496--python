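"""Standardized tissue volume, distribution and asymmetry reporting.

Per-leg tissue masks become per-slice cross-sectional areas (cm^2),
integrated volumes (litres, area x reconstructed slice spacing), and
— after mapping onto the canonical leg axis — length-, thickness- and
position-independent distribution profiles.  Mirrored left/right
profiles with shaded asymmetric portions reproduce the standard
report; longitudinal deltas compare baseline and follow-up scans on
the common normalized grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .leg_model import (
    CANONICAL_POSITIONS,
    SIDES,
    LandmarkSet,
    normalize_profile,
)
from .profiles import TISSUES, AsymmetryReport, LongitudinalDelta, TissueProfile
from .segmentation import LABELS
from .volume import Volume3D

__all__ = [
    "compute_profile",
    "asymmetry",
    "longitudinal_delta",
    "render_report",
]


def compute_profile(
    left_labels: Volume3D,
    right_labels: Volume3D,
    landmarks: LandmarkSet | None,
    n_grid: int = 256,
) -> TissueProfile:
    """Per-slice areas and integrated volumes from per-leg label maps.

    Axial slices superior to the femoral heads are excluded before any
    integration.  ``area_cm2`` counts voxels x in-plane pixel area;
    volumes multiply by the reconstructed slice *spacing* (overlapping
    reconstructions double-cover tissue, so spacing, not slice
    thickness, is the correct integration step).  Without landmarks
    only the native-axis profile is produced.
    """
    if left_labels.shape != right_labels.shape:
        raise ValueError("left/right label grids differ")
    dx, dy, dz = left_labels.spacing
    zs = left_labels.slice_zs
    keep = np.ones(len(zs), dtype=bool)
    if landmarks is not None:
        keep = zs <= landmarks.max_femoral_head_z
    rows = []
    for side, vol in (("left", left_labels), ("right", right_labels)):
        for tissue in TISSUES:
            counts = (vol.data == LABELS[tissue]).sum(axis=(0, 1))
            for k in np.nonzero(keep)[0]:
                rows.append(
                    {
                        "slice_index": int(k),
                        "z_mm": float(zs[k]),
                        "leg": side,
                        "tissue": tissue,
                        "area_cm2": float(counts[k] * dx * dy / 100.0),
                    }
                )
    native = pd.DataFrame(rows)
    volumes = {}
    for (side, tissue), sub in native.groupby(["leg", "tissue"]):
        volumes[(side, tissue)] = float(sub["area_cm2"].sum() * dz / 10.0 / 1000.0)
    profile = TissueProfile(
        native=native,
        normalized=None,
        volumes_l=volumes,
        spacing_mm=(dx, dy, dz),
        meta={
            "crop_z_max_mm": float(landmarks.max_femoral_head_z)
            if landmarks is not None
            else None,
            "landmark_provenance": landmarks.provenance if landmarks else None,
        },
    )
    if landmarks is not None and any(landmarks.has_side(s) for s in SIDES):
        profile = normalize_profile(profile, landmarks, n_grid=n_grid)
    return profile


def asymmetry(profile: TissueProfile) -> AsymmetryReport:
    """Pointwise min/excess decomposition of the two legs per tissue."""
    if profile.normalized is None or profile.normalized.empty:
        raise ValueError("asymmetry requires a normalized profile")
    wide = profile.normalized.pivot_table(
        index=["norm_pos", "tissue"], columns="leg", values="area_cm2"
    )
    if "left" not in wide.columns or "right" not in wide.columns:
        missing = [s for s in SIDES if s not in wide.columns]
        raise ValueError(f"asymmetry requires both legs; missing {missing}")
    wide = wide.reset_index()
    left = wide["left"].to_numpy(dtype=float)
    right = wide["right"].to_numpy(dtype=float)
    shared = np.minimum(left, right)
    excess = np.abs(left - right)
    side = np.where(left > right, "left", np.where(right > left, "right", ""))
    table = pd.DataFrame(
        {
            "norm_pos": wide["norm_pos"],
            "tissue": wide["tissue"],
            "shared_cm2": shared,
            "excess_cm2": excess,
            "excess_side": side,
        }
    )
    mmpu = profile.meta.get("mm_per_unit", {})
    asym_vol: dict[str, float] = {}
    by_side: dict[tuple[str, str], float] = {}
    for tissue in TISSUES:
        t_mask = (table["tissue"] == tissue).to_numpy()
        total = 0.0
        for s in SIDES:
            if s not in mmpu:
                continue
            sel = t_mask & (table["excess_side"].to_numpy() == s)
            sub = table[sel]
            if sub.empty:
                by_side[(s, tissue)] = 0.0
                continue
            grid = sub["norm_pos"].to_numpy(dtype=float)
            step = np.diff(np.unique(table["norm_pos"]))[0]
            mm = np.interp(grid, np.unique(table["norm_pos"]), mmpu[s])
            v = float(np.sum(sub["excess_cm2"].to_numpy() * mm * step / 10.0) / 1000.0)
            by_side[(s, tissue)] = v
            total += v
        asym_vol[tissue] = total
    return AsymmetryReport(
        table=table, asymmetric_volume_l=asym_vol, excess_volume_by_side_l=by_side
    )


def longitudinal_delta(
    baseline: TissueProfile, followup: TissueProfile
) -> LongitudinalDelta:
    """Baseline minus follow-up areas on the baseline's normalized grid."""
    for name, p in (("baseline", baseline), ("follow-up", followup)):
        if p.normalized is None or p.normalized.empty:
            raise ValueError(f"{name} profile is not normalized")
    base = baseline.normalized
    fol = followup.normalized
    rows = []
    for (side, tissue), bsub in base.groupby(["leg", "tissue"]):
        fsub = fol[(fol["leg"] == side) & (fol["tissue"] == tissue)]
        if fsub.empty:
            continue
        grid = bsub["norm_pos"].to_numpy(dtype=float)
        b = bsub["area_cm2"].to_numpy(dtype=float)
        f = np.interp(
            grid, fsub["norm_pos"].to_numpy(dtype=float),
            fsub["area_cm2"].to_numpy(dtype=float),
        )
        delta = b - f
        rows.append(
            pd.DataFrame(
                {
                    "norm_pos": grid, "leg": side, "tissue": tissue,
                    "baseline_cm2": b, "followup_cm2": f, "delta_cm2": delta,
                    "decrease_cm2": np.clip(delta, 0.0, None),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    change = {
        key: baseline.volumes_l.get(key, 0.0) - followup.volumes_l.get(key, 0.0)
        for key in set(baseline.volumes_l) | set(followup.volumes_l)
    }
    return LongitudinalDelta(
        table=table,
        volume_change_l=change,
        baseline_volumes_l=dict(baseline.volumes_l),
        followup_volumes_l=dict(followup.volumes_l),
    )


def _summary_dict(profile, asym=None, delta=None) -> dict:
    out = {
        "schema_version": 1,
        "volumes_l": {
            f"{leg}|{tissue}": round(v, 1)
            for (leg, tissue), v in sorted(profile.volumes_l.items())
        },
        "volumes_l_exact": {
            f"{leg}|{tissue}": v for (leg, tissue), v in sorted(profile.volumes_l.items())
        },
        "total_volume_l": {
            tissue: round(
                sum(v for (s, t), v in profile.volumes_l.items() if t == tissue), 1
            )
            for tissue in TISSUES
        },
    }
    if asym is not None:
        out["asymmetric_volume_l"] = {
            t: round(v, 1) for t, v in asym.asymmetric_volume_l.items()
        }
        out["asymmetric_volume_l_exact"] = dict(asym.asymmetric_volume_l)
    if delta is not None:
        out["volume_change_l"] = {
            f"{leg}|{tissue}": round(v, 1)
            for (leg, tissue), v in sorted(delta.volume_change_l.items())
        }
    return out


def render_report(
    profile: TissueProfile,
    out_dir,
    asym: AsymmetryReport | None = None,
    delta: LongitudinalDelta | None = None,
    stem: str = "report",
) -> dict:
    """Emit the profile CSV, a JSON summary and the mirrored
    area-vs-position figure (SVG + PNG).

    The figure is drawn from the emitted CSV — the visualization is a
    pure function of the tabular output, so it can be validated at the
    table level without image comparison.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    native_csv = out / f"{stem}_profile_native.csv"
    profile.native.to_csv(native_csv, index=False)
    paths["native_csv"] = native_csv
    if profile.normalized is not None and not profile.normalized.empty:
        norm_csv = out / f"{stem}_profile_normalized.csv"
        profile.normalized.to_csv(norm_csv, index=False)
        paths["normalized_csv"] = norm_csv
        paths.update(
            _render_figure(norm_csv, profile, asym, delta, out, stem)
        )
    summary = _summary_dict(profile, asym, delta)
    summary_json = out / f"{stem}_summary.json"
    with open(summary_json, "w") as fh:
        json.dump(summary, fh, indent=2)
    paths["summary_json"] = summary_json
    return {k: str(v) for k, v in paths.items()}


def _render_figure(norm_csv, profile, asym, delta, out: Path, stem: str) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = pd.read_csv(norm_csv)  # data-first: the figure reads the CSV
    fig, ax = plt.subplots(figsize=(6, 8))
    colors = {"SFT": "#2c5f8a", "SCT": "#e8c23a"}
    dark = {"SFT": "#16304a", "SCT": "#a8831a"}
    for side, sign in (("left", -1.0), ("right", 1.0)):
        sub = table[table["leg"] == side]
        if sub.empty:
            continue
        sft = sub[sub["tissue"] == "SFT"].sort_values("norm_pos")
        sct = sub[sub["tissue"] == "SCT"].sort_values("norm_pos")
        pos = sft["norm_pos"].to_numpy()
        a_sft = sft["area_cm2"].to_numpy()
        a_out = a_sft + sct["area_cm2"].to_numpy()
        ax.fill_betweenx(pos, 0, sign * a_sft, color=colors["SFT"], linewidth=0)
        ax.fill_betweenx(pos, sign * a_sft, sign * a_out, color=colors["SCT"],
                         linewidth=0)
        for tissue in TISSUES:
            v = profile.volume_l(side, tissue)
            ax.text(
                sign * 0.75 * float(np.max(a_out)), -0.9 + (0.08 if tissue == "SCT" else 0),
                f"{tissue} {v:.1f} L", ha="center", fontsize=8,
                color=dark[tissue],
            )
    if asym is not None:
        for tissue in TISSUES:
            sub = asym.table[asym.table["tissue"] == tissue]
            for side, sign in (("left", -1.0), ("right", 1.0)):
                sel = sub[sub["excess_side"] == side]
                if sel.empty:
                    continue
                ax.fill_betweenx(
                    sel["norm_pos"], 0, sign * sel["excess_cm2"],
                    color=dark[tissue], alpha=0.5, linewidth=0,
                )
    if delta is not None:
        for side, sign in (("left", -1.0), ("right", 1.0)):
            sub = delta.table[delta.table["leg"] == side]
            dec = sub.groupby("norm_pos")["decrease_cm2"].sum()
            ax.fill_betweenx(
                dec.index.to_numpy(), 0, sign * dec.to_numpy(),
                color="#c0392b", alpha=0.6, linewidth=0,
            )
    for name, p in CANONICAL_POSITIONS.items():
        ax.axhline(p, linestyle=":", color="0.4", linewidth=0.8)
        ax.text(ax.get_xlim()[1], p, f" {name}", va="center", fontsize=7)
    ax.set_ylabel("normalized leg position")
    ax.set_xlabel("cross-sectional area (cm$^2$)  [left | right]")
    ax.set_ylim(-1.05, 1.3)
    fig.tight_layout()
    paths = {}
    for ext in ("svg", "png"):
        p = out / f"{stem}_figure.{ext}"
        fig.savefig(p, dpi=110)
        paths[f"figure_{ext}"] = p
    plt.close(fig)
    return paths
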