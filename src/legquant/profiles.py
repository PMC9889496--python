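"""Containers for per-slice tissue area profiles and derived reports."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["TissueProfile", "AsymmetryReport", "LongitudinalDelta", "TISSUES"]

TISSUES = ("SCT", "SFT")


@dataclass
class TissueProfile:
    """Cross-sectional tissue areas per slice, plus integrated volumes.

    ``native`` has one row per (slice, leg, tissue) with columns
    ``slice_index, z_mm, leg, tissue, area_cm2``; ``normalized`` (when
    present) has one row per (grid point, leg, tissue) with columns
    ``norm_pos, leg, tissue, area_cm2`` on the canonical axis
    [-1, 1.220].  ``volumes_l`` maps ``(leg, tissue)`` to litres
    integrated on the native axis (area x reconstructed slice spacing).
    """

    native: pd.DataFrame
    normalized: pd.DataFrame | None
    volumes_l: dict[tuple[str, str], float]
    spacing_mm: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def volume_l(self, leg: str, tissue: str) -> float:
        return self.volumes_l.get((leg, tissue), 0.0)

    def to_csv(self, path) -> None:
        self.native.to_csv(path, index=False)


@dataclass
class AsymmetryReport:
    """Pointwise left/right decomposition on the normalized axis.

    For each grid point and tissue: shared area = min(left, right),
    excess = |left - right| attributed to the larger side.  The
    asymmetric volume per tissue integrates the excess in litres.
    """

    table: pd.DataFrame  # norm_pos, tissue, shared_cm2, excess_cm2, excess_side
    asymmetric_volume_l: dict[str, float]
    excess_volume_by_side_l: dict[tuple[str, str], float]


@dataclass
class LongitudinalDelta:
    """Baseline vs follow-up comparison on a common normalized grid."""

    table: pd.DataFrame  # norm_pos, leg, tissue, baseline_cm2, followup_cm2,
    #                      delta_cm2 (baseline - followup), decrease_cm2 (clipped >= 0)
    volume_change_l: dict[tuple[str, str], float]  # baseline - followup
    baseline_volumes_l: dict[tuple[str, str], float]
    followup_volumes_l: dict[tuple[str, str], float]
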