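"""Defect classification and lung-level defect metrics.

Thresholds (defaults as calibrated at 1.5 T in the PREFUL literature, and
fully configurable):

* perfusion defect:   Q < 2 % of the full-blood reference amplitude;
* ventilation defect: RV < 40 % of the lung's 90th ventilation percentile
  (or FVL correlation < 0.9 in flow-volume-loop mode);
* the four categories (exclusive ventilation defect, exclusive perfusion
  defect, combined V/Q defect, V/Q match) partition the valid lung area
  exactly; VDP = exclusive-V + combined, QDP = exclusive-Q + combined.

A value exactly equal to a threshold is non-defect (strict ``<`` tests).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .core import QuantitativeMap

__all__ = [
    "QuantificationConfig",
    "DefectClassification",
    "MetricsReport",
    "SeverityStratum",
    "classify_defects",
    "compute_metrics",
    "stratify_by_vc",
    "SEVERITY_ORDER",
]

SEVERITY_ORDER = ("mild", "moderate", "severe")

#: integer codes in the category label map
CATEGORY_CODES = {
    "vqm_nondefect": 1,
    "vent_defect_only": 2,
    "perf_defect_only": 3,
    "vq_defect": 4,
    "no_data": 0,
}


@dataclass(frozen=True)
class QuantificationConfig:
    perfusion_defect_threshold: float = 2.0
    vent_defect_fraction: float = 0.40
    fvl_defect_threshold: float = 0.9
    vdp_mode: Literal["regional_ventilation", "fvl"] = "regional_ventilation"

    def validate(self) -> None:
        if self.perfusion_defect_threshold <= 0:
            raise ValueError("perfusion threshold must be positive")
        if not (0.0 < self.vent_defect_fraction < 1.0):
            raise ValueError("ventilation defect fraction must lie in (0, 1)")
        if not (0.0 < self.fvl_defect_threshold <= 1.0):
            raise ValueError("FVL threshold must lie in (0, 1]")


@dataclass
class DefectClassification:
    """Per-voxel defect categories partitioning the valid lung mask."""

    labels: np.ndarray  # integer codes per CATEGORY_CODES
    valid_mask: np.ndarray
    vent_defect: np.ndarray
    perf_defect: np.ndarray
    vent_threshold_used: float
    perf_threshold_used: float
    mode: str

    def category_mask(self, name: str) -> np.ndarray:
        return self.labels == CATEGORY_CODES[name]


@dataclass
class MetricsReport:
    """Lung-level summary: mean maps plus defect percentages of valid area."""

    mean_ventilation: float
    mean_perfusion: float
    vdp: float
    qdp: float
    vqm_defect: float
    vqm_nondefect: float
    vent_defect_only_pct: float
    perf_defect_only_pct: float
    valid_area_voxels: int
    thresholds: dict
    identifier: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    def to_row(self) -> dict:
        """One CSV row with the standard measure abbreviations."""
        return {
            "id": self.identifier,
            "V": self.mean_ventilation,
            "Q": self.mean_perfusion,
            "VDP": self.vdp,
            "QDP": self.qdp,
            "VQM defect": self.vqm_defect,
            "VQM non-defect": self.vqm_nondefect,
        }


@dataclass(frozen=True)
class SeverityStratum:
    label: Literal["mild", "moderate", "severe"]
    vc_lower: float
    vc_upper: float


def classify_defects(
    vent_map: QuantitativeMap,
    perf_map: QuantitativeMap,
    fvl_map: QuantitativeMap | None,
    mask: np.ndarray,
    config: QuantificationConfig | None = None,
) -> DefectClassification:
    """Threshold the maps into the four-category defect partition.

    Valid voxels are mask voxels with data in both the ventilation and
    perfusion maps (and the FVL map in ``fvl`` mode); no-data voxels are
    excluded from all denominators.
    """
    cfg = config or QuantificationConfig()
    cfg.validate()
    mask = np.asarray(mask, dtype=bool)
    for m in (vent_map, perf_map) + ((fvl_map,) if cfg.vdp_mode == "fvl" else ()):
        if m.values.shape != mask.shape:
            raise ValueError("maps misaligned with the lung mask")

    valid = mask & np.isfinite(vent_map.values) & np.isfinite(perf_map.values)
    if not valid.any():
        raise ValueError("empty valid lung mask: no voxel carries data in "
                         "all required maps")
    if cfg.vdp_mode == "fvl":
        if fvl_map is None:
            raise ValueError("fvl mode requires an FVL correlation map")
        valid &= np.isfinite(fvl_map.values)
        vent_thresh = cfg.fvl_defect_threshold
        vent_defect = valid & (fvl_map.values < vent_thresh)
    else:
        rv_valid = vent_map.values[mask & np.isfinite(vent_map.values)]
        p90 = float(np.percentile(rv_valid, 90, method="linear"))
        vent_thresh = cfg.vent_defect_fraction * p90
        vent_defect = valid & (vent_map.values < vent_thresh)

    perf_defect = valid & (perf_map.values < cfg.perfusion_defect_threshold)

    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[valid] = CATEGORY_CODES["vqm_nondefect"]
    labels[vent_defect & ~perf_defect] = CATEGORY_CODES["vent_defect_only"]
    labels[perf_defect & ~vent_defect] = CATEGORY_CODES["perf_defect_only"]
    labels[vent_defect & perf_defect] = CATEGORY_CODES["vq_defect"]
    return DefectClassification(
        labels=labels,
        valid_mask=valid,
        vent_defect=vent_defect,
        perf_defect=perf_defect,
        vent_threshold_used=float(vent_thresh),
        perf_threshold_used=cfg.perfusion_defect_threshold,
        mode=cfg.vdp_mode,
    )


def compute_metrics(
    classification: DefectClassification,
    vent_map: QuantitativeMap,
    perf_map: QuantitativeMap,
    identifier: str = "",
) -> MetricsReport:
    """Category percentages of valid lung area plus mean V and Q.

    The partition identity holds exactly: exclusive-V + exclusive-Q +
    combined + match = 100 %, VDP = exclusive-V + combined, QDP =
    exclusive-Q + combined.
    """
    valid = classification.valid_mask
    n = int(valid.sum())
    if n == 0:
        raise ValueError("empty valid lung mask")

    def pct(category: str) -> float:
        return 100.0 * int(classification.category_mask(category).sum()) / n

    v_only = pct("vent_defect_only")
    q_only = pct("perf_defect_only")
    vq = pct("vq_defect")
    match = pct("vqm_nondefect")
    return MetricsReport(
        mean_ventilation=float(np.mean(vent_map.values[valid])),
        mean_perfusion=float(np.mean(perf_map.values[valid])),
        vdp=v_only + vq,
        qdp=q_only + vq,
        vqm_defect=vq,
        vqm_nondefect=match,
        vent_defect_only_pct=v_only,
        perf_defect_only_pct=q_only,
        valid_area_voxels=n,
        thresholds={
            "ventilation": classification.vent_threshold_used,
            "perfusion": classification.perf_threshold_used,
            "mode": classification.mode,
            "field_strength_note": (
                "defect thresholds calibrated at 1.5 T; interpret with care "
                "at other field strengths"
            ),
        },
        identifier=identifier,
    )


def stratify_by_vc(vc_percent: float) -> SeverityStratum:
    """Severity stratum from vital capacity in % predicted.

    mild: VC >= 88; moderate: 58 <= VC < 88; severe: VC < 58 (continuous
    closure of the printed integer bins 100-88 / 87-58 / 57-0); VC above
    100 is mild.
    """
    if vc_percent < 0:
        raise ValueError("VC %predicted cannot be negative")
    if vc_percent >= 88:
        return SeverityStratum("mild", 88.0, np.inf)
    if vc_percent >= 58:
        return SeverityStratum("moderate", 58.0, 88.0)
    return SeverityStratum("severe", 0.0, 58.0)
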