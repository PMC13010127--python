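"""End-to-end orchestration: series in, maps and metrics report out.

Stage order: respiratory signal on a coarse mask -> mid-expiration
reference selection -> nonrigid registration -> lung segmentation (or a
user-supplied mask) -> respiratory-cycle reconstruction and ventilation
map -> cardiac amplitude map, full-blood region, cardiac phase and cycle,
perfusion map -> healthy reference region and FVL correlation map ->
defect classification and lung-level metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import core, motion, segmentation
from .io import ImageSeries, RunConfig, write_map, write_mask, write_report
from .quantify import (
    DefectClassification,
    MetricsReport,
    QuantificationConfig,
    classify_defects,
    compute_metrics,
)

logger = logging.getLogger("preful")

__all__ = ["PipelineResult", "StageError", "run_pipeline", "save_result"]


class StageError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    registered: motion.RegisteredSeries
    resp_signal: motion.RespiratorySignal
    lungs: segmentation.LungMask
    blood_region: np.ndarray
    vent_map: core.QuantitativeMap
    perf_map: core.QuantitativeMap
    perf_map_full: core.QuantitativeMap  # includes the blood reference region
    fvl_map: core.QuantitativeMap
    classification: DefectClassification
    classification_fvl: DefectClassification
    report: MetricsReport
    report_fvl: MetricsReport
    cardiac_freq_hz: float
    mid_frame: int
    mid_bin: int
    config: RunConfig


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(
    series: ImageSeries,
    config: RunConfig | None = None,
    user_lung_mask: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full analysis on a dynamic 2D+t series."""
    cfg = config or RunConfig()
    qcfg = QuantificationConfig(
        perfusion_defect_threshold=cfg.perfusion_defect_threshold,
        vent_defect_fraction=cfg.vent_defect_fraction,
        fvl_defect_threshold=cfg.fvl_defect_threshold,
        vdp_mode="regional_ventilation",
    )
    logger.info(
        "config: thresholds Q<%g%%, RV<%g*P90, FVL<%g; bands lowpass %g Hz, "
        "cardiac %s Hz; n_bins=%d; seed=%d",
        cfg.perfusion_defect_threshold, cfg.vent_defect_fraction,
        cfg.fvl_defect_threshold, cfg.resp_lowpass_hz,
        cfg.cardiac_band_hz, cfg.n_bins, cfg.seed,
    )

    @_stage("motion")
    def do_motion():
        coarse = motion.coarse_body_mask(series)
        resp = motion.extract_respiratory_signal(series, coarse, cfg.resp_lowpass_hz)
        mid = motion.select_mid_expiration_frame(resp)
        guidance = motion.lowpass_frames(series, cfg.resp_lowpass_hz)
        registered = motion.register_series(
            series, mid, cfg, keep_fields=False, guidance_frames=guidance
        )
        return resp, mid, registered

    resp, mid_frame, registered = do_motion()
    logger.info("motion: %d breaths, mid-expiration frame %d",
                resp.end_expiration_peaks.size, mid_frame)

    @_stage("segmentation")
    def do_segmentation():
        mean_img = registered.frames.mean(axis=0)
        if user_lung_mask is not None:
            return segmentation.validate_user_mask(
                user_lung_mask, series.shape, series.pixel_spacing_mm
            )
        return segmentation.segment_lungs(mean_img, series.pixel_spacing_mm)

    lungs = do_segmentation()
    logger.info("segmentation: %d lung voxels in %d components",
                lungs.area_voxels, lungs.n_components)

    @_stage("preful_core")
    def do_core():
        resp_cycle = core.reconstruct_cycle(
            registered, resp.phase, lungs.mask, cfg.n_bins
        )
        mid_bin = core.select_mid_bin(resp_cycle)
        vent_map = core.compute_ventilation_map(resp_cycle, mid_bin)

        amp = core.cardiac_band_amplitude(registered, cfg.cardiac_band_hz)
        blood = segmentation.find_full_blood_region(amp, lungs)
        card_phase, f_card = core.extract_cardiac_phase(
            registered, blood, cfg.cardiac_band_hz
        )
        card_mask = lungs.mask | blood
        card_src = core.cardiac_filtered_series(registered, cfg.cardiac_band_hz)
        card_cycle = core.reconstruct_cycle(
            card_src, card_phase, card_mask, cfg.n_bins
        )
        perf_map_full = core.compute_perfusion_map(card_cycle, blood)
        perf_map = core.QuantitativeMap(
            values=np.where(lungs.mask, perf_map_full.values, np.nan),
            kind="perfusion_pct",
            mask=lungs.mask,
        )
        ref_region = core.healthy_reference_region(vent_map)
        fvl_map = core.compute_fvl_correlation_map(resp_cycle, ref_region)
        return vent_map, perf_map, perf_map_full, fvl_map, blood, f_card, mid_bin

    vent_map, perf_map, perf_map_full, fvl_map, blood, f_card, mid_bin = do_core()
    logger.info("core: cardiac %.3f Hz, mid bin %d", f_card, mid_bin)

    @_stage("quantification")
    def do_quant():
        cls_rv = classify_defects(vent_map, perf_map, fvl_map, lungs.mask, qcfg)
        rep_rv = compute_metrics(cls_rv, vent_map, perf_map, series.identifier)
        qcfg_fvl = QuantificationConfig(
            perfusion_defect_threshold=cfg.perfusion_defect_threshold,
            vent_defect_fraction=cfg.vent_defect_fraction,
            fvl_defect_threshold=cfg.fvl_defect_threshold,
            vdp_mode="fvl",
        )
        cls_fvl = classify_defects(vent_map, perf_map, fvl_map, lungs.mask, qcfg_fvl)
        rep_fvl = compute_metrics(cls_fvl, vent_map, perf_map,
                                  f"{series.identifier}:fvl")
        return cls_rv, rep_rv, cls_fvl, rep_fvl

    cls_rv, rep_rv, cls_fvl, rep_fvl = do_quant()
    logger.info("metrics: V=%.2f%% Q=%.2f%% VDP=%.2f%% QDP=%.2f%%",
                rep_rv.mean_ventilation, rep_rv.mean_perfusion,
                rep_rv.vdp, rep_rv.qdp)

    return PipelineResult(
        registered=registered,
        resp_signal=resp,
        lungs=lungs,
        blood_region=blood,
        vent_map=vent_map,
        perf_map=perf_map,
        perf_map_full=perf_map_full,
        fvl_map=fvl_map,
        classification=cls_rv,
        classification_fvl=cls_fvl,
        report=rep_rv,
        report_fvl=rep_fvl,
        cardiac_freq_hz=f_card,
        mid_frame=mid_frame,
        mid_bin=mid_bin,
        config=cfg,
    )


def save_result(result: PipelineResult, out_dir: str | Path,
                series: ImageSeries) -> dict[str, str]:
    """Write maps, masks, classification and the report; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = series.pixel_spacing_mm
    paths = {
        "lung_mask": str(write_mask(result.lungs.mask, out / "lung_mask.nii.gz", sp)),
        "blood_region": str(write_mask(result.blood_region,
                                       out / "blood_region.nii.gz", sp)),
        "ventilation_map": str(write_map(result.vent_map.values,
                                         out / "ventilation_pct.nii.gz", sp)),
        "perfusion_map": str(write_map(result.perf_map.values,
                                       out / "perfusion_pct.nii.gz", sp)),
        "fvl_map": str(write_map(result.fvl_map.values,
                                 out / "fvl_correlation.nii.gz", sp)),
        "defect_labels": str(write_map(result.classification.labels.astype(float),
                                       out / "defect_categories.nii.gz", sp)),
    }
    report_csv = out / "report.csv"
    write_report([result.report.to_row(), result.report_fvl.to_row()], report_csv)
    paths["report"] = str(report_csv)

    from .plots import save_map_panel, save_mask_overlay

    paths["qc_masks"] = str(save_mask_overlay(
        result.registered.frames.mean(axis=0), result.lungs.mask,
        result.blood_region, out / "qc_masks.png",
    ))
    paths["qc_maps"] = str(save_map_panel(result, out / "qc_maps.png"))

    cfg_digest = hashlib.sha256(
        json.dumps(asdict(result.config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    meta = {
        "identifier": series.identifier,
        "config": asdict(result.config),
        "config_hash": cfg_digest,
        "mid_expiration_frame": result.mid_frame,
        "mid_bin": result.mid_bin,
        "cardiac_freq_hz": result.cardiac_freq_hz,
        "report": result.report.to_dict(),
        "report_fvl": result.report_fvl.to_dict(),
    }
    (out / "run.json").write_text(json.dumps(meta, indent=2, default=float))
    paths["run_meta"] = str(out / "run.json")
    return paths
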