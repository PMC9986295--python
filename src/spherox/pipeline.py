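"""End-to-end composition: stack + calibration pair -> series + metrics.

Deterministic given the configuration; every stage's parameters are echoed
into the run log, and stage failures propagate with the stage name.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sxio
from .calibration import fit_two_point
from .segmentation import build_roi_masks, correct_illumination, detect_cavities
from .stresstest import (
    StressTestResult, gradient_series, label_phases, phase_plateaus,
    respiration_metrics,
)
from .synth import PhaseSchedule, SynthStack
from .timeseries import extract_series, normalize_terminal
from .geometry import ArrayGeometry

__all__ = ["RunConfig", "run_pipeline", "analyze_stack"]

log = logging.getLogger("spherox")


@dataclass
class RunConfig:
    """Paths and parameters of one analysis run."""

    stack_path: str
    calib_0pct_path: str
    calib_100pct_path: str
    output_dir: str
    geometry: ArrayGeometry
    schedule: PhaseSchedule
    calibration_form: str = "stern_volmer"
    n_last: int = 10
    norm_reference: float = 100.0
    k_last: int = 5
    seed: int = 0


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def analyze_stack(
    stack: SynthStack,
    calib_pair,
    geometry: ArrayGeometry,
    schedule: PhaseSchedule,
    calibration_form: str = "stern_volmer",
    n_last: int = 10,
    norm_reference: float = 100.0,
    k_last: int = 5,
):
    """Library-level pipeline on in-memory objects.

    Returns (series, plateaus, StressTestResult, gradients, rois, model).
    """
    img0, img100 = calib_pair
    model = _stage("calibrate")(fit_two_point)(
        img0, img100, form=calibration_form
    )
    log.info("calibrate: R0=%.6g R100=%.6g form=%s", model.R0, model.R100,
             model.form)

    green0 = stack.frames[0, 1]
    corrected = _stage("segment")(correct_illumination)(green0)
    centers = _stage("segment")(detect_cavities)(corrected, geometry)
    rois = _stage("segment")(build_roi_masks)(
        centers, geometry, image_shape=green0.shape
    )
    log.info("segment: %d cavities", len(rois.ids))

    series = _stage("extract")(extract_series)(stack, rois, model)
    series = _stage("normalize")(normalize_terminal)(
        series, model, n_last=n_last, reference=norm_reference
    )
    labeled = _stage("stresstest")(label_phases)(series, schedule)
    plateaus = _stage("stresstest")(phase_plateaus)(labeled, k_last=k_last)
    result = _stage("stresstest")(respiration_metrics)(plateaus)
    gradients = _stage("stresstest")(gradient_series)(labeled)
    return labeled, plateaus, result, gradients, rois, model


def run_pipeline(config: RunConfig) -> StressTestResult:
    """File-to-file pipeline; writes series CSV, plateau CSV, JSON summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("run start %s seed=%d",
                 datetime.datetime.now().isoformat(), config.seed)
        for p, stage in [
            (config.calib_0pct_path, "calibrate"),
            (config.calib_100pct_path, "calibrate"),
            (config.stack_path, "read"),
        ]:
            if not Path(p).exists():
                raise RuntimeError(f"stage {stage!r} failed: missing {p}")
        img0 = sxio.read_stack(config.calib_0pct_path).frames[0]
        img100 = sxio.read_stack(config.calib_100pct_path).frames[0]
        stack = sxio.read_stack(
            config.stack_path,
            frame_interval_min=config.schedule.frame_interval_min,
        )
        labeled, plateaus, result, gradients, rois, model = analyze_stack(
            stack, (img0, img100), config.geometry, config.schedule,
            calibration_form=config.calibration_form,
            n_last=config.n_last, norm_reference=config.norm_reference,
            k_last=config.k_last,
        )
        sxio.write_json(out / "calibration.json", model.to_dict())
        sxio.write_series_csv(out / "series.csv", labeled, seed=config.seed)
        sxio.write_series_csv(out / "plateaus.csv", plateaus, seed=config.seed)
        sxio.write_series_csv(out / "gradients.csv", gradients,
                              seed=config.seed)
        sxio.write_series_csv(out / "indices.csv", result.indices,
                              seed=config.seed)
        summary = result.to_dict()
        summary["seed"] = config.seed
        sxio.write_json(out / "summary.json", summary)
        log.info("run done: %d cavities, %d records",
                 len(rois.ids), len(labeled))
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
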