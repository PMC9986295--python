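"""Shared fixtures: small (4x4) scenarios for unit tests, and the full
default 8x8 stress-test run reused by the end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

import spherox as sx


@pytest.fixture(scope="session")
def small_scenario():
    """4x4 noise-free default scenario (cheap unit-test workhorse)."""
    return sx.default_scenario(noise_free=True, n_rows=4, n_cols=4)


@pytest.fixture(scope="session")
def small_stack(small_scenario):
    geo, sched, truth = small_scenario
    return sx.render_stack(geo, sched, truth, seed=7)


@pytest.fixture(scope="session")
def small_calib_pair(small_scenario):
    geo, _, truth = small_scenario
    return sx.render_calibration_pair(truth, geo, seed=7)


@pytest.fixture(scope="session")
def small_model(small_calib_pair):
    img0, img100 = small_calib_pair
    return sx.fit_two_point(img0, img100)


@pytest.fixture(scope="session")
def small_rois(small_scenario, small_stack):
    geo, _, _ = small_scenario
    green = small_stack.frames[0, 1]
    centers = sx.detect_cavities(sx.correct_illumination(green), geo)
    return sx.build_roi_masks(centers, geo, image_shape=green.shape)


@pytest.fixture(scope="session")
def default_model():
    """Exact two-point model with the generator's default anchors."""
    return sx.CalibrationModel(R0=2.0, R100=1.0)


@pytest.fixture(scope="session")
def full_run():
    """Full default 8x8 stochastic scenario (seed 1) through the pipeline.

    The acceptance scenario: noise sigma 0.02, jitter <= 3 px, red
    exposure gain on.  Returns a dict with every intermediate product.
    """
    geo, sched, truth = sx.default_scenario()
    img0, img100 = sx.render_calibration_pair(truth, geo, seed=2)
    stack = sx.render_stack(geo, sched, truth, seed=1)
    labeled, plateaus, result, gradients, rois, model = sx.analyze_stack(
        stack, (img0, img100), geo, sched
    )
    return {
        "geometry": geo, "schedule": sched, "truth": truth,
        "stack": stack, "model": model, "rois": rois,
        "series": labeled, "plateaus": plateaus, "result": result,
        "gradients": gradients,
    }


@pytest.fixture(scope="session")
def full_noise_free_image():
    """One noise-free two-channel frame of the full 8x8 array."""
    geo, _, truth = sx.default_scenario(noise_free=True)
    img0, img100 = sx.render_calibration_pair(truth, geo, seed=3)
    return geo, img100


def roi_pixel_counts(rois: sx.CavityROISet) -> dict:
    """Pixel count per (cavity, roi) — brute-force oracle helper."""
    out = {}
    for cav, roi, lab in rois.iter_rois():
        out[(cav, roi)] = int(np.sum(rois.label_image == lab))
    return out
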