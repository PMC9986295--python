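"""Registration, per-ROI extraction, terminal normalization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import spherox as sx
from spherox.synth import SynthStack
from spherox.segmentation import CavityROISet


class TestRegisterFrame:
    def test_recovers_injected_jitter_exactly(self, small_scenario):
        geo, sched, truth = small_scenario
        truth = dataclasses.replace(truth, jitter_max_px=3)
        stack = sx.render_stack(geo, sched, truth, seed=21)
        ref = stack.frames[0, 1]
        for i in (1, 10, 40, 75):
            dy, dx = sx.register_frame(stack.frames[i, 1], ref)
            row = stack.offsets.iloc[i]
            assert (dy, dx) == (row["dy"], row["dx"])

    def test_identity_offset(self, small_stack):
        g = small_stack.frames[0, 1]
        assert sx.register_frame(g, g) == (0, 0)

    def test_uniform_image_ambiguous(self):
        img = np.full((64, 64), 5.0)
        with pytest.raises(ValueError, match="ambiguous"):
            sx.register_frame(img, img)

    def test_specific_shift_recovered(self, small_stack):
        g = small_stack.frames[0, 1]
        shifted = np.roll(g, (3, -2), axis=(0, 1))
        assert sx.register_frame(shifted, g) == (3, -2)


class TestExtractSeries:
    def test_registration_restores_unjittered_means(self, small_scenario,
                                                    default_model):
        """ROI means after registering a jittered noise-free stack equal
        those of the unjittered stack (paired runs, same seed)."""
        geo, sched, truth = small_scenario
        jittered = dataclasses.replace(truth, jitter_max_px=3)
        s0 = sx.render_stack(geo, sched, truth, seed=21)
        s1 = sx.render_stack(geo, sched, jittered, seed=21)
        centers = sx.detect_cavities(
            sx.correct_illumination(s0.frames[0, 1]), geo
        )
        rois = sx.build_roi_masks(centers, geo)
        a = sx.extract_series(s0, rois, default_model, register=False)
        b = sx.extract_series(s1, rois, default_model, register=True)
        for col in ("mean_red", "mean_green", "ratio", "oxygen_raw"):
            np.testing.assert_allclose(a[col], b[col], rtol=1e-6)

    def test_hand_built_four_pixel_mask(self, default_model):
        """Means over a tiny hand-built mask equal scripted arithmetic."""
        red = np.zeros((1, 2, 8, 8))
        red[0, 0, 2, 2], red[0, 0, 2, 3] = 10.0, 12.0
        red[0, 0, 3, 2], red[0, 0, 3, 3] = 14.0, 16.0
        red[0, 1] = 8.0  # green uniform
        red[0, 0, 5, 5] = 9.0
        red[0, 0, 5, 6] = 11.0
        label = np.zeros((8, 8), dtype=np.int16)
        label[2:4, 2:4] = 1  # spheroid ROI of cavity (0, 0)
        label[5, 5] = 2      # minimal wall / chamfer pixels
        label[5, 6] = 3
        rois = CavityROISet(
            ids=[(0, 0)], centers=np.array([[2.5, 2.5]]), label_image=label
        )
        stack = SynthStack(
            frames=red, times_min=np.array([0.0]),
            ground_truth=pd.DataFrame(), offsets=pd.DataFrame(),
        )
        series = sx.extract_series(stack, rois, default_model, register=False)
        sph = series[series["roi"] == "spheroid"].iloc[0]
        assert sph["mean_red"] == pytest.approx((10 + 12 + 14 + 16) / 4)
        assert sph["mean_green"] == pytest.approx(8.0)
        assert sph["ratio"] == pytest.approx(13.0 / 8.0)
        wall = series[series["roi"] == "wall"].iloc[0]
        assert wall["mean_red"] == pytest.approx(9.0)

    def test_empty_mask_rejected(self, default_model):
        label = np.zeros((8, 8), dtype=np.int16)
        rois = CavityROISet(
            ids=[(0, 0)], centers=np.array([[4.0, 4.0]]), label_image=label
        )
        stack = SynthStack(
            frames=np.ones((1, 2, 8, 8)), times_min=np.array([0.0]),
            ground_truth=pd.DataFrame(), offsets=pd.DataFrame(),
        )
        with pytest.raises(ValueError, match="empty ROI mask"):
            sx.extract_series(stack, rois, default_model)

    def test_uniform_saturation_extracts_100(self, default_model):
        from spherox.synth import PHASE_ORDER, ROI_CLASSES
        geo, sched, truth = sx.default_scenario(noise_free=True, n_rows=2,
                                                n_cols=2)
        truth = dataclasses.replace(
            truth,
            targets={p: {r: 100.0 for r in ROI_CLASSES} for p in PHASE_ORDER},
        )
        stack = sx.render_stack(geo, sched, truth, seed=0)
        rois = sx.build_roi_masks(geo.centers_px(), geo)
        series = sx.extract_series(stack, rois, default_model, register=False)
        np.testing.assert_allclose(series["oxygen_raw"], 100.0, atol=1e-6)

    def test_noise_free_control_plateau_raw(self, small_scenario, small_stack,
                                            small_rois, small_model):
        """Raw (un-normalized) chamfer oxygen levels off at 25 %a.s. late in
        the control phase."""
        _, sched, _ = small_scenario
        series = sx.extract_series(small_stack, small_rois, small_model)
        labeled = sx.label_phases(series, sched)
        ctrl = labeled.query("phase == 'control' and roi == 'chamfer'")
        tail = ctrl[ctrl["frame"] >= ctrl["frame"].max() - 4]
        assert tail["oxygen_raw"].mean() == pytest.approx(25.0, abs=0.1)


class TestNormalizeTerminal:
    model = sx.CalibrationModel(R0=2.0, R100=1.0)

    def _series(self, values):
        values = np.asarray(values, dtype=float)
        n = len(values)
        return pd.DataFrame({
            "frame": np.arange(n), "time_min": 2.0 * np.arange(n),
            "row": 0, "col": 0, "roi": "spheroid",
            "ratio": self.model.oxygen_to_ratio(values),
            "oxygen_raw": values,
        })

    def test_unit_factor_when_terminal_already_at_reference(self):
        s = self._series(np.r_[np.linspace(20, 90, 20), np.full(10, 100.0)])
        out = sx.normalize_terminal(s, self.model)
        np.testing.assert_allclose(out["oxygen_norm"], out["oxygen_raw"],
                                   atol=1e-9)

    def test_gain_corrected_terminal_mean(self, small_scenario, small_rois,
                                          small_model):
        """A x0.9 red exposure gain leaves the raw terminal mean off 100
        but the normalized terminal mean at exactly 100."""
        geo, sched, truth = small_scenario
        truth = dataclasses.replace(truth, red_gain=0.9)
        stack = sx.render_stack(geo, sched, truth, seed=3)
        series = sx.extract_series(stack, small_rois, small_model,
                                   register=False)
        out = sx.normalize_terminal(series, small_model)
        last = out[out["frame"] >= out["frame"].max() - 9]
        g = last.groupby(["row", "col", "roi"])
        raw_term = g["oxygen_raw"].mean()
        norm_term = g["oxygen_norm"].mean()
        assert np.abs(raw_term - 100.0).min() > 1.0
        np.testing.assert_allclose(norm_term, 100.0, atol=1e-6)

    def test_idempotent(self):
        s = self._series(np.r_[np.linspace(30, 80, 30), np.full(10, 90.0)])
        once = sx.normalize_terminal(s, self.model)
        twice = sx.normalize_terminal(once, self.model)
        np.testing.assert_allclose(twice["oxygen_norm"], once["oxygen_norm"],
                                   atol=1e-9)

    def test_uses_last_10_frames(self):
        # 76-frame curve: only frames 66..75 (the last 10) set the factor
        vals = np.full(76, 50.0)
        vals[-10:] = 80.0
        out = sx.normalize_terminal(self._series(vals), self.model)
        # closed-form oracle: exposure scale maps the 80-plateau ratio onto
        # the saturation ratio, then the head of the curve converts through
        # the calibration at the scaled ratio
        s = self.model.oxygen_to_ratio(100.0) / self.model.oxygen_to_ratio(80.0)
        expected = self.model.ratio_to_oxygen(
            self.model.oxygen_to_ratio(50.0) * s
        )
        assert out["oxygen_norm"].iloc[0] == pytest.approx(expected, abs=1e-9)
        tail = out[out["frame"] >= 66]
        assert tail["oxygen_norm"].mean() == pytest.approx(100.0, abs=1e-9)

    def test_red_scale_invariance(self, small_scenario, small_stack,
                                  small_rois, small_model):
        """Scaling every red intensity by a constant changes oxygen_raw but
        leaves oxygen_norm unchanged."""
        geo, sched, _ = small_scenario
        scaled = SynthStack(
            frames=small_stack.frames.copy(),
            times_min=small_stack.times_min,
            ground_truth=small_stack.ground_truth,
            offsets=small_stack.offsets,
        )
        scaled.frames[:, 0] *= 0.93
        a = sx.normalize_terminal(
            sx.extract_series(small_stack, small_rois, small_model,
                              register=False), small_model)
        b = sx.normalize_terminal(
            sx.extract_series(scaled, small_rois, small_model,
                              register=False), small_model)
        assert not np.allclose(a["oxygen_raw"], b["oxygen_raw"], atol=0.5)
        np.testing.assert_allclose(a["oxygen_norm"], b["oxygen_norm"],
                                   rtol=1e-6)

    def test_errors(self):
        s = self._series(np.full(5, 50.0))
        with pytest.raises(ValueError, match="exceeds series length"):
            sx.normalize_terminal(s, self.model, n_last=10)
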