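"""Synthetic two-channel sensor images with exact per-ROI ground truth.

Renders the microcavity array as seen by the ratiometric imager: a green
reference channel carrying only geometry, illumination and noise, and a red
sensor channel whose per-pixel ratio to green encodes oxygen through the
inverse calibration.  Every downstream stage (calibration, segmentation,
extraction, stress-test metrics) is testable against the returned ground
truth without any acquired data.

The mitochondrial stress-test scenario follows the five-phase protocol —
basal, medium control, oligomycin, FCCP, rotenone+antimycin A, 30 min each
at 2-min frames — with phenomenological first-order oxygen kinetics toward
per-phase, per-ROI targets.  Imaging artefacts emulated: additive Gaussian
pixel noise per channel, a shared radial-vignette illumination field, a
red-only exposure-gain factor (what terminal normalization corrects), and
integer-pixel frame jitter (what registration corrects).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import CalibrationModel
from .geometry import ArrayGeometry

__all__ = [
    "Phase",
    "PhaseSchedule",
    "ScenarioTruth",
    "default_scenario",
    "render_calibration_pair",
    "render_stack",
    "SynthStack",
]

PHASE_ORDER = ("basal", "control", "oligomycin", "fccp", "rot_aa")
ROI_CLASSES = ("spheroid", "wall", "chamfer")

#: Intensity of the green reference channel on flat film, camera counts.
BASE_GREEN = 10000.0
#: Full scale of the 16-bit camera; noise_sigma is a fraction of BASE_GREEN.
FULL_SCALE = 65535.0


@dataclass(frozen=True)
class Phase:
    name: str
    start_min: float
    duration_min: float


@dataclass(frozen=True)
class PhaseSchedule:
    """Contiguous modulator phases sampled at a fixed frame cadence."""

    phases: tuple[Phase, ...]
    frame_interval_min: float = 2.0

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        names = [p.name for p in self.phases]
        allowed = [n for n in PHASE_ORDER if n in names]
        if names != allowed:
            raise ValueError(
                f"phases must appear in canonical order {PHASE_ORDER}, "
                f"got {names}"
            )
        t = self.phases[0].start_min
        for p in self.phases:
            if p.start_min != t:
                raise ValueError("phases must be contiguous, non-overlapping")
            if p.duration_min <= 0:
                raise ValueError("phase durations must be > 0")
            n = p.duration_min / self.frame_interval_min
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    "frame interval must divide every phase duration"
                )
            t += p.duration_min

    @property
    def start_min(self) -> float:
        return self.phases[0].start_min

    @property
    def end_min(self) -> float:
        last = self.phases[-1]
        return last.start_min + last.duration_min

    @property
    def total_duration_min(self) -> float:
        return self.end_min - self.start_min

    def frame_times(self) -> np.ndarray:
        """Sample times in minutes, inclusive of both endpoints."""
        n = int(round(self.total_duration_min / self.frame_interval_min))
        return self.start_min + self.frame_interval_min * np.arange(n + 1)

    def phase_of(self, t_min: float) -> str:
        """Phase containing time ``t_min``.

        Intervals are half-open [start, start+duration); the final phase is
        closed at its right endpoint so the last frame is covered.
        """
        for i, p in enumerate(self.phases):
            hi = p.start_min + p.duration_min
            if p.start_min <= t_min < hi:
                return p.name
            if i == len(self.phases) - 1 and t_min == hi:
                return p.name
        raise ValueError(f"time {t_min} min is outside the schedule")


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground-truth oxygen dynamics and imaging-artefact parameters.

    ``targets[phase][roi]`` is the asymptotic oxygen level (%a.s.) the ROI
    approaches during that phase with first-order time constant
    ``tau_min``; the approach starts from the previous phase's final level
    (continuity).  ``initial[roi]`` seeds the very first phase.
    """

    targets: dict  # phase name -> {roi class -> %a.s.}
    initial: dict = field(
        default_factory=lambda: {r: 100.0 for r in ROI_CLASSES}
    )
    background_oxygen: float = 100.0
    tau_min: float = 2.0
    noise_sigma: float = 0.02
    jitter_max_px: int = 3
    red_gain: float | tuple = 0.98
    vignette_strength: float = 0.15
    R0: float = 2.0
    R100: float = 1.0

    def __post_init__(self) -> None:
        if not (self.R0 > self.R100 > 0):
            raise ValueError("require R0 > R100 > 0")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be > 0")
        if self.noise_sigma < 0 or self.jitter_max_px < 0:
            raise ValueError("noise_sigma and jitter_max_px must be >= 0")
        for phase, rois in self.targets.items():
            for roi, level in rois.items():
                if not (0.0 <= level <= 150.0):
                    raise ValueError(
                        f"target {phase}/{roi} = {level} outside [0, 150]"
                    )

    @property
    def calibration(self) -> CalibrationModel:
        """The generator-side transfer function (Stern-Volmer)."""
        return CalibrationModel(R0=self.R0, R100=self.R100)

    def red_gain_series(self, n_frames: int) -> np.ndarray:
        g = np.asarray(self.red_gain, dtype=float)
        if g.ndim == 0:
            return np.full(n_frames, float(g))
        if g.size != n_frames:
            raise ValueError(
                f"red_gain sequence length {g.size} != frame count {n_frames}"
            )
        return g.copy()


def default_scenario(
    noise_free: bool = False,
    n_rows: int = 8,
    n_cols: int = 8,
) -> tuple[ArrayGeometry, PhaseSchedule, ScenarioTruth]:
    """Canonical stress-test configuration.

    8 x 8 cavities (300 um inner, 500 um bevel-outer diameter, 1 mm pitch,
    10 um/px), five 30-min phases at 2-min frames, control-phase plateaus
    25 %a.s. (chamfer) / 20 %a.s. (spheroid), oligomycin 75/72, FCCP 18/10,
    full inhibition 100/100.  ``noise_free=True`` switches off pixel noise,
    jitter and the red exposure gain (the vignette stays on — it cancels in
    the ratio).
    """
    geometry = ArrayGeometry(n_rows=n_rows, n_cols=n_cols)
    phases = tuple(
        Phase(name, start_min=30.0 * i, duration_min=30.0)
        for i, name in enumerate(PHASE_ORDER)
    )
    schedule = PhaseSchedule(phases=phases, frame_interval_min=2.0)

    def _levels(spheroid: float, chamfer: float) -> dict:
        return {
            "spheroid": spheroid,
            "wall": (spheroid + chamfer) / 2,
            "chamfer": chamfer,
        }

    targets = {
        "basal": _levels(20.0, 25.0),
        "control": _levels(20.0, 25.0),
        "oligomycin": _levels(72.0, 75.0),
        "fccp": _levels(10.0, 18.0),
        "rot_aa": _levels(100.0, 100.0),
    }
    truth = ScenarioTruth(targets=targets)
    if noise_free:
        truth = replace(truth, noise_sigma=0.0, jitter_max_px=0, red_gain=1.0)
    return geometry, schedule, truth


# ---------------------------------------------------------------------------
# rendering


def _roi_class_map(geometry: ArrayGeometry) -> np.ndarray:
    """int8 map: 0 background, 1 spheroid, 2 wall, 3 chamfer."""
    h, w = geometry.image_shape
    out = np.zeros((h, w), dtype=np.int8)
    yy, xx = np.mgrid[0:h, 0:w]
    r_sph = geometry.spheroid_radius_px
    r_in = geometry.inner_radius_px
    r_out = geometry.bevel_outer_radius_px
    for cy, cx in geometry.centers_px():
        y0, y1 = int(cy - r_out) - 1, int(cy + r_out) + 2
        x0, x1 = int(cx - r_out) - 1, int(cx + r_out) + 2
        d = np.hypot(yy[y0:y1, x0:x1] - cy, xx[y0:y1, x0:x1] - cx)
        sub = out[y0:y1, x0:x1]
        sub[d < r_out] = 3
        sub[d < r_in] = 2
        sub[d < r_sph] = 1
    return out


def _structure_map(geometry: ArrayGeometry, class_map: np.ndarray) -> np.ndarray:
    """Relative green-channel brightness of the thermoformed film.

    The bevel appears bright (thinned, tilted film), the cavity wall dim,
    and the spheroid darker still with a gentle radial falloff — enough
    contrast for lattice detection without any cell-level rendering.
    """
    levels = np.array([1.0, 0.45, 0.65, 1.35])
    struct = levels[class_map]
    # mild radial texture on the spheroid disc
    h, w = class_map.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r_sph = geometry.spheroid_radius_px
    for cy, cx in geometry.centers_px():
        y0, y1 = int(cy - r_sph) - 1, int(cy + r_sph) + 2
        x0, x1 = int(cx - r_sph) - 1, int(cx + r_sph) + 2
        d = np.hypot(yy[y0:y1, x0:x1] - cy, xx[y0:y1, x0:x1] - cx)
        sub = struct[y0:y1, x0:x1]
        inside = d < r_sph
        sub[inside] *= 1.0 - 0.15 * (d[inside] / r_sph) ** 2
    return struct


def _vignette(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Smooth radial illumination gain, 1.0 at centre."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    r2 = ((yy - cy) / cy) ** 2 + ((xx - cx) / cx) ** 2
    return 1.0 - strength * r2 / 2.0


def _render_frame(
    green_base: np.ndarray,
    ratio_map: np.ndarray,
    red_gain: float,
    noise_sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-channel frame (2, H, W): red sensor, green reference."""
    green = green_base.copy()
    red = green_base * ratio_map * red_gain
    if noise_sigma > 0:
        sd = noise_sigma * BASE_GREEN
        red += rng.normal(0.0, sd, size=red.shape)
        green += rng.normal(0.0, sd, size=green.shape)
    return np.stack([red, green])


def render_calibration_pair(
    truth: ScenarioTruth,
    geometry: ArrayGeometry,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-point calibration images: sulfite (0 %a.s.) and air-saturated.

    Over the whole sensor film the red/green ratio has mean R0 (0% image)
    and R100 (100% image) up to pixel noise; the green channel is modulated
    only by the shared illumination field and the film structure.
    """
    rng = np.random.default_rng(seed)
    class_map = _roi_class_map(geometry)
    struct = _structure_map(geometry, class_map)
    green_base = BASE_GREEN * struct * _vignette(
        geometry.image_shape, truth.vignette_strength
    )
    flat0 = np.full(geometry.image_shape, truth.R0)
    flat100 = np.full(geometry.image_shape, truth.R100)
    img0 = _render_frame(green_base, flat0, 1.0, truth.noise_sigma, rng)
    img100 = _render_frame(green_base, flat100, 1.0, truth.noise_sigma, rng)
    return img0, img100


def _approach(start, target, dt, tau):
    return target + (start - target) * np.exp(-np.asarray(dt) / tau)


def _oxygen_trajectories(
    schedule: PhaseSchedule, truth: ScenarioTruth
) -> pd.DataFrame:
    """Per-frame, per-ROI-class true oxygen (%a.s.), continuous across phases."""
    times = schedule.frame_times()
    rows = []
    for roi in ROI_CLASSES:
        # level at the start of each phase: previous phase's endpoint
        start_levels = {}
        level = truth.initial[roi]
        for p in schedule.phases:
            start_levels[p.name] = level
            level = _approach(
                level, truth.targets[p.name][roi], p.duration_min,
                truth.tau_min,
            )
        vals = np.empty(len(times))
        for i, t in enumerate(times):
            name = schedule.phase_of(t)
            p = next(q for q in schedule.phases if q.name == name)
            vals[i] = _approach(
                start_levels[name], truth.targets[name][roi],
                t - p.start_min, truth.tau_min,
            )
        rows.append(
            pd.DataFrame({
                "frame": np.arange(len(times)),
                "time_min": times,
                "roi": roi,
                "oxygen_true": vals,
            })
        )
    return pd.concat(rows, ignore_index=True)


@dataclass
class SynthStack:
    """A rendered stack plus its ground truth.

    Attributes
    ----------
    frames : ndarray, shape (n_frames, 2, H, W)
        Channel 0 = red sensor, channel 1 = green reference (float64).
    times_min : ndarray
    ground_truth : DataFrame
        frame, time_min, phase, row, col, roi, oxygen_true — one record per
        frame x cavity x ROI class.
    offsets : DataFrame
        frame, dy, dx, red_gain — the injected jitter and exposure gain.
    """

    frames: np.ndarray
    times_min: np.ndarray
    ground_truth: pd.DataFrame
    offsets: pd.DataFrame

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def render_stack(
    geometry: ArrayGeometry,
    schedule: PhaseSchedule,
    truth: ScenarioTruth,
    seed: int,
) -> SynthStack:
    """Render the full stress-test time-lapse with ground truth.

    Per-ROI oxygen follows a first-order approach to each phase target;
    pixel ratios encode it through the inverse calibration; the red channel
    carries the per-frame exposure gain; each frame is rigidly translated
    by an integer jitter drawn uniformly from [-jitter_max_px,
    jitter_max_px] (frame 0 is unshifted).  Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(seed)
    model = truth.calibration
    times = schedule.frame_times()
    n_frames = len(times)

    class_map = _roi_class_map(geometry)
    struct = _structure_map(geometry, class_map)
    vign = _vignette(geometry.image_shape, truth.vignette_strength)
    green_base0 = BASE_GREEN * struct * vign  # foil coordinates

    traj = _oxygen_trajectories(schedule, truth)
    gains = truth.red_gain_series(n_frames)

    # jitter: frame 0 unshifted, others uniform integers
    j = truth.jitter_max_px
    offs = rng.integers(-j, j + 1, size=(n_frames, 2)) if j > 0 else np.zeros(
        (n_frames, 2), dtype=int
    )
    offs[0] = 0

    # per-frame ratio LUT indexed by ROI class (0 = background)
    traj_wide = traj.pivot(index="frame", columns="roi", values="oxygen_true")
    lut = np.empty((n_frames, 4))
    lut[:, 0] = model.oxygen_to_ratio(truth.background_oxygen)
    for k, roi in enumerate(ROI_CLASSES, start=1):
        lut[:, k] = model.oxygen_to_ratio(traj_wide[roi].to_numpy())

    frames = np.empty((n_frames, 2) + geometry.image_shape)
    for i in range(n_frames):
        dy, dx = offs[i]
        base = np.roll(green_base0, (dy, dx), axis=(0, 1))
        cmap = np.roll(class_map, (dy, dx), axis=(0, 1))
        ratio_map = lut[i][cmap]
        frames[i] = _render_frame(
            base, ratio_map, gains[i], truth.noise_sigma, rng
        )

    # ground truth per cavity (all cavities share the per-class dynamics)
    cav = pd.DataFrame(
        [(r, c) for r in range(geometry.n_rows) for c in range(geometry.n_cols)],
        columns=["row", "col"],
    )
    gt = traj.merge(cav, how="cross")
    gt["phase"] = [schedule.phase_of(t) for t in gt["time_min"]]
    gt = gt[["frame", "time_min", "phase", "row", "col", "roi", "oxygen_true"]]

    offsets = pd.DataFrame({
        "frame": np.arange(n_frames),
        "dy": offs[:, 0],
        "dx": offs[:, 1],
        "red_gain": gains,
    })
    return SynthStack(
        frames=frames, times_min=times, ground_truth=gt, offsets=offsets
    )
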