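"""Frame registration, per-ROI intensity extraction, and normalization.

Produces the long-format oxygen table: one record per frame x cavity x ROI
with mean red / mean green intensities, their ratio, calibrated oxygen
(``oxygen_raw``) and, after terminal normalization, ``oxygen_norm``.

Registration is integer-pixel rigid translation of each frame against the
first frame's green channel (cross-correlation peak); the acquisition
system does not correct small stage shifts, so this is done here.
Terminal normalization rescales every per-(cavity, ROI) curve so the mean
of its last ``n_last`` calibrated points equals the saturation reference —
after full respiratory inhibition the medium re-equilibrates with air, so
those points report a maximally saturated state and any residual offset is
exposure/gain error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import mean as ndi_mean

from .calibration import CalibrationModel
from .segmentation import CavityROISet
from .synth import SynthStack

__all__ = [
    "register_frame",
    "extract_series",
    "normalize_terminal",
    "SERIES_COLUMNS",
]

SERIES_COLUMNS = [
    "frame", "time_min", "row", "col", "roi",
    "mean_red", "mean_green", "ratio", "oxygen_raw",
    "offset_y", "offset_x",
]


def register_frame(
    frame_green: np.ndarray,
    reference_green: np.ndarray,
    max_shift: int = 10,
    margin: float = 1e-6,
) -> tuple[int, int]:
    """Integer translation (dy, dx) of ``frame_green`` vs the reference.

    The returned offset satisfies ``frame ~ roll(reference, (dy, dx))``;
    rolling the frame by ``(-dy, -dx)`` aligns it.  The peak of the
    circular cross-correlation is searched within ``+-max_shift``; a
    non-unique peak (within ``margin`` relative) raises ``ValueError``.
    """
    a = np.asarray(frame_green, dtype=float)
    b = np.asarray(reference_green, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frame and reference must have the same shape")
    fa = np.fft.rfft2(a - a.mean())
    fb = np.fft.rfft2(b - b.mean())
    corr = np.fft.irfft2(fa * np.conj(fb), s=a.shape)

    shifts = np.arange(-max_shift, max_shift + 1)
    window = corr[np.ix_(shifts, shifts)]  # negative indices wrap
    k = np.argmax(window)
    iy, ix = np.unravel_index(k, window.shape)
    best = window.flat[k]
    rest = window.copy()
    rest[iy, ix] = -np.inf
    second = rest.max()
    scale = max(abs(best), 1e-300)
    if (best - second) / scale <= margin:
        raise ValueError(
            "ambiguous registration: correlation peak is not unique "
            f"(best {best:.6g}, runner-up {second:.6g})"
        )
    return int(shifts[iy]), int(shifts[ix])


def _roi_means(channel: np.ndarray, label_image: np.ndarray,
               labels: np.ndarray) -> np.ndarray:
    return ndi_mean(channel, labels=label_image, index=labels)


def extract_series(
    stack: SynthStack,
    rois: CavityROISet,
    model: CalibrationModel,
    register: bool = True,
    max_shift: int = 10,
) -> pd.DataFrame:
    """Per-frame, per-cavity, per-ROI mean intensities and oxygen.

    Each frame is registered to the first frame's green channel (unless
    ``register=False``), then for every ROI mask the mean red and mean
    green are taken, their ratio formed (mean-red over mean-green, the
    ROI convention), and oxygen obtained from the calibration model.
    """
    entries = list(rois.iter_rois())
    if not entries:
        raise ValueError("empty ROI set")
    counts = np.bincount(
        rois.label_image.ravel(), minlength=3 * len(rois.ids) + 1
    )
    labels = np.array([lab for _, _, lab in entries])
    if np.any(counts[labels] == 0):
        raise ValueError("empty ROI mask in ROI set")

    reference = stack.frames[0, 1]
    records = []
    for i in range(stack.n_frames):
        red, green = stack.frames[i]
        if register and i > 0:
            dy, dx = register_frame(green, reference, max_shift=max_shift)
            red = np.roll(red, (-dy, -dx), axis=(0, 1))
            green = np.roll(green, (-dy, -dx), axis=(0, 1))
        else:
            dy, dx = 0, 0
        mr = _roi_means(red, rois.label_image, labels)
        mg = _roi_means(green, rois.label_image, labels)
        if np.any(mg == 0):
            raise ValueError(f"zero mean green intensity in frame {i}")
        ratio = mr / mg
        oxy = model.ratio_to_oxygen(ratio)
        for ((rc, roi, _), a, b, rat, c) in zip(entries, mr, mg, ratio, oxy):
            records.append((
                i, stack.times_min[i], rc[0], rc[1], roi,
                a, b, rat, c, dy, dx,
            ))
    return pd.DataFrame(records, columns=SERIES_COLUMNS)


def exposure_scale(
    model: CalibrationModel, terminal_ratios: np.ndarray, reference: float
) -> float:
    """Per-curve exposure correction factor on the ratio.

    The scalar ``s`` such that the calibrated oxygen of ``s * ratio``
    averages exactly ``reference`` over the given terminal ratios; closed
    form for both transfer-function forms (exposure deviations act
    multiplicatively on the measured intensities, hence on the ratio).
    """
    r = np.asarray(terminal_ratios, dtype=float)
    if np.any(r <= 0):
        raise ValueError("terminal ratios must be positive")
    if model.form == "stern_volmer":
        return float(
            model.R0 * np.mean(1.0 / r) / (1.0 + model.Ksv * reference)
        )
    return float(model.oxygen_to_ratio(reference) / np.mean(r))


def normalize_terminal(
    series: pd.DataFrame,
    model: CalibrationModel,
    n_last: int = 10,
    reference: float = 100.0,
) -> pd.DataFrame:
    """Rescale each (cavity, ROI) curve to its terminal saturation plateau.

    After full respiratory inhibition the medium is maximally saturated,
    so the mean of the last ``n_last`` calibrated points must equal
    ``reference``.  Any deviation is exposure/gain error, which acts
    multiplicatively on the measured ratio: each curve's ratios are scaled
    by the closed-form factor from :func:`exposure_scale` and re-converted,
    giving ``oxygen_norm`` (clamped to the model range).  The factor is
    always recomputed from the stored raw ratios, so the operation is
    idempotent, and a global rescaling of the red channel cancels exactly.
    """
    frames = np.sort(series["frame"].unique())
    if n_last > len(frames):
        raise ValueError(
            f"n_last={n_last} exceeds series length {len(frames)}"
        )
    last = set(frames[-n_last:])
    out = series.copy()
    tail = out[out["frame"].isin(last)]
    scale = tail.groupby(["row", "col", "roi"], sort=False)["ratio"].agg(
        lambda r: exposure_scale(model, r.to_numpy(), reference)
    )
    if np.any(scale <= 0):
        raise ValueError("terminal plateau gives a non-positive scale")
    out = out.join(scale.rename("_scale"), on=["row", "col", "roi"])
    out["oxygen_norm"] = model.ratio_to_oxygen(
        out["ratio"].to_numpy() * out.pop("_scale").to_numpy()
    )
    return out
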