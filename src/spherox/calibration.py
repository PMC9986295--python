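"""Two-point ratiometric calibration of the oxygen sensor film.

The sensor dye (red channel) is quenched by oxygen while the reference dye
(green channel) is oxygen-insensitive; the per-pixel ratio R = red/green
therefore falls with rising oxygen and cancels illumination and focus
variations.  A two-point calibration anchors the transfer function at the
zero-oxygen ratio ``R0`` (sodium-sulfite drop) and the air-saturated ratio
``R100`` (equilibrated water drop), expressed in percent air saturation
(%a.s., 100 = maximum soluble oxygen).

Two functional forms through the anchors are supported:

* ``stern_volmer`` (default): R0/R = 1 + Ksv * C, the quenching law, with
  Ksv = (R0/R100 - 1)/100 per %a.s.
* ``linear``: R falls linearly from R0 to R100 between 0 and 100 %a.s.

Both reproduce the anchors exactly; they differ in how they extrapolate
toward the 150 %a.s. upper range limit.  Reported oxygen is clamped to
[0, 150] %a.s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CalibrationModel", "fit_two_point", "OXYGEN_RANGE"]

#: Reportable oxygen range of the sensor film, %a.s.
OXYGEN_RANGE: tuple[float, float] = (0.0, 150.0)

_FORMS = ("stern_volmer", "linear")


@dataclass(frozen=True)
class CalibrationModel:
    """Ratio-to-oxygen transfer function anchored at 0 and 100 %a.s."""

    R0: float
    R100: float
    form: str = "stern_volmer"
    range: tuple[float, float] = OXYGEN_RANGE

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown calibration form {self.form!r}")
        if not (self.R0 > self.R100 > 0):
            raise ValueError(
                "inverted calibration anchors: require R0 > R100 > 0 "
                f"(got R0={self.R0}, R100={self.R100})"
            )

    @property
    def Ksv(self) -> float:
        """Stern-Volmer quenching constant per %a.s."""
        return (self.R0 / self.R100 - 1.0) / 100.0

    # -- forward (measurement) direction -----------------------------------

    def ratio_to_oxygen(self, R):
        """Convert ratio(s) to oxygen in %a.s., clamped to ``self.range``.

        Strictly decreasing in R before clamping.  Raises on R <= 0.
        """
        R = np.asarray(R, dtype=float)
        if np.any(R <= 0):
            raise ValueError("ratio must be strictly positive")
        if self.form == "stern_volmer":
            C = (self.R0 / R - 1.0) / self.Ksv
        else:
            C = 100.0 * (self.R0 - R) / (self.R0 - self.R100)
        C = np.clip(C, *self.range)
        return float(C) if C.ndim == 0 else C

    # -- inverse (generator) direction -------------------------------------

    def oxygen_to_ratio(self, C):
        """Exact inverse of :meth:`ratio_to_oxygen` on the model range."""
        C = np.asarray(C, dtype=float)
        lo, hi = self.range
        if np.any(C < lo) or np.any(C > hi):
            raise ValueError(f"oxygen outside calibrated range [{lo}, {hi}]")
        if self.form == "stern_volmer":
            R = self.R0 / (1.0 + self.Ksv * C)
        else:
            R = self.R0 - (self.R0 - self.R100) * C / 100.0
        return float(R) if R.ndim == 0 else R

    def to_dict(self) -> dict:
        return {
            "R0": self.R0,
            "R100": self.R100,
            "form": self.form,
            "Ksv": self.Ksv,
            "range": list(self.range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            R0=float(d["R0"]),
            R100=float(d["R100"]),
            form=d.get("form", "stern_volmer"),
            range=tuple(d.get("range", OXYGEN_RANGE)),
        )


def mean_pixel_ratio(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean of the per-pixel red/green ratio over ``mask``.

    ``image`` is a two-channel array (2, H, W), channel 0 = red sensor,
    channel 1 = green reference.  The ratio is computed pixel-wise and then
    averaged (the anchor convention; per-ROI time series use mean-red over
    mean-green instead).
    """
    red, green = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(red.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("sensor mask is empty")
    g = green[mask]
    if np.any(g == 0):
        raise ValueError("zero green pixel inside the sensor mask")
    return float(np.mean(red[mask] / g))


def fit_two_point(
    image_0pct: np.ndarray,
    image_100pct: np.ndarray,
    sensor_mask: np.ndarray | None = None,
    form: str = "stern_volmer",
) -> CalibrationModel:
    """Fit the two-point calibration from a 0% and a 100% a.s. image pair.

    Parameters
    ----------
    image_0pct, image_100pct
        Two-channel images (2, H, W) taken under the sulfite (zero oxygen)
        and air-saturated conditions; same shape.
    sensor_mask
        Boolean mask of sensor-film pixels; all pixels if None.
    form
        ``"stern_volmer"`` or ``"linear"``.

    Raises
    ------
    ValueError
        If shapes differ, the mask is empty, a green pixel is zero inside
        the mask, or the anchors come out inverted (R0 <= R100 — the
        classic sign of swapped input images).
    """
    a = np.asarray(image_0pct)
    b = np.asarray(image_100pct)
    if a.shape != b.shape:
        raise ValueError("calibration images must have the same shape")
    R0 = mean_pixel_ratio(a, sensor_mask)
    R100 = mean_pixel_ratio(b, sensor_mask)
    if R0 <= R100:
        raise ValueError(
            "inverted calibration anchors: mean ratio of the 0% image "
            f"({R0:.4g}) must exceed that of the 100% image ({R100:.4g}); "
            "check whether the images are swapped"
        )
    return CalibrationModel(R0=R0, R100=R100, form=form)
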