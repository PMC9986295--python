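"""Physical layout of the microcavity array and the pixel raster.

All physical quantities are micrometres; image coordinates are pixels,
origin at the top-left corner, row-major, 0-based.  Physical lengths enter
pixel space only through ``pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArrayGeometry"]


@dataclass(frozen=True)
class ArrayGeometry:
    """Regular lattice of thermoformed sensor-film microcavities.

    Each cavity is a cylindrical well (inner diameter ``inner_diameter_um``)
    surrounded by a sloped bevel (chamfer) of outer diameter
    ``bevel_outer_diameter_um``.  A single spheroid sits at the cavity
    bottom; its projected footprint is modelled as a centred disc of
    diameter ``spheroid_diameter_um``.

    The default geometry is an 8 x 8 array, 300 um inner cavity diameter,
    500 um chamfer outer diameter, 1 mm centre-to-centre pitch, imaged at
    10 um per pixel (a 850 x 850 px frame).
    """

    n_rows: int = 8
    n_cols: int = 8
    pitch_um: float = 1000.0
    inner_diameter_um: float = 300.0
    bevel_outer_diameter_um: float = 500.0
    spheroid_diameter_um: float = 200.0
    pixel_size_um: float = 10.0
    origin_offset_um: tuple[float, float] = (750.0, 750.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be >= 1")
        lengths = (
            self.pitch_um,
            self.inner_diameter_um,
            self.bevel_outer_diameter_um,
            self.spheroid_diameter_um,
            self.pixel_size_um,
        )
        if any(x <= 0 for x in lengths):
            raise ValueError("all lengths must be strictly positive")
        if not (
            self.spheroid_diameter_um
            < self.inner_diameter_um
            < self.bevel_outer_diameter_um
            < self.pitch_um
        ):
            raise ValueError(
                "require spheroid < inner < bevel-outer diameter < pitch"
            )
        oy, ox = self.origin_offset_um
        if min(oy, ox) < self.bevel_outer_diameter_um / 2:
            raise ValueError(
                "origin offset too small: bevel discs would be clipped by "
                "the image border"
            )

    # -- pixel-space conversions -------------------------------------------

    @property
    def pitch_px(self) -> float:
        return self.pitch_um / self.pixel_size_um

    @property
    def spheroid_radius_px(self) -> float:
        return self.spheroid_diameter_um / 2 / self.pixel_size_um

    @property
    def inner_radius_px(self) -> float:
        return self.inner_diameter_um / 2 / self.pixel_size_um

    @property
    def bevel_outer_radius_px(self) -> float:
        return self.bevel_outer_diameter_um / 2 / self.pixel_size_um

    @property
    def image_shape(self) -> tuple[int, int]:
        """Canvas (rows, cols) in pixels; every bevel disc fits inside."""
        oy, ox = self.origin_offset_um
        h = 2 * oy + (self.n_rows - 1) * self.pitch_um
        w = 2 * ox + (self.n_cols - 1) * self.pitch_um
        return (int(round(h / self.pixel_size_um)),
                int(round(w / self.pixel_size_um)))

    def center_px(self, row: int, col: int) -> tuple[float, float]:
        """Centre of cavity (row, col) in pixel coordinates (y, x)."""
        oy, ox = self.origin_offset_um
        return (
            (oy + row * self.pitch_um) / self.pixel_size_um,
            (ox + col * self.pitch_um) / self.pixel_size_um,
        )

    def centers_px(self) -> np.ndarray:
        """All cavity centres, shape (n_rows*n_cols, 2), row-major order."""
        return np.array(
            [self.center_px(r, c)
             for r in range(self.n_rows) for c in range(self.n_cols)]
        )
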