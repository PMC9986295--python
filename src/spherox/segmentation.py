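"""Cavity-lattice detection and per-cavity ROI decomposition.

Works on the green (reference) channel only, which carries the film
geometry but no oxygen signal: illumination is flattened, cavities are
found by a matched annular filter at the known bevel scale followed by
lattice validation (the array layout is known a priori from the molding
mask), and each cavity is decomposed into three concentric ROIs —
spheroid disc, cavity wall, chamfer (bevel) — whose radii come from the
array geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max

from .geometry import ArrayGeometry

__all__ = [
    "CavityROISet",
    "correct_illumination",
    "detect_cavities",
    "build_roi_masks",
    "ROI_LABELS",
]

#: ROI class -> label value in the per-cavity label plane.
ROI_LABELS = {"spheroid": 1, "wall": 2, "chamfer": 3}


def correct_illumination(image: np.ndarray, degree: int = 2) -> np.ndarray:
    """Remove smooth large-scale illumination gain from a single channel.

    Divides by a low-order polynomial background surface (default
    quadratic — exact for a radial vignette) fitted by least squares; the
    fit varies on scales far above the bevel outer diameter, so cavity
    structure is untouched.  Output is rescaled to preserve the global
    mean.  Fails if the background estimate has zeros.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    h, w = img.shape
    y = np.linspace(-1.0, 1.0, h)
    x = np.linspace(-1.0, 1.0, w)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    cols = [np.ones_like(yy)]
    for d in range(1, degree + 1):
        for k in range(d + 1):
            cols.append(yy ** (d - k) * xx ** k)
    A = np.stack([c.ravel() for c in cols], axis=1)
    # subsample for the fit; evaluate on the full grid
    step = max(1, img.size // 40000)
    coef, *_ = np.linalg.lstsq(A[::step], img.ravel()[::step], rcond=None)
    bg = (A @ coef).reshape(h, w)
    if np.any(bg == 0):
        raise ValueError("background estimate contains zeros")
    out = img / bg
    m = out.mean()
    if m == 0:
        return out
    return out * (img.mean() / m)


def _annulus_template(geometry: ArrayGeometry) -> np.ndarray:
    """Zero-sum matched filter: +1 on the chamfer ring, -1 in the cavity."""
    r_out = geometry.bevel_outer_radius_px
    r_in = geometry.inner_radius_px
    n = int(np.ceil(r_out)) * 2 + 1
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    d = np.hypot(yy - c, xx - c)
    t = np.zeros((n, n))
    t[(d >= r_in) & (d < r_out)] = 1.0
    t[d < r_in] = -1.0
    t -= t.mean() * (t != 0)  # keep support, kill DC response
    return t


def detect_cavities(
    green_image: np.ndarray,
    geometry: ArrayGeometry,
    snr_min: float = 8.0,
) -> np.ndarray:
    """Find cavity centres on an illumination-corrected green image.

    Returns an (n, 2) array of (y, x) centres in row-major lattice order.
    The detected set must form a complete rectangular lattice whose pitch
    matches ``geometry.pitch_um`` within +-10%; it may be the full
    ``n_rows x n_cols`` array or a contiguous subgrid (smaller field of
    view).  Raises ``ValueError`` with a count report otherwise, and
    "no lattice found" when no significant ring response exists (e.g. a
    blank image).
    """
    img = np.asarray(green_image, dtype=float)
    templ = _annulus_template(geometry)
    resp = fftconvolve(img - img.mean(), templ[::-1, ::-1], mode="same")

    mad = np.median(np.abs(resp - np.median(resp)))
    peak = resp.max()
    if mad == 0 or peak < snr_min * mad:
        raise ValueError("no lattice found: no significant cavity response")

    min_dist = max(3, int(0.5 * geometry.pitch_px))
    coords = peak_local_max(
        resp, min_distance=min_dist, threshold_abs=0.5 * peak,
        exclude_border=False,
    )
    if len(coords) == 0:
        raise ValueError("no lattice found: no significant cavity response")

    rows = _cluster_1d(coords[:, 0], geometry.pitch_px / 2)
    cols = _cluster_1d(coords[:, 1], geometry.pitch_px / 2)
    n_exp = geometry.n_rows * geometry.n_cols
    if len(rows) * len(cols) != len(coords) or len(coords) > n_exp:
        raise ValueError(
            f"detected {len(coords)} cavities; expected "
            f"{n_exp} ({geometry.n_rows}x{geometry.n_cols}) or a complete "
            f"subgrid ({len(rows)} row x {len(cols)} col clusters found)"
        )
    for line in (rows, cols):
        gaps = np.diff(line)
        if len(gaps) and np.any(
            np.abs(gaps - geometry.pitch_px) > 0.1 * geometry.pitch_px
        ):
            raise ValueError(
                "detected centres are not consistent with the array pitch "
                "within 10%"
            )

    # merge near-duplicates (closer than the inner radius): peak_local_max's
    # min_distance already enforces this at default geometry, but guard it.
    centers = _snap_to_lattice(coords, rows, cols, resp)
    return centers


def _cluster_1d(values: np.ndarray, tol: float) -> np.ndarray:
    """Cluster scalar coordinates into lattice lines; returns line centres."""
    v = np.sort(np.asarray(values, dtype=float))
    groups = [[v[0]]]
    for x in v[1:]:
        if x - groups[-1][-1] <= tol:
            groups[-1].append(x)
        else:
            groups.append([x])
    return np.array([np.mean(g) for g in groups])


def _snap_to_lattice(coords, rows, cols, resp) -> np.ndarray:
    """Assign each peak a (row, col) slot; keep the strongest per slot."""
    best = {}
    for y, x in coords:
        r = int(np.argmin(np.abs(rows - y)))
        c = int(np.argmin(np.abs(cols - x)))
        key = (r, c)
        val = resp[y, x]
        if key not in best or val > best[key][0]:
            best[key] = (val, y, x)
    if len(best) != len(rows) * len(cols):
        raise ValueError(
            f"lattice incomplete: {len(best)} occupied slots of "
            f"{len(rows) * len(cols)}"
        )
    out = [
        (best[(r, c)][1], best[(r, c)][2])
        for r in range(len(rows)) for c in range(len(cols))
    ]
    return np.array(out, dtype=float)


@dataclass
class CavityROISet:
    """Per-cavity centres and the three concentric ROI masks.

    ``label_image`` encodes both cavity and ROI class in one int16 plane:
    0 = background, otherwise ``cavity_index * 3 + ROI_LABELS[roi]`` with
    cavity_index the row-major position in ``ids``.  Masks of distinct
    cavities are disjoint by construction (nearest-centre assignment).
    """

    ids: list  # [(row, col), ...] row-major
    centers: np.ndarray  # (n, 2) float (y, x)
    label_image: np.ndarray  # int16, same shape as source image

    def mask(self, cavity_id: tuple[int, int], roi: str) -> np.ndarray:
        idx = self.ids.index(tuple(cavity_id))
        return self.label_image == idx * 3 + ROI_LABELS[roi]

    def iter_rois(self):
        """Yield (cavity_id, roi_name, label_value) in deterministic order."""
        for idx, cav in enumerate(self.ids):
            for roi, lab in ROI_LABELS.items():
                yield cav, roi, idx * 3 + lab


def build_roi_masks(
    centers: np.ndarray,
    geometry: ArrayGeometry,
    image_shape: tuple[int, int] | None = None,
) -> CavityROISet:
    """Decompose each cavity into spheroid / wall / chamfer masks.

    Radial boundaries in pixels come from the geometry: spheroid disc up to
    ``spheroid_diameter_um/2``, wall annulus up to ``inner_diameter_um/2``,
    chamfer annulus up to ``bevel_outer_diameter_um/2``.  Pixels reachable
    from two centres go to the nearer one (ties to the lower row-major
    index).  A cavity whose bevel disc is clipped by the image border is
    dropped with a warning rather than measured partially.
    """
    centers = np.asarray(centers, dtype=float)
    if image_shape is None:
        image_shape = geometry.image_shape
    h, w = image_shape
    r_sph = geometry.spheroid_radius_px
    r_in = geometry.inner_radius_px
    r_out = geometry.bevel_outer_radius_px

    # infer row-major lattice ids from the centre coordinates
    rows = _cluster_1d(centers[:, 0], geometry.pitch_px / 2)
    cols = _cluster_1d(centers[:, 1], geometry.pitch_px / 2)

    kept_ids: list[tuple[int, int]] = []
    kept_centers = []
    for cy, cx in centers:
        r = int(np.argmin(np.abs(rows - cy)))
        c = int(np.argmin(np.abs(cols - cx)))
        if (cy - r_out < -0.5 or cy + r_out > h - 0.5
                or cx - r_out < -0.5 or cx + r_out > w - 0.5):
            warnings.warn(
                f"cavity ({r}, {c}) clipped by the image border; dropped",
                stacklevel=2,
            )
            continue
        kept_ids.append((r, c))
        kept_centers.append((cy, cx))
    if not kept_centers:
        raise ValueError("no cavity lies fully inside the image")
    kept_centers = np.asarray(kept_centers)

    label = np.zeros((h, w), dtype=np.int16)
    dist_best = np.full((h, w), np.inf)
    yy, xx = np.mgrid[0:h, 0:w]
    # iterate in row-major id order: with strict '<' on the distance update,
    # ties stay with the earlier (lower) id
    order = np.lexsort((
        [c for _, c in kept_ids], [r for r, _ in kept_ids]
    ))
    kept_ids = [kept_ids[i] for i in order]
    kept_centers = kept_centers[order]
    for idx, (cy, cx) in enumerate(kept_centers):
        y0, y1 = int(cy - r_out) - 1, int(cy + r_out) + 2
        x0, x1 = int(cx - r_out) - 1, int(cx + r_out) + 2
        y0, x0 = max(y0, 0), max(x0, 0)
        d = np.hypot(yy[y0:y1, x0:x1] - cy, xx[y0:y1, x0:x1] - cx)
        sub_lab = label[y0:y1, x0:x1]
        sub_best = dist_best[y0:y1, x0:x1]
        claim = (d < r_out) & (d < sub_best)
        code = np.zeros_like(sub_lab)
        code[(d >= r_in) & (d < r_out)] = idx * 3 + ROI_LABELS["chamfer"]
        code[(d >= r_sph) & (d < r_in)] = idx * 3 + ROI_LABELS["wall"]
        code[d < r_sph] = idx * 3 + ROI_LABELS["spheroid"]
        sub_lab[claim] = code[claim]
        sub_best[claim] = d[claim]

    return CavityROISet(
        ids=kept_ids, centers=kept_centers, label_image=label
    )
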