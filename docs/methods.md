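# Methods

## Scope and data model

`spherox` analyses two-channel time-lapse stacks of oxygen-sensor
microcavity arrays: channel 0 is the oxygen-quenched red sensor dye,
channel 1 the oxygen-insensitive green reference dye. All coordinates are
pixels (origin top-left, row-major, 0-based); physical micrometres enter
only through `ArrayGeometry.pixel_size_um`. The long-format result table
(`frame, time_min, row, col, roi, mean_red, mean_green, ratio,
oxygen_raw, oxygen_norm, offset_y, offset_x`) carries one record per
frame × cavity × ROI.

## Calibration

Two-point calibration: the anchor ratios are the means of the per-pixel
red/green ratio over the sensor mask of the 0 %a.s. (sulfite) and
100 %a.s. (air-saturated) images. Two transfer functions through the
anchors are provided:

* **Stern–Volmer** (default): `R0/R = 1 + Ksv·C` with
  `Ksv = (R0/R100 − 1)/100`. Physically motivated by collisional
  quenching; resolution is highest toward 0 %a.s.
* **linear**: `C = 100·(R0 − R)/(R0 − R100)`.

Both reproduce the anchors exactly and differ only in extrapolation;
converted values are clamped to the sensor's reportable range,
0–150 %a.s. Two ratio conventions coexist deliberately: calibration
anchors use the mean of per-pixel ratios (robust to the shared
illumination field, which cancels pixel-wise), while per-ROI time series
use mean-red over mean-green (the ROI-statistics convention). Inputs with
swapped calibration images are caught by the `R0 > R100` precondition.

## Segmentation

Segmentation is a pure function of the green channel, which carries film
geometry but no oxygen signal.

1. **Illumination correction** divides by a least-squares quadratic
   background surface (exact for a radial vignette, incapable of varying
   at the 500 µm bevel scale, so cavity structure is untouched) and
   rescales to preserve the global mean. The fit subsamples the image to
   ≤ ~40 000 pixels; the surface is evaluated on the full grid.
2. **Lattice detection** cross-correlates a zero-DC matched annulus
   (+1 on the chamfer ring, −1 inside the cavity, built from the known
   geometry) with the corrected image. Peaks (minimum separation half a
   pitch, ≥ 50% of the maximum response) must form a complete rectangular
   lattice with spacing within ±10% of the nominal pitch — either the
   full `n_rows × n_cols` array or a contiguous subgrid (smaller field of
   view). A response maximum below 8 robust SDs (MAD) of the response map
   is reported as "no lattice found". The known-layout prior makes
   detection deterministic and grid-snapped rather than free-form.
3. **ROI construction** rasterizes three concentric regions per centre
   with strict-inequality boundaries (pixel centre distance `d`):
   spheroid `d < r_spheroid`, wall `r_spheroid ≤ d < r_inner`, chamfer
   `r_inner ≤ d < r_outer`. Disjointness within a cavity is structural
   (single label plane); contested pixels go to the nearest centre, ties
   to the lower row-major index. A cavity whose bevel disc would be
   clipped by the border is dropped with a warning, never measured
   partially.

The wall/chamfer radial boundaries (100 µm spheroid radius, 150 µm inner
radius, 250 µm bevel-outer radius by default) are geometry parameters,
not constants; the chamfer ROI is read as the full sloped annulus.

## Registration and extraction

The acquisition does not correct small stage shifts, so each frame's
green channel is registered to the first frame's green channel by the
integer-shift maximum of the circular FFT cross-correlation, searched
within ±10 px. A peak not unique by a 10⁻⁶ relative margin (e.g. a
featureless frame) is an error, not a guess. The same integer shift is
applied to both channels; sub-pixel drift and rotation are out of scope.
Per-ROI means then convert to oxygen via the calibration model.

## Terminal normalization

After rotenone + antimycin A, mitochondrial respiration is fully blocked
(non-mitochondrial consumption is treated as negligible) and oxygen
re-equilibrates to saturation, so the mean of each curve's last 10
calibrated points must equal 100 %a.s. Residual deviations are exposure
differences, which act multiplicatively on measured intensities and hence
on the ratio — not on calibrated oxygen, which is non-linear in the
ratio. Normalization therefore solves, per (cavity, ROI) curve and in
closed form, for the scalar `s` such that the calibrated oxygen of
`s · ratio` averages exactly the reference over the terminal window
(Stern–Volmer: `s = R0·mean(1/R)/(1 + Ksv·C_ref)`; linear:
`s = R(C_ref)/mean(R)`), then re-converts the whole curve. Consequences,
all tested: the terminal mean hits the reference to ≤ 10⁻⁶, the operation
is idempotent (the factor is always recomputed from the stored raw
ratios), a constant red-channel gain is corrected exactly, and a global
rescaling of the red channel leaves `oxygen_norm` unchanged.
Normalization is applied per curve — the stricter reading — rather than
with one global factor.

## Stress-test metrics

Frames are assigned to phases by timestamp over half-open intervals
[start, start + duration); the final phase is closed at its right
endpoint so the last frame (t = 150 min on the default schedule) is
covered, while later times are rejected. Plateaus are means of the last
`k_last = 5` frames (10 min) of each phase — the curves level off but no
window is canonical, so it is a parameter. Respiration indices are
plateau differences relative to the fully inhibited level (open-cavity
geometry: concentration depressions, not consumption rates); ATP-linked
< 0 or maximal < basal are flagged, not fatal, since noise can invert
them on weakly respiring cultures. Summary statistics (mean, SD, n over
cavities) are reported alongside per-cavity values.

## Synthetic scenario generator

The generator renders the experiment the pipeline expects, with exact
ground truth:

* **Geometry**: 8 × 8 cavities, 300 µm inner diameter, 500 µm bevel
  outer diameter, 200 µm spheroid footprint (a centred textured disc —
  the projected size is a modelling choice), 1 mm pitch (unstated for
  the physical array; 8 cavities at 1 mm fit the ~1 cm² film), 10 µm/px
  (default frames 850 × 850 px), 750 µm margins.
* **Schedule**: five 30-min phases — basal, medium control, oligomycin,
  FCCP, rotenone + antimycin A — at 2-min frames: 76 frames, t = 0–150
  min.
* **Oxygen dynamics**: phenomenological per-ROI first-order approach to
  per-phase targets, continuous across phase boundaries, starting from
  100 %a.s. (fresh medium). Default targets (chamfer/spheroid):
  basal and control 25/20, oligomycin 75/72, FCCP 18/10, rot/AA 100/100;
  the wall interpolates midway. No reaction–diffusion transport is
  modelled. The time constant is τ = 2 min: fast enough that the
  terminal normalization window (the last 20 min of the inhibited phase)
  is genuinely at saturation (residual < 0.05 %a.s.) — the premise the
  normalization rests on — while transitions still span several frames.
* **Encoding**: pixel ratios come from the inverse calibration
  (R0 = 2.0, R100 = 1.0, arbitrary plausible anchors); background
  (inter-cavity) film encodes 100 %a.s. The green channel is the product
  of a film-structure pattern (bright bevel, dim wall, darker spheroid)
  and a radial vignette; it is bit-invariant to oxygen.
* **Artefacts**: independent additive Gaussian noise per channel (σ =
  0.02 of the reference intensity); a shared multiplicative vignette
  (strength 0.15), applied in foil coordinates so it translates with the
  frame; integer-pixel rigid jitter, uniform in ±3 px (frame 0 fixed);
  and a red-only exposure gain, default a constant 0.98 — a few-percent
  exposure mismatch between calibration and measurement, the error mode
  terminal normalization exists to correct (an arbitrary per-frame gain
  sequence can be supplied).
* **Determinism**: one seeded generator drives jitter and noise;
  identical seeds give bit-identical stacks and tables.

In-memory frames are float64, so at zero noise decoding any sensor pixel
recovers ground-truth oxygen to ≤ 10⁻⁹ %a.s.; the TIFF dialect
(interleaved red/green pages, uint16) adds ~10⁻³ %a.s. quantization on
file round-trips.

What the generator does **not** emulate — hence what passing tests do not
show about acquired data: photobleaching, focus drift, sub-pixel or
rotational motion, cell-level texture and debris, cavity-to-cavity
biological variability (all cavities share one true trajectory per ROI
class), dye loading gradients, and the brief oxygen spike a medium
addition can cause. Recovery numbers on synthetic data are a correctness
check of the pipeline, not an accuracy claim for any instrument.

## Problem sizes and runtime

Default validation runs use the full 8 × 8 array (850 × 850 px, 76
frames, 64 cavities, 192 ROI curves); unit tests use 4 × 4 and 2 × 2
variants of the same scenario. The full stochastic render + pipeline
takes well under a minute on one CPU; `scripts/acceptance.py` (which adds
a complete TIFF write/read round-trip) completes in under a minute.

## Known limitations

* Free-form (non-lattice) cavity layouts and partially occupied grids
  with holes are rejected rather than analysed.
* The Stern–Volmer form assumes ideal single-site quenching; real sensor
  foils may need two-site models or temperature compensation, neither of
  which is implemented.
* Indices are concentration-based proxies; converting to molar oxygen
  flux would require the reaction–diffusion physics deliberately left
  out.
* Registration assumes the first frame is representative; a corrupted
  reference frame would propagate to every offset.
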