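"""File formats: the two-channel TIFF dialect, CSV tables, configs.

Stacks are multi-page TIFF, channel-interleaved — page order frame0-red,
frame0-green, frame1-red, frame1-green, ... — 16-bit unsigned.  Channel
identity is part of the dialect (red = oxygen-sensitive dye, green =
reference dye), never guessed from content.  CSV tables carry a single
``#`` header comment line with a schema version and the seed where one
applies.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import ArrayGeometry
from .synth import Phase, PhaseSchedule, ScenarioTruth, SynthStack

__all__ = [
    "write_stack", "read_stack", "write_series_csv", "read_series_csv",
    "write_json", "read_json", "load_scenario_yaml", "dump_scenario_yaml",
]

CSV_SCHEMA = "spherox-csv-v1"


def write_stack(path, frames: np.ndarray, times_min=None) -> None:
    """Write frames (n, 2, H, W) as interleaved uint16 multi-page TIFF."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[1] != 2:
        raise ValueError("expected frames of shape (n_frames, 2, H, W)")
    pages = frames.reshape((-1,) + frames.shape[2:])
    data = np.clip(np.round(pages), 0, 65535).astype(np.uint16)
    meta = {"dialect": "spherox-interleaved-rg", "n_frames": frames.shape[0]}
    if times_min is not None:
        meta["times_min"] = [float(t) for t in times_min]
    tifffile.imwrite(str(path), data, metadata=meta,
                     photometric="minisblack")


def read_stack(path, frame_interval_min: float | None = None) -> SynthStack:
    """Read the interleaved two-channel TIFF dialect back into a stack.

    Frame times come from the embedded metadata when present, else from
    ``frame_interval_min`` (no timestamp inference from file names).  The
    returned object has empty ground-truth/offset tables: those belong to
    the generator, not the file format.
    """
    with tifffile.TiffFile(str(path)) as tf:
        pages = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % 2 != 0:
        raise ValueError(
            f"incomplete channel pair: {pages.shape[0]} pages is odd"
        )
    n = pages.shape[0] // 2
    frames = pages.reshape(n, 2, *pages.shape[1:]).astype(float)
    times = meta.get("times_min")
    if times is not None:
        times = np.asarray(times, dtype=float)
        if len(times) != n:
            raise ValueError("metadata frame times do not match page count")
    elif frame_interval_min is not None:
        times = frame_interval_min * np.arange(n, dtype=float)
    else:
        times = np.arange(n, dtype=float)
    empty = pd.DataFrame()
    return SynthStack(
        frames=frames, times_min=times, ground_truth=empty, offsets=empty
    )


def write_series_csv(path, df: pd.DataFrame, seed=None) -> None:
    header = f"# {CSV_SCHEMA}"
    if seed is not None:
        header += f" seed={seed}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_series_csv(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            fh.seek(0)
        return pd.read_csv(fh)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


# -- scenario configuration -------------------------------------------------


def dump_scenario_yaml(
    path, geometry: ArrayGeometry, schedule: PhaseSchedule,
    truth: ScenarioTruth,
) -> None:
    red_gain = truth.red_gain
    if not np.isscalar(red_gain):
        red_gain = [float(g) for g in np.asarray(red_gain)]
    cfg = {
        "geometry": {
            "n_rows": geometry.n_rows,
            "n_cols": geometry.n_cols,
            "pitch_um": geometry.pitch_um,
            "inner_diameter_um": geometry.inner_diameter_um,
            "bevel_outer_diameter_um": geometry.bevel_outer_diameter_um,
            "spheroid_diameter_um": geometry.spheroid_diameter_um,
            "pixel_size_um": geometry.pixel_size_um,
            "origin_offset_um": list(geometry.origin_offset_um),
        },
        "schedule": {
            "frame_interval_min": schedule.frame_interval_min,
            "phases": [
                {"name": p.name, "start_min": p.start_min,
                 "duration_min": p.duration_min}
                for p in schedule.phases
            ],
        },
        "truth": {
            "targets": {k: dict(v) for k, v in truth.targets.items()},
            "initial": dict(truth.initial),
            "background_oxygen": truth.background_oxygen,
            "tau_min": truth.tau_min,
            "noise_sigma": truth.noise_sigma,
            "jitter_max_px": truth.jitter_max_px,
            "red_gain": red_gain,
            "vignette_strength": truth.vignette_strength,
            "R0": truth.R0,
            "R100": truth.R100,
        },
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_scenario_yaml(path):
    cfg = yaml.safe_load(Path(path).read_text())
    g = cfg["geometry"]
    geometry = ArrayGeometry(
        n_rows=int(g["n_rows"]), n_cols=int(g["n_cols"]),
        pitch_um=float(g["pitch_um"]),
        inner_diameter_um=float(g["inner_diameter_um"]),
        bevel_outer_diameter_um=float(g["bevel_outer_diameter_um"]),
        spheroid_diameter_um=float(g["spheroid_diameter_um"]),
        pixel_size_um=float(g["pixel_size_um"]),
        origin_offset_um=tuple(g["origin_offset_um"]),
    )
    s = cfg["schedule"]
    schedule = PhaseSchedule(
        phases=tuple(
            Phase(p["name"], float(p["start_min"]), float(p["duration_min"]))
            for p in s["phases"]
        ),
        frame_interval_min=float(s["frame_interval_min"]),
    )
    t = cfg["truth"]
    red_gain = t["red_gain"]
    if isinstance(red_gain, list):
        red_gain = tuple(float(x) for x in red_gain)
    truth = ScenarioTruth(
        targets={k: dict(v) for k, v in t["targets"].items()},
        initial=dict(t["initial"]),
        background_oxygen=float(t["background_oxygen"]),
        tau_min=float(t["tau_min"]),
        noise_sigma=float(t["noise_sigma"]),
        jitter_max_px=int(t["jitter_max_px"]),
        red_gain=red_gain,
        vignette_strength=float(t["vignette_strength"]),
        R0=float(t["R0"]),
        R100=float(t["R100"]),
    )
    return geometry, schedule, truth
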