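"""Mitochondrial stress-test readout from per-ROI oxygen time series.

The five-phase protocol (basal, medium control, oligomycin, FCCP,
rotenone + antimycin A) is decomposed into per-phase plateau levels and
three respiration indices per cavity.  Because the cavities are open —
oxygen is replenished by diffusion and not consumed by the measurement —
the indices are concentration depressions relative to the fully inhibited
plateau, proxies for respiratory activity rather than consumption rates:

* basal respiration index   = C(rot_aa) - C(basal)
* ATP-linked index          = C(oligomycin) - C(basal)
* maximal respiration index = C(rot_aa) - C(fccp)

all on the spheroid ROI unless stated.  The chamfer-minus-spheroid
difference per frame quantifies the radial oxygen gradient around each
spheroid, largest after uncoupling by FCCP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import PhaseSchedule, PHASE_ORDER

__all__ = [
    "label_phases",
    "phase_plateaus",
    "respiration_metrics",
    "gradient_series",
    "StressTestResult",
]

_INDEX_DEFS = {
    "basal_respiration_index": ("rot_aa", "basal"),
    "atp_linked_index": ("oligomycin", "basal"),
    "maximal_respiration_index": ("rot_aa", "fccp"),
}


def label_phases(series: pd.DataFrame, schedule: PhaseSchedule) -> pd.DataFrame:
    """Assign each frame its modulator phase by timestamp.

    Intervals are half-open [start, start+duration); the final phase keeps
    its right endpoint.  Frames outside the schedule raise ``ValueError``.
    """
    out = series.copy()
    out["phase"] = [schedule.phase_of(t) for t in out["time_min"]]
    return out


def phase_plateaus(
    labeled: pd.DataFrame,
    k_last: int = 5,
    value: str = "oxygen_norm",
) -> pd.DataFrame:
    """Quasi-steady level per phase: mean of its last ``k_last`` frames.

    Returns one row per (row, col, roi, phase) with columns ``plateau``
    and ``n_frames`` (frames averaged).
    """
    if value not in labeled.columns:
        raise KeyError(f"series has no column {value!r}")
    rows = []
    for phase, grp in labeled.groupby("phase", sort=False):
        frames = np.sort(grp["frame"].unique())
        if k_last > len(frames):
            raise ValueError(
                f"k_last={k_last} exceeds the {len(frames)} frames of "
                f"phase {phase!r}"
            )
        tail = grp[grp["frame"].isin(frames[-k_last:])]
        agg = tail.groupby(["row", "col", "roi"], sort=False)[value].mean()
        sub = agg.reset_index().rename(columns={value: "plateau"})
        sub.insert(3, "phase", phase)
        sub["n_frames"] = k_last
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    order = {p: i for i, p in enumerate(PHASE_ORDER)}
    return out.sort_values(
        ["row", "col", "roi", "phase"],
        key=lambda s: s.map(order) if s.name == "phase" else s,
        ignore_index=True,
    )


@dataclass
class StressTestResult:
    """Per-cavity plateaus, respiration indices, and summary statistics."""

    plateaus: pd.DataFrame  # row, col, roi, phase, plateau, n_frames
    indices: pd.DataFrame   # row, col, the three indices, flags
    summary: pd.DataFrame   # index name -> mean, sd, n across cavities

    def to_dict(self) -> dict:
        return {
            "indices_summary": {
                r["index"]: {"mean": r["mean"], "sd": r["sd"], "n": int(r["n"])}
                for _, r in self.summary.iterrows()
            }
        }


def respiration_metrics(
    plateaus: pd.DataFrame, roi: str = "spheroid"
) -> StressTestResult:
    """Respiration indices per cavity from the plateau table.

    Uses the ``roi`` curve (default spheroid).  On well-behaved data the
    ATP-linked index is non-negative and the maximal index is at least the
    basal one; violations are flagged (column ``flagged``), not fatal.
    """
    present = set(plateaus["phase"].unique())
    missing = [p for p in PHASE_ORDER if p not in present]
    if missing:
        raise ValueError(f"missing phases: {missing}")
    sub = plateaus[plateaus["roi"] == roi]
    wide = sub.pivot_table(
        index=["row", "col"], columns="phase", values="plateau"
    )
    idx = pd.DataFrame(index=wide.index)
    for name, (hi, lo) in _INDEX_DEFS.items():
        idx[name] = wide[hi] - wide[lo]
    idx["flagged"] = (idx["atp_linked_index"] < 0) | (
        idx["maximal_respiration_index"] < idx["basal_respiration_index"]
    )
    idx = idx.reset_index()

    rows = []
    for name in _INDEX_DEFS:
        v = idx[name].to_numpy(dtype=float)
        rows.append({
            "index": name,
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "n": len(v),
        })
    summary = pd.DataFrame(rows)
    return StressTestResult(plateaus=plateaus, indices=idx, summary=summary)


def gradient_series(labeled: pd.DataFrame) -> pd.DataFrame:
    """Chamfer-minus-spheroid oxygen per cavity per frame.

    Quantifies the radial gradient between the spheroid's direct
    microenvironment and its wider surroundings (the bevel).  Requires
    both ROI records for every frame/cavity.
    """
    value = "oxygen_norm" if "oxygen_norm" in labeled.columns else "oxygen_raw"
    keys = ["frame", "time_min", "row", "col"]
    if "phase" in labeled.columns:
        keys.append("phase")
    ch = labeled[labeled["roi"] == "chamfer"].set_index(keys)[value].sort_index()
    sp = labeled[labeled["roi"] == "spheroid"].set_index(keys)[value].sort_index()
    if len(ch) != len(sp) or not ch.index.equals(sp.index):
        raise ValueError("chamfer/spheroid records do not pair up")
    out = (ch - sp).rename("delta_oxygen").reset_index()
    return out
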