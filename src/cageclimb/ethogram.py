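"""Zeitgeber-time binning, light/dark phases, and transition windows.

Activity is aggregated per cage into fixed-length bins on the zeitgeber
clock (ZT0 = lights-on). With the default 6-min bins there are 240 bins per
24 h; the two transition windows of interest each span exactly 5 bins:

* ``end_of_dark``: ZT 23.5-24.0, i.e. the 30 min directly before lights-on
  (06:30-07:00 under the default 07:00-19:00 schedule);
* ``end_of_light``: ZT 11.5-12.0, the 30 min directly before lights-off
  (18:30-19:00).

Distance travelled is computed per mouse (Euclidean displacement between
consecutive position fixes) and summed over a cage's mice per bin; climbing
is a single cage-level label stream, converted to seconds per bin. Missing
bins are reported and dropped, never imputed.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import FrameLabelSeries, frames_to_seconds
from .io_formats import LightSchedule, zeitgeber_hours

__all__ = [
    "WINDOWS",
    "bins_per_day",
    "window_bin_starts",
    "distance_per_bin",
    "climbing_per_bin",
    "window_means",
    "phase_means",
]

#: transition windows as half-open ZT hour intervals
WINDOWS: dict[str, tuple[float, float]] = {
    "end_of_dark": (23.5, 24.0),
    "end_of_light": (11.5, 12.0),
}


def bins_per_day(bin_length_min: float = 6.0) -> int:
    n = 24 * 60 / bin_length_min
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"bin length {bin_length_min} min does not tile 24 h")
    return int(round(n))


def window_bin_starts(window: str, bin_length_min: float = 6.0) -> np.ndarray:
    """ZT start hours of the bins making up a transition window (5 for 6-min bins)."""
    lo, hi = WINDOWS[window]
    step = bin_length_min / 60.0
    starts = np.arange(0, bins_per_day(bin_length_min)) * step
    return starts[(starts >= lo - 1e-9) & (starts < hi - 1e-9)]


def _zt_bin_start(zt: float, bin_length_min: float) -> float:
    step = bin_length_min / 60.0
    return np.floor(np.asarray(zt) / step) * step


def distance_per_bin(
    records: pd.DataFrame,
    schedule: LightSchedule | None = None,
    bin_length_min: float = 6.0,
) -> pd.DataFrame:
    """Cage-level distance per ZT bin from per-mouse position fixes.

    ``records`` needs columns timestamp, cage_id, mouse_id, x_mm, y_mm,
    day_of_recording. Per mouse, each step contributes the Euclidean
    displacement between consecutive fixes; a step is assigned to the bin
    of its ending fix. Per cage, distances are summed over mice. Returns a
    tidy frame with cage_id, day_of_recording, bin_start_zt, phase,
    distance_mm.
    """
    schedule = schedule or LightSchedule()
    df = records.dropna(subset=["x_mm", "y_mm"]).copy()
    df = df.sort_values("timestamp", kind="stable")
    parts = []
    for (cage, mouse, day), grp in df.groupby(["cage_id", "mouse_id", "day_of_recording"]):
        if len(grp) < 2:
            continue
        dx = np.diff(grp["x_mm"].to_numpy(dtype=float))
        dy = np.diff(grp["y_mm"].to_numpy(dtype=float))
        step = np.hypot(dx, dy)
        end_ts = grp["timestamp"].iloc[1:]
        zt = np.array([zeitgeber_hours(t, schedule) for t in end_ts])
        parts.append(
            pd.DataFrame(
                {
                    "cage_id": cage,
                    "day_of_recording": day,
                    "bin_start_zt": _zt_bin_start(zt, bin_length_min),
                    "distance_mm": step,
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=["cage_id", "day_of_recording", "bin_start_zt", "phase", "distance_mm"]
        )
    out = (
        pd.concat(parts)
        .groupby(["cage_id", "day_of_recording", "bin_start_zt"], as_index=False)[
            "distance_mm"
        ]
        .sum()
    )
    out["phase"] = [schedule.phase_of_zt(z) for z in out["bin_start_zt"]]
    return out[["cage_id", "day_of_recording", "bin_start_zt", "phase", "distance_mm"]]


def climbing_per_bin(
    series: FrameLabelSeries,
    anchor: _dt.datetime,
    cage_id: str,
    day_of_recording: int = 1,
    frame_duration_ms: float = 40.0,
    schedule: LightSchedule | None = None,
    bin_length_min: float = 6.0,
) -> pd.DataFrame:
    """Cage-level climbing seconds per ZT bin from a frame-label stream.

    Frame ``i`` occurs at ``anchor + i * frame_duration_ms``; per bin the
    climbing seconds are the climbing-frame count times the frame
    duration. Bins never observed (no frames at all) are absent from the
    output, not zero-filled.
    """
    schedule = schedule or LightSchedule()
    anchor = pd.Timestamp(anchor)
    idx = np.arange(series.n_frames)
    ts = anchor + pd.to_timedelta(idx * frame_duration_ms, unit="ms")
    anchor_zt = zeitgeber_hours(anchor, schedule)
    zt = (anchor_zt + idx * frame_duration_ms / 3.6e6) % 24.0
    frame_df = pd.DataFrame(
        {
            "bin_start_zt": _zt_bin_start(zt, bin_length_min),
            "climbing": series.labels,
        }
    )
    counts = frame_df.groupby("bin_start_zt", as_index=False)["climbing"].sum()
    counts["climbing_s"] = frames_to_seconds(
        counts["climbing"].to_numpy(), frame_duration_ms
    )
    counts["cage_id"] = cage_id
    counts["day_of_recording"] = day_of_recording
    counts["phase"] = [schedule.phase_of_zt(z) for z in counts["bin_start_zt"]]
    return counts[
        ["cage_id", "day_of_recording", "bin_start_zt", "phase", "climbing_s"]
    ]


def _value_column(binned: pd.DataFrame, value: str | None) -> str:
    if value is not None:
        return value
    for cand in ("distance_mm", "climbing_s", "activity"):
        if cand in binned.columns:
            return cand
    raise ValueError("no activity value column found; pass value= explicitly")


def window_means(
    binned: pd.DataFrame,
    window: str,
    bin_length_min: float = 6.0,
    value: str | None = None,
) -> pd.DataFrame:
    """Mean activity over the 5 bins of a transition window, per cage x day.

    Cage/day combinations missing any of the window's bins are dropped
    with a warning (reported as missing, never imputed).
    """
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {sorted(WINDOWS)}")
    col = _value_column(binned, value)
    starts = window_bin_starts(window, bin_length_min)
    sel = binned[np.isin(np.round(binned["bin_start_zt"], 9), np.round(starts, 9))]
    grouped = sel.groupby(["cage_id", "day_of_recording"], as_index=False).agg(
        mean_activity=(col, "mean"), n_bins=(col, "size")
    )
    incomplete = grouped[grouped["n_bins"] != len(starts)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} cage-day(s) with missing {window} bins",
            stacklevel=2,
        )
        grouped = grouped[grouped["n_bins"] == len(starts)]
    grouped = grouped.drop(columns="n_bins")
    grouped["window"] = window
    return grouped[["cage_id", "day_of_recording", "window", "mean_activity"]]


def phase_means(
    binned: pd.DataFrame,
    phase: str,
    value: str | None = None,
) -> pd.DataFrame:
    """Mean activity over all bins of the light or dark phase, per cage x day."""
    if phase not in ("light", "dark"):
        raise ValueError("phase must be 'light' or 'dark'")
    col = _value_column(binned, value)
    sel = binned[binned["phase"] == phase]
    out = sel.groupby(["cage_id", "day_of_recording"], as_index=False).agg(
        mean_activity=(col, "mean")
    )
    out["phase"] = phase
    return out[["cage_id", "day_of_recording", "phase", "mean_activity"]]
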