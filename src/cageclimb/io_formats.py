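"""Readers/writers and the fixed coordinate/time conventions.

Conventions used throughout the package:

* frames are 2-D ``uint8`` grayscale grids, row-major, origin top-left;
  frame indices are 0-based;
* bout intervals are half-open ``[start_frame, end_frame)``;
* zeitgeber time (ZT) is hours since lights-on, in ``[0, 24)``; the dark
  phase under the default 07:00–19:00 light schedule is the half-open ZT
  interval ``[12, 24)``;
* color sources are collapsed to grayscale with ITU-R BT.601 luma weights.
"""

from __future__ import annotations

import datetime as _dt
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FrameStack",
    "RegionOfInterest",
    "LightSchedule",
    "RoiBoundsError",
    "FrameShapeError",
    "BoutTableError",
    "ActivityError",
    "BOUT_COLUMNS",
    "read_frame_stack",
    "write_frame_stack",
    "read_bout_table",
    "write_bout_table",
    "normalize_bout_table",
    "read_activity",
    "write_activity",
    "zeitgeber_hours",
]

#: magic bytes opening the raw frame-stack container
_STACK_MAGIC = b"CLMB"

#: mandatory bout-table columns, in canonical order
BOUT_COLUMNS = ["segment_id", "annotator_id", "start_frame", "end_frame", "label"]

# BT.601 luma weights for collapsing RGB sources to grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


class RoiBoundsError(ValueError):
    """Region of interest extends outside the frame bounds."""


class FrameShapeError(ValueError):
    """Frames in one source do not share a single height/width."""


class BoutTableError(ValueError):
    """A bout table violates the interval conventions."""


class ActivityError(ValueError):
    """An activity table violates timestamp/column conventions."""


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular pixel region, 0-based inclusive origin, row-major.

    The default 690 x 385 matches the cage-lid region the climbing
    detector was designed around.
    """

    x0: int = 0
    y0: int = 0
    width: int = 690
    height: int = 385

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")
        if self.x0 < 0 or self.y0 < 0:
            raise RoiBoundsError("ROI origin must be non-negative")

    def validate_within(self, frame_height: int, frame_width: int) -> None:
        if self.y0 + self.height > frame_height or self.x0 + self.width > frame_width:
            raise RoiBoundsError(
                f"ROI {self.width}x{self.height}@({self.x0},{self.y0}) exceeds "
                f"frame bounds {frame_width}x{frame_height}"
            )

    def crop(self, frames: np.ndarray) -> np.ndarray:
        """Crop an ``(n, H, W)`` or ``(H, W)`` array to this region."""
        self.validate_within(frames.shape[-2], frames.shape[-1])
        return frames[..., self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width]


@dataclass
class FrameStack:
    """Ordered grayscale frames plus their time base.

    ``frame_duration_ms`` is always ``1000 / frame_rate_hz``; the default
    25 frames/s gives 40 ms frames, the conversion used when climbing
    frame counts are turned into seconds.
    """

    frames: np.ndarray  # (n_frames, height, width) uint8
    frame_rate_hz: float = 25.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FrameShapeError("frames must be a (n, height, width) array")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.frames.dtype != np.uint8:
            self.frames = self.frames.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_duration_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a single frame."""
        return self.frames.shape[1], self.frames.shape[2]

    def time_ms(self, index: int) -> float:
        """Wall-clock offset of frame ``index`` from the stack start."""
        return index * self.frame_duration_ms

    def crop(self, roi: RegionOfInterest) -> "FrameStack":
        return FrameStack(roi.crop(self.frames), self.frame_rate_hz)


@dataclass(frozen=True)
class LightSchedule:
    """Lights-on/lights-off times of day; ZT0 is defined as lights-on."""

    lights_on: _dt.time = _dt.time(7, 0)
    lights_off: _dt.time = _dt.time(19, 0)

    def __post_init__(self) -> None:
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on and lights_off must differ")

    @property
    def dark_start_zt(self) -> float:
        """ZT hour at which the dark phase starts (12.0 for a 12:12 cycle)."""
        on = _time_to_hours(self.lights_on)
        off = _time_to_hours(self.lights_off)
        return (off - on) % 24.0

    def phase_of_zt(self, zt_hours: float) -> str:
        """'light' or 'dark'; the dark phase is the half-open [dark_start, 24)."""
        return "dark" if (zt_hours % 24.0) >= self.dark_start_zt else "light"


def _time_to_hours(t: _dt.time) -> float:
    return t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9


def zeitgeber_hours(timestamp: _dt.datetime | pd.Timestamp, schedule: LightSchedule) -> float:
    """Hours since the most recent lights-on, in [0, 24).

    Periodic with period 24 h; a timestamp at exactly lights-on maps to 0.0.
    """
    ts = pd.Timestamp(timestamp)
    clock = ts.hour + ts.minute / 60.0 + ts.second / 3600.0 + ts.microsecond / 3.6e9
    return (clock - _time_to_hours(schedule.lights_on)) % 24.0


# ---------------------------------------------------------------------------
# frame stacks
# ---------------------------------------------------------------------------

def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img.astype(np.uint8)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return np.clip(img[..., :3].astype(np.float64) @ _LUMA, 0, 255).astype(np.uint8)
    raise FrameShapeError(f"cannot interpret image of shape {img.shape} as a frame")


def write_frame_stack(stack: FrameStack, path: str | Path) -> None:
    """Write the documented raw binary container.

    Layout (little-endian): 4-byte magic ``CLMB``; uint32 height, width,
    n_frames; float64 frame_rate_hz; then the uint8 frames row-major.
    """
    path = Path(path)
    h, w = stack.shape
    with open(path, "wb") as fh:
        fh.write(_STACK_MAGIC)
        fh.write(struct.pack("<IIId", h, w, stack.n_frames, stack.frame_rate_hz))
        fh.write(np.ascontiguousarray(stack.frames).tobytes())


def _read_raw_stack(path: Path) -> FrameStack:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _STACK_MAGIC:
            raise IOError(f"{path} is not a raw frame stack (bad magic {magic!r})")
        h, w, n, rate = struct.unpack("<IIId", fh.read(20))
        data = np.frombuffer(fh.read(h * w * n), dtype=np.uint8)
    if data.size != h * w * n:
        raise IOError(f"{path} truncated: expected {h * w * n} pixels, got {data.size}")
    return FrameStack(data.reshape(n, h, w).copy(), rate)


def read_frame_stack(
    path: str | Path,
    roi: RegionOfInterest | None = None,
    frame_rate_hz: float = 25.0,
) -> FrameStack:
    """Read a frame stack from a raw container, an image directory, or a video.

    ``path`` may be the documented raw binary (written by
    :func:`write_frame_stack`, which carries its own frame rate), a
    directory of lexicographically ordered image files, or a video
    container decodable by imageio. Color inputs are collapsed with BT.601
    luma. When ``roi`` is given, frames are cropped to it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise IOError(f"no image files in directory {path}")
        import imageio.v3 as iio

        frames = [_to_gray(np.asarray(iio.imread(f))) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise FrameShapeError(f"inconsistent frame sizes in {path}: {sorted(shapes)}")
        stack = FrameStack(np.stack(frames), frame_rate_hz)
    elif path.suffix in (".stack", ".raw", ".clmb"):
        stack = _read_raw_stack(path)
    else:
        import imageio.v3 as iio

        try:
            arr = np.asarray(iio.imread(path))
        except Exception as exc:  # pragma: no cover - backend specific
            raise IOError(f"cannot decode {path}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 4 or (arr.ndim == 3 and arr.shape[-1] in (3, 4)):
            if arr.ndim == 3:
                arr = arr[None]
            arr = np.stack([_to_gray(f) for f in arr])
        stack = FrameStack(arr, frame_rate_hz)
    if roi is not None:
        stack = stack.crop(roi)
    return stack


# ---------------------------------------------------------------------------
# bout tables
# ---------------------------------------------------------------------------

def _check_bout_frame(table: pd.DataFrame) -> None:
    if (table["start_frame"] < 0).any():
        raise BoutTableError("negative start_frame")
    if (table["start_frame"] >= table["end_frame"]).any():
        bad = table[table["start_frame"] >= table["end_frame"]]
        raise BoutTableError(
            f"empty or inverted interval(s), e.g. row {bad.index[0]}: "
            f"[{bad['start_frame'].iloc[0]}, {bad['end_frame'].iloc[0]})"
        )


def normalize_bout_table(table: pd.DataFrame, warn: bool = True) -> pd.DataFrame:
    """Sort and merge overlapping/touching intervals per (segment, annotator, label).

    Intervals are half-open, so (0, 10) and (10, 20) merge to (0, 20).
    Emits a warning when merging actually collapses rows.
    """
    _check_bout_frame(table)
    out = []
    n_in = len(table)
    for (seg, ann, lab), grp in table.groupby(
        ["segment_id", "annotator_id", "label"], sort=True
    ):
        ivals = sorted(zip(grp["start_frame"], grp["end_frame"]))
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            out.append((seg, ann, int(s), int(e), lab))
    result = pd.DataFrame(out, columns=BOUT_COLUMNS)
    if warn and len(result) < n_in:
        warnings.warn(
            f"merged {n_in - len(result)} overlapping bout interval(s)", stacklevel=2
        )
    return result


def read_bout_table(path: str | Path) -> pd.DataFrame:
    """Read a bout CSV; intervals are normalized (merged) on the way in."""
    table = pd.read_csv(path)
    missing = set(BOUT_COLUMNS) - set(table.columns)
    if missing:
        raise BoutTableError(f"bout table missing column(s): {sorted(missing)}")
    table = table[BOUT_COLUMNS].copy()
    table["start_frame"] = table["start_frame"].astype(int)
    table["end_frame"] = table["end_frame"].astype(int)
    return normalize_bout_table(table)


def write_bout_table(table: pd.DataFrame, path: str | Path) -> None:
    _check_bout_frame(table)
    table[BOUT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# activity tables
# ---------------------------------------------------------------------------

_ACTIVITY_REQUIRED = ["timestamp", "cage_id", "day_of_recording"]


def read_activity(path: str | Path, schedule: LightSchedule | None = None) -> pd.DataFrame:
    """Read an activity CSV and annotate zeitgeber time and phase.

    Expected columns: ``timestamp`` (ISO-8601), ``cage_id``,
    ``day_of_recording``, and either planar position (``x_mm``, ``y_mm``,
    with ``mouse_id``) or cage-level ``climbing_s``. Timestamps must be
    non-decreasing within a cage.
    """
    schedule = schedule or LightSchedule()
    df = pd.read_csv(path)
    missing = set(_ACTIVITY_REQUIRED) - set(df.columns)
    if missing:
        raise ActivityError(f"activity table missing column(s): {sorted(missing)}")
    has_pos = {"x_mm", "y_mm"} <= set(df.columns)
    has_climb = "climbing_s" in df.columns
    if not (has_pos or has_climb):
        raise ActivityError("activity table needs (x_mm, y_mm) or climbing_s")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ActivityError(f"unparseable timestamps: {exc}") from exc
    for cage, grp in df.groupby("cage_id"):
        if not grp["timestamp"].is_monotonic_increasing:
            raise ActivityError(f"timestamps not non-decreasing within cage {cage!r}")
    if has_climb and (df["climbing_s"].dropna() < 0).any():
        raise ActivityError("climbing_s must be non-negative")
    df["zt_hours"] = [zeitgeber_hours(t, schedule) for t in df["timestamp"]]
    df["phase"] = [schedule.phase_of_zt(z) for z in df["zt_hours"]]
    return df


def write_activity(df: pd.DataFrame, path: str | Path) -> None:
    out = df.drop(columns=[c for c in ("zt_hours", "phase") if c in df.columns])
    out.to_csv(path, index=False)
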