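"""Bout intervals <-> frame labels, annotator consensus, frames -> seconds.

Human scorers annotate climbing as bouts (half-open frame intervals); the
classifier and all metrics work on per-frame binary labels. A gold standard
is built from several annotators: the majority rule labels a frame climbing
when more than half of the annotators marked it, the "any" rule when at
least one did (the latter is what the training labels use, so that no
example of climbing is missed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BOUT_COLUMNS, BoutTableError

__all__ = [
    "FrameLabelSeries",
    "bouts_to_labels",
    "labels_to_bouts",
    "consensus",
    "frames_to_seconds",
]

#: frame duration implied by 25 frames/s recording
DEFAULT_FRAME_DURATION_MS = 40.0


@dataclass
class FrameLabelSeries:
    """Binary per-frame labels (1 = climbing) for one video segment."""

    segment_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D sequence")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    @property
    def n_frames(self) -> int:
        return self.labels.size

    def __len__(self) -> int:
        return self.labels.size


def bouts_to_labels(
    table: pd.DataFrame,
    annotator_id: str,
    segment_id: str,
    n_frames: int,
    label: str = "climbing",
) -> FrameLabelSeries:
    """Paint the annotator's bouts for one segment onto a frame-label series.

    ``labels[f] == 1`` iff frame ``f`` lies inside some bout (half-open
    intervals). Bouts must fit inside ``[0, n_frames)``.
    """
    sel = table[
        (table["annotator_id"] == annotator_id)
        & (table["segment_id"] == segment_id)
        & (table["label"] == label)
    ]
    labels = np.zeros(n_frames, dtype=np.int8)
    for s, e in zip(sel["start_frame"], sel["end_frame"]):
        if s < 0 or e > n_frames:
            raise BoutTableError(
                f"bout [{s}, {e}) outside the segment's [0, {n_frames}) range"
            )
        labels[s:e] = 1
    return FrameLabelSeries(segment_id, labels)


def labels_to_bouts(
    series: FrameLabelSeries,
    annotator_id: str = "auto",
    label: str = "climbing",
) -> pd.DataFrame:
    """Maximal runs of 1s as half-open bout rows (inverse of bouts_to_labels)."""
    x = np.concatenate([[0], series.labels, [0]])
    starts = np.flatnonzero(np.diff(x) == 1)
    ends = np.flatnonzero(np.diff(x) == -1)
    rows = [
        (series.segment_id, annotator_id, int(s), int(e), label)
        for s, e in zip(starts, ends)
    ]
    return pd.DataFrame(rows, columns=BOUT_COLUMNS)


def consensus(
    series_by_annotator: list[FrameLabelSeries],
    rule: str = "majority",
    tie: str = "negative",
) -> FrameLabelSeries:
    """Merge >=1 annotators' frame labels into a single gold standard.

    rule="majority"
        Frame is climbing iff strictly more than half of the annotators
        marked it. With an even annotator count exact ties are resolved by
        ``tie``: "negative" (default, conservative) -> non-climbing,
        "positive" -> climbing; passing ``tie=None`` makes an even count
        an error.
    rule="any"
        Frame is climbing iff at least one annotator marked it.
    """
    if not series_by_annotator:
        raise ValueError("need at least one annotator series")
    lengths = {len(s) for s in series_by_annotator}
    if len(lengths) > 1:
        raise ValueError(f"annotator series lengths differ: {sorted(lengths)}")
    seg = series_by_annotator[0].segment_id
    votes = np.sum([s.labels for s in series_by_annotator], axis=0)
    n = len(series_by_annotator)
    if rule == "any":
        return FrameLabelSeries(seg, (votes >= 1).astype(np.int8))
    if rule == "majority":
        if n % 2 == 0 and tie is None:
            raise ValueError(
                f"majority rule with an even annotator count ({n}) needs a tie rule"
            )
        out = (votes * 2 > n).astype(np.int8)
        if n % 2 == 0 and tie == "positive":
            out |= (votes * 2 == n).astype(np.int8)
        return FrameLabelSeries(seg, out)
    raise ValueError(f"unknown consensus rule {rule!r}")


def frames_to_seconds(
    n_frames: int | np.ndarray,
    frame_duration_ms: float = DEFAULT_FRAME_DURATION_MS,
) -> float | np.ndarray:
    """Seconds of behaviour for a frame count: ``n_frames * 40 / 1000`` at 25 fps."""
    arr = np.asarray(n_frames)
    if (arr < 0).any():
        raise ValueError("frame counts must be non-negative")
    out = arr * frame_duration_ms / 1000.0
    return float(out) if np.isscalar(n_frames) or arr.ndim == 0 else out
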