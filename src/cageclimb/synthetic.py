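"""Seeded generators for synthetic test substrate.

Three generators emulate the data the climbing pipeline consumes:

* :func:`generate_video` - grayscale home-cage-like frame stacks with
  discrete climbing bouts: during a bout a high-contrast textured blob
  oscillates inside the cage-lid ROI; a floor distractor moves outside the
  ROI throughout; pixel noise on top. Gold bouts are exactly the frames
  where the climb texture is active.
* :func:`simulate_annotators` - imperfect human annotators: Gaussian
  boundary jitter, per-bout misses, Poisson false bouts.
* :func:`generate_activity` - per-cage 6-min-binned activity with a
  biphasic, dark-dominant circadian baseline, sex/age multipliers, a
  genotype deficit confined to the end-of-dark window, cage random
  intercepts, day-of-recording random slopes, and observation noise
  (both a distance-like and a climbing-like channel).

All generators are pure functions of (scenario, seed): the same scenario
with the same seed reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotations import FrameLabelSeries, labels_to_bouts
from .ethogram import WINDOWS, bins_per_day
from .io_formats import BOUT_COLUMNS, FrameStack, RegionOfInterest

__all__ = [
    "VideoScenario",
    "AnnotatorModel",
    "ActivityScenario",
    "generate_video",
    "generate_segments",
    "simulate_annotators",
    "generate_activity",
]


@dataclass(frozen=True)
class VideoScenario:
    """Synthetic cage video with planted climbing bouts.

    Bouts alternate with pauses; durations are gamma-distributed with the
    stated means (defaults: 60 s off, 8 s on, shape 2). The frame size
    and ROI default to a reduced desk scale (96 x 160 ROI in a 120 x 200
    frame); the feature length depends only on the pooling grid, so the
    descriptor keeps its default 16,384 dimensions at any ROI size.
    """

    n_frames: int = 3000
    frame_height: int = 120
    frame_width: int = 200
    roi: RegionOfInterest = field(
        default_factory=lambda: RegionOfInterest(x0=20, y0=8, width=160, height=96)
    )
    frame_rate_hz: float = 25.0
    off_mean_s: float = 60.0
    on_mean_s: float = 8.0
    duration_shape: float = 2.0
    background_level: int = 60
    climb_contrast: int = 160
    blob_size: int = 22
    noise_sd: float = 2.0
    distractor: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        self.roi.validate_within(self.frame_height, self.frame_width)


def _alternating_bouts(rng: np.random.Generator, n_frames: int, fps: float,
                       off_mean_s: float, on_mean_s: float, shape: float) -> np.ndarray:
    """Binary climbing mask from an alternating renewal process (starts off,
    with a random phase into the first off period)."""
    labels = np.zeros(n_frames, dtype=np.int8)
    t = -rng.uniform(0, off_mean_s * fps)  # random phase
    state = 0
    while t < n_frames:
        mean = on_mean_s if state else off_mean_s
        dur = max(1.0, rng.gamma(shape, mean / shape) * fps)
        if state:
            s = int(np.clip(np.ceil(t), 0, n_frames))
            e = int(np.clip(np.ceil(t + dur), 0, n_frames))
            if s < e:
                labels[s:e] = 1
        t += dur
        state = 1 - state
    return labels


def generate_video(scenario: VideoScenario, segment_id: str = "seg0"):
    """Generate one segment; returns ``(FrameStack, gold BoutTable)``.

    The gold table contains exactly the maximal frame runs during which
    the climb texture is rendered.
    """
    rng = np.random.default_rng(scenario.seed)
    n, H, W = scenario.n_frames, scenario.frame_height, scenario.frame_width
    roi = scenario.roi
    fps = scenario.frame_rate_hz

    labels = _alternating_bouts(
        rng, n, fps, scenario.off_mean_s, scenario.on_mean_s, scenario.duration_shape
    )

    base = np.full((H, W), scenario.background_level, dtype=np.float32)
    # static texture so the scene is not flat
    base += rng.normal(0, 4, size=(H, W)).astype(np.float32)

    bs = scenario.blob_size
    blob = rng.uniform(0.4, 1.0, size=(bs, bs)).astype(np.float32)
    phase = rng.uniform(0, 2 * np.pi)
    x_drift = rng.uniform(0.2, 0.6)

    frames = np.empty((n, H, W), dtype=np.uint8)
    for t in range(n):
        img = base.copy()
        if labels[t]:
            # climbing: textured blob oscillating vertically inside the ROI
            cy = roi.y0 + (roi.height - bs) * 0.5 * (
                1 + np.sin(2 * np.pi * t / (0.8 * fps) + phase)
            )
            cx = roi.x0 + (roi.width - bs) * (0.5 + 0.4 * np.sin(x_drift * t / fps))
            y0, x0 = int(cy), int(cx)
            img[y0 : y0 + bs, x0 : x0 + bs] += scenario.climb_contrast * blob
        if scenario.distractor:
            # floor distractor strictly below the ROI
            floor_top = roi.y0 + roi.height
            if floor_top + 10 < H:
                dx = int((W - 12) * (0.5 + 0.5 * np.sin(2 * np.pi * t / (3.0 * fps))))
                img[floor_top + 2 : floor_top + 10, dx : dx + 12] += 120
        if scenario.noise_sd > 0:
            img += rng.normal(0, scenario.noise_sd, size=(H, W)).astype(np.float32)
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)

    stack = FrameStack(frames, fps)
    gold = labels_to_bouts(FrameLabelSeries(segment_id, labels), annotator_id="gold")
    return stack, gold


def generate_segments(scenario: VideoScenario, n_segments: int, seed: int | None = None):
    """Independent segments ``seg0..segN-1`` with per-segment derived seeds."""
    base_seed = scenario.seed if seed is None else seed
    out = []
    for i in range(n_segments):
        sc = replace(scenario, seed=int((base_seed * 100003 + i) % (2**31)))
        out.append(generate_video(sc, segment_id=f"seg{i}"))
    return out


@dataclass(frozen=True)
class AnnotatorModel:
    """Imperfect human annotator.

    Each gold bout is missed independently with ``miss_probability``;
    surviving bout boundaries are shifted by rounded Gaussian jitter
    (clamped to the segment); spurious bouts arrive as a Poisson process
    at ``false_bouts_per_hour`` with short gamma-distributed durations.
    A zero-noise model reproduces the gold annotation exactly.
    """

    jitter_sd_frames: float = 5.0
    miss_probability: float = 0.1
    false_bouts_per_hour: float = 2.0
    false_bout_mean_s: float = 2.0
    seed: int = 0


def simulate_annotators(
    gold: pd.DataFrame,
    models: list[AnnotatorModel],
    n_frames: int,
    frame_rate_hz: float = 25.0,
) -> pd.DataFrame:
    """Apply annotator models to a gold bout table; one table per model,
    concatenated, with annotator ids ``ann0..annK-1``."""
    out = []
    for a, model in enumerate(models):
        rng = np.random.default_rng(model.seed)
        for seg, grp in gold.groupby("segment_id"):
            labels = np.zeros(n_frames, dtype=np.int8)
            for s, e in zip(grp["start_frame"], grp["end_frame"]):
                if rng.uniform() < model.miss_probability:
                    continue
                if model.jitter_sd_frames > 0:
                    s = s + int(round(rng.normal(0, model.jitter_sd_frames)))
                    e = e + int(round(rng.normal(0, model.jitter_sd_frames)))
                s, e = max(0, s), min(n_frames, e)
                if s < e:
                    labels[s:e] = 1
            hours = n_frames / frame_rate_hz / 3600.0
            for _ in range(rng.poisson(model.false_bouts_per_hour * hours)):
                dur = max(1, int(rng.gamma(2.0, model.false_bout_mean_s / 2.0)
                                 * frame_rate_hz))
                s = int(rng.integers(0, n_frames))
                labels[s : min(n_frames, s + dur)] = 1
            out.append(labels_to_bouts(FrameLabelSeries(seg, labels),
                                       annotator_id=f"ann{a}"))
    if not out:
        return pd.DataFrame(columns=BOUT_COLUMNS)
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class ActivityScenario:
    """Cage-level circadian activity with group structure.

    Per cage and 6-min bin the expected activity is
    ``baseline(phase) * sex_mult * age_mult * genotype_mult(bin)`` where
    the genotype deficit multiplier applies only to hemizygous cages and
    only within the end-of-dark window (ZT 23.5-24); on top come a cage
    random intercept, a cage-specific day slope (numeric day 1..3) and
    iid observation noise, floored at 0. Units are arbitrary activity
    counts per bin; both a distance-like and a climbing-like channel are
    emitted with proportional baselines.
    """

    dark_baseline: float = 1000.0
    light_baseline: float = 300.0
    female_multiplier: float = 1.3
    old_multiplier: float = 0.8
    genotype_deficit: float = 0.5  # Hemi activity multiplier in end_of_dark
    cage_intercept_sd: float = 40.0
    day_slope_sd: float = 15.0
    noise_sd: float = 60.0
    climbing_scale: float = 0.1  # climbing channel = scale * distance channel mean
    n_cages_per_group: int = 3
    n_days: int = 3
    bin_length_min: float = 6.0
    ages: tuple[str, ...] = ("young", "old")
    genotypes: tuple[str, ...] = ("WT", "Hemi")
    sexes: tuple[str, ...] = ("F", "M")
    seed: int = 0


def generate_activity(scenario: ActivityScenario) -> pd.DataFrame:
    """Tidy per-bin activity table (one row per cage x day x bin).

    Columns: cage_id, Age, Genotype, Sex, day_of_recording, bin_start_zt,
    phase, distance_mm, climbing_s.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    nb = bins_per_day(sc.bin_length_min)
    step = sc.bin_length_min / 60.0
    bin_starts = np.arange(nb) * step
    dark = bin_starts >= 12.0
    eod_lo, eod_hi = WINDOWS["end_of_dark"]
    in_eod = (bin_starts >= eod_lo - 1e-9) & (bin_starts < eod_hi - 1e-9)

    rows = []
    cage_no = 0
    for age in sc.ages:
        for geno in sc.genotypes:
            for sex in sc.sexes:
                for _ in range(sc.n_cages_per_group):
                    cage_id = f"cage{cage_no:02d}"
                    cage_no += 1
                    intercept = rng.normal(0, sc.cage_intercept_sd)
                    slope = rng.normal(0, sc.day_slope_sd)
                    base = np.where(dark, sc.dark_baseline, sc.light_baseline)
                    mult = np.ones(nb)
                    if sex == "F":
                        mult *= sc.female_multiplier
                    if age == "old":
                        mult *= sc.old_multiplier
                    geno_mult = np.where(
                        in_eod & (geno == "Hemi"), sc.genotype_deficit, 1.0
                    )
                    mean = base * mult * geno_mult
                    for day in range(1, sc.n_days + 1):
                        noise = rng.normal(0, sc.noise_sd, size=nb)
                        dist = np.maximum(0.0, mean + intercept + slope * day + noise)
                        climb = np.maximum(
                            0.0,
                            sc.climbing_scale
                            * (mean + intercept + slope * day)
                            + rng.normal(0, sc.climbing_scale * sc.noise_sd, size=nb),
                        )
                        rows.append(
                            pd.DataFrame(
                                {
                                    "cage_id": cage_id,
                                    "Age": age,
                                    "Genotype": geno,
                                    "Sex": sex,
                                    "day_of_recording": day,
                                    "bin_start_zt": bin_starts,
                                    "phase": np.where(dark, "dark", "light"),
                                    "distance_mm": dist,
                                    "climbing_s": climb,
                                }
                            )
                        )
    return pd.concat(rows, ignore_index=True)
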