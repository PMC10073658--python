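"""Validation of automated against human annotation.

Two views: frame-level accuracy (overall plus per-class recalls against a
gold standard) and agreement of climbing time aggregated into fixed-length
time bins (Spearman rank correlation between automated and human seconds
per bin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats as sps

from .annotations import DEFAULT_FRAME_DURATION_MS, FrameLabelSeries, frames_to_seconds

__all__ = ["FrameMetrics", "BinAgreement", "frame_metrics", "binned_agreement"]


@dataclass
class FrameMetrics:
    """Frame-by-frame confusion summary.

    ``accuracy == prevalence * recall_climbing +
    (1 - prevalence) * recall_nonclimbing`` holds as an exact identity
    (counts are combined with rational arithmetic before float conversion).
    Recalls are ``None`` when the corresponding gold class is absent.
    """

    accuracy: float
    recall_climbing: float | None
    recall_nonclimbing: float | None
    prevalence: float
    n_frames: int


def _labels(x) -> np.ndarray:
    if isinstance(x, FrameLabelSeries):
        return x.labels
    return np.asarray(x).ravel()


def frame_metrics(pred, gold) -> FrameMetrics:
    """Accuracy, per-class recalls and gold prevalence over all frames."""
    p, g = _labels(pred), _labels(gold)
    if p.size != g.size:
        raise ValueError(f"length mismatch: {p.size} predicted vs {g.size} gold frames")
    if p.size == 0:
        raise ValueError("empty label series")
    n = int(p.size)
    n_pos = int(np.sum(g == 1))
    n_neg = n - n_pos
    tp = int(np.sum((g == 1) & (p == 1)))
    tn = int(np.sum((g == 0) & (p == 0)))
    acc = Fraction(tp + tn, n)
    rec_c = Fraction(tp, n_pos) if n_pos else None
    rec_n = Fraction(tn, n_neg) if n_neg else None
    return FrameMetrics(
        accuracy=float(acc),
        recall_climbing=None if rec_c is None else float(rec_c),
        recall_nonclimbing=None if rec_n is None else float(rec_n),
        prevalence=float(Fraction(n_pos, n)),
        n_frames=n,
    )


@dataclass
class BinAgreement:
    """Rank agreement of per-bin climbing seconds, automated vs human."""

    bin_length_s: float
    auto_s: np.ndarray
    human_s: np.ndarray
    spearman_rho: float
    p_value: float
    n_bins: int


def _bin_seconds(labels: np.ndarray, frames_per_bin: int, n_bins: int,
                 frame_duration_ms: float) -> np.ndarray:
    counts = labels[: n_bins * frames_per_bin].reshape(n_bins, frames_per_bin).sum(axis=1)
    return frames_to_seconds(counts, frame_duration_ms)


def binned_agreement(
    pred,
    gold,
    bin_length_s: float = 300.0,
    frame_duration_ms: float = DEFAULT_FRAME_DURATION_MS,
    exact_p: bool = False,
) -> BinAgreement:
    """Spearman rho between automated and human climbing seconds per bin.

    Both series are cut into ``bin_length_s`` bins (default 5 min); a
    trailing partial bin is dropped with a warning. Ties get average
    ranks; the two-sided p-value uses the asymptotic t approximation, or
    an exact permutation p for ``n_bins <= 10`` when ``exact_p`` is set.
    At least 3 complete bins are required.
    """
    p, g = _labels(pred), _labels(gold)
    if p.size != g.size:
        raise ValueError(f"length mismatch: {p.size} vs {g.size} frames")
    frames_per_bin = int(round(bin_length_s * 1000.0 / frame_duration_ms))
    if frames_per_bin <= 0:
        raise ValueError("bin shorter than one frame")
    n_bins = p.size // frames_per_bin
    if p.size % frames_per_bin:
        warnings.warn(
            f"dropping trailing partial bin of {p.size % frames_per_bin} frames",
            stacklevel=2,
        )
    if n_bins < 3:
        raise ValueError(f"need >= 3 complete bins, got {n_bins}")
    auto_s = _bin_seconds(p, frames_per_bin, n_bins, frame_duration_ms)
    human_s = _bin_seconds(g, frames_per_bin, n_bins, frame_duration_ms)
    if exact_p and n_bins > 10:
        raise ValueError("exact permutation p only supported for n_bins <= 10")
    if np.ptp(auto_s) == 0 or np.ptp(human_s) == 0:
        # constant series: rho undefined; report 0 with p = 1
        rho, pval = 0.0, 1.0
    elif exact_p:
        res = sps.permutation_test(
            (auto_s,),
            lambda x: sps.spearmanr(x, human_s).statistic,
            permutation_type="pairings",
            n_resamples=np.inf,
            alternative="two-sided",
        )
        rho = float(sps.spearmanr(auto_s, human_s).statistic)
        pval = float(res.pvalue)
    else:
        rho, pval = sps.spearmanr(auto_s, human_s)
        rho, pval = float(rho), float(pval)
    return BinAgreement(
        bin_length_s=float(bin_length_s),
        auto_s=auto_s,
        human_s=human_s,
        spearman_rho=rho,
        p_value=pval,
        n_bins=int(n_bins),
    )
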