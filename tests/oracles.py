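"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by the most direct route possible
(per-pixel triple loops, explicit window scans, literal formulas) and is
kept deliberately separate from the library's vectorised code paths.
"""

from __future__ import annotations

import numpy as np


def ltp_oracle_feature(frames: np.ndarray, roi, t: int, params) -> np.ndarray:
    """Per-pixel triple-loop LTP descriptor (exact integer arithmetic)."""
    y0, x0, w, h = roi.y0, roi.x0, roi.width, roi.height
    f = frames[:, y0 : y0 + h, x0 : x0 + w].astype(np.int64)
    ph, gap = params.patch_half, params.temporal_gap
    m = params.patch_half + params.neighbor_radius
    offsets = params.offsets
    ch = max(h // params.grid_rows, 1)
    cw = max(w // params.grid_cols, 1)
    hist = np.zeros(params.dimension, dtype=np.float64)

    def patch(s, r, c):
        return f[s, r - ph : r + ph + 1, c - ph : c + ph + 1]

    for r in range(m, h - m):
        for c in range(m, w - m):
            b_pos = b_neg = 0
            p0 = patch(t, r, c)
            for i, (dr, dc) in enumerate(offsets):
                d_minus = int(((p0 - patch(t - gap, r + dr, c + dc)) ** 2).sum())
                d_plus = int(((p0 - patch(t + gap, r + dr, c + dc)) ** 2).sum())
                if d_minus - d_plus > params.ssd_threshold:
                    b_pos |= 1 << i
                elif d_plus - d_minus > params.ssd_threshold:
                    b_neg |= 1 << i
            cell = (
                min(r // ch, params.grid_rows - 1) * params.grid_cols
                + min(c // cw, params.grid_cols - 1)
            )
            hist[cell * 512 + b_pos] += 1
            hist[cell * 512 + 256 + b_neg] += 1
    if params.normalize == "l1":
        blocks = hist.reshape(-1, 256)
        sums = blocks.sum(axis=1, keepdims=True)
        np.divide(blocks, sums, out=blocks, where=sums > 0)
        hist = blocks.ravel()
    return hist


def ltp_oracle_trits(frames: np.ndarray, roi, t: int, params):
    """Per-pixel (b_pos, b_neg) grids, uncoded border left 0."""
    y0, x0, w, h = roi.y0, roi.x0, roi.width, roi.height
    f = frames[:, y0 : y0 + h, x0 : x0 + w].astype(np.int64)
    ph, gap = params.patch_half, params.temporal_gap
    m = params.patch_half + params.neighbor_radius
    b_pos = np.zeros((h, w), dtype=np.uint8)
    b_neg = np.zeros((h, w), dtype=np.uint8)
    for r in range(m, h - m):
        for c in range(m, w - m):
            p0 = f[t, r - ph : r + ph + 1, c - ph : c + ph + 1]
            for i, (dr, dc) in enumerate(params.offsets):
                pm = f[t - gap, r + dr - ph : r + dr + ph + 1, c + dc - ph : c + dc + ph + 1]
                pp = f[t + gap, r + dr - ph : r + dr + ph + 1, c + dc - ph : c + dc + ph + 1]
                d_minus = int(((p0 - pm) ** 2).sum())
                d_plus = int(((p0 - pp) ** 2).sum())
                if d_minus - d_plus > params.ssd_threshold:
                    b_pos[r, c] |= 1 << i
                elif d_plus - d_minus > params.ssd_threshold:
                    b_neg[r, c] |= 1 << i
    return b_pos, b_neg


def vote_oracle(raw, k: int, theta: float) -> np.ndarray:
    """Literal window scan of the temporal vote."""
    x = np.asarray(raw).ravel()
    n = x.size
    out = np.zeros(n, dtype=np.int8)
    for t in range(n):
        lo, hi = max(0, t - k), min(n - 1, t + k)
        window = x[lo : hi + 1]
        out[t] = 1 if window.sum() > theta * window.size else 0
    return out


def consensus_oracle(label_arrays, rule: str) -> np.ndarray:
    """Per-frame counting of annotator votes."""
    arrs = [np.asarray(a) for a in label_arrays]
    n_ann = len(arrs)
    out = np.zeros(arrs[0].size, dtype=np.int8)
    for f in range(arrs[0].size):
        votes = sum(int(a[f]) for a in arrs)
        if rule == "any":
            out[f] = 1 if votes >= 1 else 0
        else:
            out[f] = 1 if votes * 2 > n_ann else 0
    return out


def confusion_oracle(pred, gold):
    """Hand-counted confusion entries -> (accuracy, recall_c, recall_n, prev)."""
    p, g = np.asarray(pred), np.asarray(gold)
    tp = fn = tn = fp = 0
    for a, b in zip(p, g):
        if b == 1 and a == 1:
            tp += 1
        elif b == 1:
            fn += 1
        elif a == 0:
            tn += 1
        else:
            fp += 1
    n = len(p)
    acc = (tp + tn) / n
    rec_c = tp / (tp + fn) if (tp + fn) else None
    rec_n = tn / (tn + fp) if (tn + fp) else None
    return acc, rec_c, rec_n, (tp + fn) / n


def rank_average(x) -> np.ndarray:
    """Average ranks by explicit sorting (1-based)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Rank-then-Pearson Spearman rho."""
    rx, ry = rank_average(x), rank_average(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom) if denom > 0 else np.nan


def bh_oracle(pvals) -> np.ndarray:
    """Literal step-up rule: p_adj[(i)] = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(1.0, m * p[order[j]] / (j + 1)) for j in range(i, m)
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]
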