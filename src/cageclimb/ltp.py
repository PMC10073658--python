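"""Local trinary pattern (LTP) motion descriptor.

The descriptor characterises motion in the cage-lid region of interest as a
fixed-length histogram vector, one per video frame. For every coded pixel
``p`` and each of the 8 neighbour offsets ``n_i`` at ``neighbor_radius``
(ordered clockwise from top-left; bit ``i`` of the byte codes offset ``i``):

* ``d_minus_i`` = sum of squared differences (SSD) between the patch
  centred at ``p`` in frame ``t`` and the patch centred at ``p + n_i`` in
  frame ``t - gap``;
* ``d_plus_i`` = the same SSD computed against frame ``t + gap``;
* the trit is +1 when ``d_minus_i - d_plus_i > tau``, -1 when
  ``d_plus_i - d_minus_i > tau``, otherwise 0.

The +1 trits form one byte (``b_pos``), the -1 trits another (``b_neg``);
the two bytes have disjoint set bits by construction. The ROI is tiled by a
``grid_cols x grid_rows`` cell grid and each cell contributes a 256-bin
histogram of ``b_pos`` followed by one of ``b_neg``, so the feature length
is ``grid_cols * grid_rows * 512`` — exactly 16,384 with the default 8 x 4
grid, whatever the ROI size in pixels.

Pixels within ``patch_half + neighbor_radius`` of the ROI border are not
coded (their own patch or a neighbour patch would leave the ROI) and do not
enter any histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .io_formats import FrameStack, RegionOfInterest

__all__ = [
    "LTPParams",
    "FeatureVector",
    "NEIGHBOR_OFFSETS_UNIT",
    "trit_codes",
    "coded_margin",
    "ltp_feature",
    "ltp_features_for_segment",
    "ltp_feature_matrix",
]

#: the 8 neighbour offsets at unit radius, (row, col), clockwise from top-left;
#: bit i of a code byte corresponds to offset i
NEIGHBOR_OFFSETS_UNIT: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


@dataclass(frozen=True)
class LTPParams:
    """Configuration of the LTP descriptor.

    patch_half
        SSD patches are ``(2*patch_half+1)**2`` pixels around a pixel.
    neighbor_radius
        Distance of the 8 neighbour offsets, in pixels.
    temporal_gap
        Frame offset between the centre frame and its past/future
        comparison frames.
    ssd_threshold
        Dead zone ``tau`` (squared-intensity units) inside which a trit
        is 0 rather than +/-1.
    grid_cols, grid_rows
        Pooling grid over the ROI; feature length is
        ``grid_cols * grid_rows * 512``.
    normalize
        ``"l1"`` scales each 256-bin histogram to sum to 1 (empty cells
        stay all-zero); ``"none"`` keeps raw counts.
    """

    patch_half: int = 1
    neighbor_radius: int = 2
    temporal_gap: int = 2
    ssd_threshold: float = 0.0
    grid_cols: int = 8
    grid_rows: int = 4
    normalize: str = "l1"

    def __post_init__(self) -> None:
        if self.patch_half < 0:
            raise ValueError("patch_half must be >= 0")
        if self.neighbor_radius < 1:
            raise ValueError("neighbor_radius must be >= 1")
        if self.temporal_gap < 1:
            raise ValueError("temporal_gap must be >= 1")
        if self.ssd_threshold < 0:
            raise ValueError("ssd_threshold must be non-negative")
        if self.grid_cols < 1 or self.grid_rows < 1:
            raise ValueError("pooling grid must have at least one cell")
        if self.normalize not in ("l1", "none"):
            raise ValueError("normalize must be 'l1' or 'none'")

    @property
    def dimension(self) -> int:
        return self.grid_cols * self.grid_rows * 512

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        r = self.neighbor_radius
        return tuple((dr * r, dc * r) for dr, dc in NEIGHBOR_OFFSETS_UNIT)


@dataclass
class FeatureVector:
    """One LTP descriptor: non-negative values plus its frame index."""

    values: np.ndarray
    frame_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


def coded_margin(params: LTPParams) -> int:
    """Border width (pixels) inside the ROI whose pixels are not coded."""
    return params.patch_half + params.neighbor_radius


def _roi_frame(stack: FrameStack, roi: RegionOfInterest, t: int) -> np.ndarray:
    return roi.crop(stack.frames[t]).astype(np.int64)


def _box_sum(sq: np.ndarray, half: int) -> np.ndarray:
    """Exact integer box sum over the (2*half+1)^2 window centred per pixel.

    Integer arithmetic keeps SSD comparisons exact, so equal SSDs yield a
    0 trit deterministically. Border entries (windows leaving the array)
    are 0 and must be masked by the caller via :func:`coded_margin`.
    """
    if half == 0:
        return sq
    return _box1d(_box1d(sq, half, 0), half, 1)


def _box1d(a: np.ndarray, half: int, axis: int) -> np.ndarray:
    n = a.shape[axis]

    def sl(s, e):
        return tuple(slice(s, e) if ax == axis else slice(None) for ax in range(a.ndim))

    c = np.cumsum(a, axis=axis, dtype=np.int64)
    out = np.zeros_like(c)
    out[sl(half, n - half)] = c[sl(2 * half, n)]
    out[sl(half + 1, n - half)] -= c[sl(0, n - 2 * half - 1)]
    return out


def _shifted_ssd(center: np.ndarray, other: np.ndarray, offset: tuple[int, int],
                 patch_half: int) -> np.ndarray:
    """SSD between the patch at p in `center` and the patch at p+offset in `other`.

    Full-ROI map; entries whose patches leave the ROI carry garbage
    (wrap-around) and must be masked by the caller via :func:`coded_margin`.
    """
    dr, dc = offset
    shifted = np.roll(np.roll(other, -dr, axis=0), -dc, axis=1)
    return _box_sum((center - shifted) ** 2, patch_half)


def trit_codes(
    stack: FrameStack,
    roi: RegionOfInterest,
    t: int,
    params: LTPParams = LTPParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Compute the (b_pos, b_neg) code bytes for frame ``t``.

    Returns two uint8 arrays of the ROI shape. Pixels inside the
    :func:`coded_margin` border are not coded and are left 0; callers that
    histogram codes must exclude them (as :func:`ltp_feature` does).
    """
    gap = params.temporal_gap
    if t < gap or t > stack.n_frames - 1 - gap:
        raise IndexError(
            f"frame {t} outside the codable range [{gap}, {stack.n_frames - 1 - gap}]"
        )
    roi.validate_within(*stack.shape)
    center = _roi_frame(stack, roi, t)
    past = _roi_frame(stack, roi, t - gap)
    future = _roi_frame(stack, roi, t + gap)

    h, w = center.shape
    b_pos = np.zeros((h, w), dtype=np.uint8)
    b_neg = np.zeros((h, w), dtype=np.uint8)
    for i, off in enumerate(params.offsets):
        d_minus = _shifted_ssd(center, past, off, params.patch_half)
        d_plus = _shifted_ssd(center, future, off, params.patch_half)
        diff = d_minus - d_plus
        bit = np.uint8(1 << i)
        b_pos |= np.where(diff > params.ssd_threshold, bit, 0).astype(np.uint8)
        b_neg |= np.where(-diff > params.ssd_threshold, bit, 0).astype(np.uint8)

    m = coded_margin(params)
    if 2 * m >= h or 2 * m >= w:
        raise ValueError(
            f"ROI {w}x{h} too small: no pixel survives the {m}-pixel coding margin"
        )
    mask = np.zeros((h, w), dtype=bool)
    mask[m : h - m, m : w - m] = True
    b_pos[~mask] = 0
    b_neg[~mask] = 0
    return b_pos, b_neg


def _cell_index(h: int, w: int, params: LTPParams) -> np.ndarray:
    """Cell id per ROI pixel, cell-major (row, then column); remainder pixels
    when the ROI is not divisible by the grid go to the last row/column."""
    ch = max(h // params.grid_rows, 1)
    cw = max(w // params.grid_cols, 1)
    rows = np.minimum(np.arange(h) // ch, params.grid_rows - 1)
    cols = np.minimum(np.arange(w) // cw, params.grid_cols - 1)
    return rows[:, None] * params.grid_cols + cols[None, :]


def _pooled_histogram(
    b_pos: np.ndarray, b_neg: np.ndarray, params: LTPParams
) -> np.ndarray:
    h, w = b_pos.shape
    m = coded_margin(params)
    cells = _cell_index(h, w, params)
    sl = (slice(m, h - m), slice(m, w - m))
    c = cells[sl].ravel()
    # layout: cell-major, b_pos 256 bins then b_neg 256 bins within each cell
    idx_pos = c * 512 + b_pos[sl].ravel()
    idx_neg = c * 512 + 256 + b_neg[sl].ravel()
    counts = np.bincount(
        np.concatenate([idx_pos, idx_neg]), minlength=params.dimension
    ).astype(np.float64)
    if params.normalize == "l1":
        blocks = counts.reshape(-1, 256)
        sums = blocks.sum(axis=1, keepdims=True)
        np.divide(blocks, sums, out=blocks, where=sums > 0)
        counts = blocks.ravel()
    return counts


def ltp_feature(
    stack: FrameStack,
    roi: RegionOfInterest,
    t: int,
    params: LTPParams = LTPParams(),
) -> FeatureVector:
    """The pooled LTP descriptor of frame ``t`` (length ``params.dimension``)."""
    b_pos, b_neg = trit_codes(stack, roi, t, params)
    return FeatureVector(_pooled_histogram(b_pos, b_neg, params), t)


def _interior_range(stack: FrameStack, params: LTPParams) -> range:
    gap = params.temporal_gap
    if stack.n_frames <= 2 * gap:
        raise ValueError(
            f"stack of {stack.n_frames} frames too short for temporal gap {gap} "
            f"(needs > {2 * gap})"
        )
    return range(gap, stack.n_frames - gap)


def ltp_feature_matrix(
    stack: FrameStack,
    roi: RegionOfInterest,
    params: LTPParams = LTPParams(),
    sparse_output: bool = True,
):
    """Descriptors for every frame as an ``(n_frames, dimension)`` matrix.

    Interior frames (``gap <= t < n_frames - gap``) are computed directly;
    the first/last ``gap`` boundary frames replicate the nearest interior
    vector so that every frame gets a label downstream. Histograms are
    mostly empty bins, so the default CSR output keeps long segments cheap.
    """
    interior = _interior_range(stack, params)
    gap = params.temporal_gap
    rows = []
    for t in interior:
        dense = _pooled_histogram(*trit_codes(stack, roi, t, params), params)
        if sparse_output:
            (nz,) = np.nonzero(dense)
            rows.append((nz, dense[nz]))
        else:
            rows.append(dense)
    full = [rows[0]] * gap + rows + [rows[-1]] * gap
    if not sparse_output:
        return np.stack(full)
    indptr = np.zeros(len(full) + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([len(nz) for nz, _ in full])
    indices = np.concatenate([nz for nz, _ in full])
    data = np.concatenate([d for _, d in full])
    return sparse.csr_matrix(
        (data, indices, indptr), shape=(len(full), params.dimension)
    )


def ltp_features_for_segment(
    stack: FrameStack,
    roi: RegionOfInterest,
    params: LTPParams = LTPParams(),
) -> list[FeatureVector]:
    """One :class:`FeatureVector` per frame index, boundary frames replicated."""
    mat = ltp_feature_matrix(stack, roi, params, sparse_output=False)
    return [FeatureVector(mat[t], t) for t in range(stack.n_frames)]
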