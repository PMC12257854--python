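"""Fluid-reservoir boundary segmentation.

Detects the lens back surface and the corneal epithelial front surface in a
B-scan as two sub-pixel polylines.  The detector is classical and fully
deterministic: Gaussian ridge enhancement, then a minimum-cost path search
down the columns with a quadratic smoothness penalty on per-column row
increments (dynamic programming), sub-pixel refinement by parabolic fit, and
an ordering constraint (lens anterior to cornea, row 0 = top = anterior).

Frames are first resized to a square 512 x 512 working image; detected
coordinates are mapped back to the original dimensions by the exact inverse
linear transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .errors import SegmentationError

WORK_SIZE = (512, 512)


@dataclass
class BoundaryPair:
    """Sub-pixel boundary rows per column, in original image coordinates."""

    lens_back_rows: np.ndarray
    cornea_front_rows: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.lens_back_rows = np.asarray(self.lens_back_rows, float)
        self.cornea_front_rows = np.asarray(self.cornea_front_rows, float)
        self.valid = np.asarray(self.valid, bool)


@dataclass(frozen=True)
class ResizeTransform:
    """Linear map between working (512 x 512) and original coordinates.

    Pixel centres are aligned: original = (working + 0.5) * scale - 0.5.
    """

    row_scale: float
    col_scale: float

    @property
    def identity(self):
        return self.row_scale == 1.0 and self.col_scale == 1.0

    def to_original(self, row, col):
        return (
            (np.asarray(row, float) + 0.5) * self.row_scale - 0.5,
            (np.asarray(col, float) + 0.5) * self.col_scale - 0.5,
        )

    def to_working(self, row, col):
        return (
            (np.asarray(row, float) + 0.5) / self.row_scale - 0.5,
            (np.asarray(col, float) + 0.5) / self.col_scale - 0.5,
        )


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable detector parameters (pixel units refer to the working image)."""

    smooth_sigma: float = 1.2
    smoothness_weight: float = 0.02  # quadratic penalty per squared row step
    max_step: int = 8  # DP transition window (rows per column)
    min_separation_px: int = 6  # exclusion band around the first ridge
    valid_threshold: float = 0.25  # ridge strength (normalized) for validity
    contrast_min: float = 0.4  # smoothed relative contrast to accept a frame
    max_gap_frac: float = 0.10  # invalid gaps up to this width are interpolated
    min_valid_frac: float = 0.30  # reject frames with less ridge support


DEFAULT_PARAMS = SegmentationParams()


def resize_for_segmentation(frame, work_size=WORK_SIZE):
    """Resize a frame's pixels to the square working size.

    Returns ``(working_image, ResizeTransform)``; the transform maps any
    working (row, col) back to original coordinates exactly.
    """
    pixels = np.asarray(frame.pixels if hasattr(frame, "pixels") else frame, float)
    if pixels.ndim != 2 or pixels.size == 0:
        raise SegmentationError("frame must be a non-empty 2-D image")
    rows, cols = pixels.shape
    tr = ResizeTransform(rows / work_size[0], cols / work_size[1])
    if (rows, cols) == tuple(work_size):
        return pixels, tr
    work = resize(pixels, work_size, order=1, mode="edge", anti_aliasing=rows > work_size[0])
    return work, tr


def min_cost_path(cost, smoothness_weight, max_step):
    """Minimum-cost left-to-right path through ``cost`` (one row per column).

    Per-column row steps are limited to ``max_step`` with an additional
    quadratic penalty weight * step^2.  Equal-cost ties resolve to the
    smaller row.  Returns integer row indices per column.
    """
    rows, cols = cost.shape
    W = int(max_step)
    # window index k corresponds to previous row r - W + k (ascending), so
    # argmin's first-occurrence rule ties toward the smaller previous row
    pen = smoothness_weight * (W - np.arange(2 * W + 1, dtype=float)) ** 2
    big = 1e18
    D = cost[:, 0].astype(float)
    back = np.empty((rows, cols), dtype=np.uint8)
    pad = np.full(rows + 2 * W, big)
    win = np.lib.stride_tricks.sliding_window_view(pad, 2 * W + 1)  # view
    ar = np.arange(rows)
    for c in range(1, cols):
        pad[W:W + rows] = D
        tot = win + pen
        k = np.argmin(tot, axis=1)
        D = tot[ar, k] + cost[:, c]
        back[:, c] = k
    path = np.empty(cols, dtype=int)
    path[-1] = int(np.argmin(D))
    for c in range(cols - 1, 0, -1):
        path[c - 1] = path[c] - W + int(back[path[c], c])
    return path


def _subpixel(smoothed, path):
    """Parabolic sub-pixel refinement of integer ridge rows."""
    rows, cols = smoothed.shape
    r0 = np.clip(path, 1, rows - 2)
    c = np.arange(cols)
    vm = smoothed[r0 - 1, c]
    v0 = smoothed[r0, c]
    vp = smoothed[r0 + 1, c]
    denom = vm - 2 * v0 + vp
    delta = np.zeros_like(denom)
    ok = np.abs(denom) > 1e-12
    delta[ok] = 0.5 * (vm - vp)[ok] / denom[ok]
    return r0 + np.clip(delta, -0.5, 0.5)


def _fill_small_gaps(rows_a, rows_b, valid, max_gap):
    """Interpolate invalid runs up to ``max_gap`` columns wide (in place)."""
    n = valid.size
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        return valid
    filled = valid.copy()
    c = idx[0]
    for nxt in idx[1:]:
        gap = nxt - c - 1
        if 0 < gap <= max_gap:
            span = np.arange(c + 1, nxt)
            for arr in (rows_a, rows_b):
                arr[span] = np.interp(span, [c, nxt], [arr[c], arr[nxt]])
            filled[span] = True
        c = nxt
    return filled


def detect_boundaries(image, params=DEFAULT_PARAMS):
    """Detect the two reservoir boundaries in a working image.

    Returns a :class:`BoundaryPair` in working coordinates.  Raises
    :class:`SegmentationError` when fewer than two ridges are detectable.
    """
    img = np.asarray(image, float)
    smoothed = gaussian_filter(img, params.smooth_sigma)
    bg = float(np.median(smoothed))
    peak = float(np.percentile(smoothed, 99.9))
    if peak - bg <= 0 or (peak - bg) / max(peak + bg, 1e-12) < params.contrast_min:
        raise SegmentationError("no boundary ridges detectable (flat image)")
    norm = (smoothed - bg) / (peak - bg)

    # search only the contiguous span of columns with ridge evidence; the
    # path model cannot say anything useful where there is no ridge
    has_ridge = norm.max(axis=0) >= params.valid_threshold
    idx = np.nonzero(has_ridge)[0]
    if idx.size < 2:
        raise SegmentationError("no boundary ridges detectable")
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    sub_norm = norm[:, lo:hi]
    sub_smoothed = smoothed[:, lo:hi]

    cost = -sub_norm
    p1 = min_cost_path(cost, params.smoothness_weight, params.max_step)
    span_cols = np.arange(hi - lo)
    # second ridge: search strictly above, or strictly below, the first
    # path — the hard one-sided constraint prevents the second path from
    # riding the first ridge's shoulder where the true second ridge is
    # weak.  The side is chosen by ridge evidence; if the evidence is
    # ambiguous both sides are searched and the stronger path kept.
    rows_idx = np.arange(img.shape[0])[:, None]
    big = 1e6
    masks = {
        "above": rows_idx >= (p1 - params.min_separation_px)[None, :],
        "below": rows_idx <= (p1 + params.min_separation_px)[None, :],
    }
    evidence = {
        side: float(np.mean(np.where(m, -np.inf, sub_norm).max(axis=0)))
        for side, m in masks.items()
    }
    order = sorted(masks, key=lambda s: -evidence[s])
    ambiguous = abs(evidence[order[0]] - evidence[order[1]]) < 0.1
    candidates = []
    for side in order if ambiguous else order[:1]:
        cost2 = np.where(masks[side], big, cost)
        if np.all(cost2 >= big):
            continue
        pc = min_cost_path(cost2, params.smoothness_weight, params.max_step)
        candidates.append((float(np.mean(sub_norm[pc, span_cols])), pc))
    if not candidates:
        raise SegmentationError("no second boundary ridge detectable")
    p2 = max(candidates, key=lambda c: c[0])[1]
    s1 = _subpixel(sub_smoothed, p1)
    s2 = _subpixel(sub_smoothed, p2)
    strength1 = sub_norm[p1, span_cols]
    strength2 = sub_norm[p2, span_cols]
    n_cols = img.shape[1]
    lens = np.full(n_cols, np.nan)
    cornea = np.full(n_cols, np.nan)
    valid = np.zeros(n_cols, dtype=bool)
    valid[lo:hi] = (strength1 >= params.valid_threshold) & (
        strength2 >= params.valid_threshold
    )
    if np.mean(p1) <= np.mean(p2):
        lens[lo:hi], cornea[lo:hi] = s1, s2
    else:
        lens[lo:hi], cornea[lo:hi] = s2, s1
    # ordering constraint: lens anterior (smaller row) at every valid column
    with np.errstate(invalid="ignore"):
        valid &= lens < cornea

    max_gap = int(params.max_gap_frac * img.shape[1])
    valid = _fill_small_gaps(lens, cornea, valid, max_gap)

    if np.mean(valid) < params.min_valid_frac:
        raise SegmentationError(
            f"only {np.mean(valid):.0%} of columns show two ridges; frame rejected"
        )
    return BoundaryPair(lens, cornea, valid)


def segment_frame(frame, params=DEFAULT_PARAMS, work_size=WORK_SIZE):
    """Segment a frame: resize, detect, map back to original coordinates."""
    work, tr = resize_for_segmentation(frame, work_size)
    pair = detect_boundaries(work, params)
    if tr.identity:
        return pair
    cols_work = np.arange(work_size[1], dtype=float)
    lens_r, cols_orig = tr.to_original(pair.lens_back_rows, cols_work)
    cornea_r, _ = tr.to_original(pair.cornea_front_rows, cols_work)
    # resample per original column by linear interpolation along the polyline
    n_cols = np.asarray(frame.pixels).shape[1]
    co = np.arange(n_cols, dtype=float)
    lens = np.interp(co, cols_orig, lens_r)
    cornea = np.interp(co, cols_orig, cornea_r)
    valid = np.interp(co, cols_orig, pair.valid.astype(float)) > 0.5
    return BoundaryPair(lens, cornea, valid)
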