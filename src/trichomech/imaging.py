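"""Centroid tracking of a bright object in a bright-field image stack.

Replaces the hand-written macro role in the measurement chain: per frame,
the intensity-weighted center of mass of the tracked object (the pipette
tip, imaged as a bright blob) is extracted inside a region of interest, to
sub-pixel precision, and converted to micrometres.

Pixel convention: pixel centers sit at integer coordinates, with the origin
at the center of the top-left pixel, axes (x → column, y → row).  Because
every downstream quantity is a position *difference*, any consistent
convention cancels; this one is stated so traces and images can be overlaid.

Frames in which no pixel rises above threshold are flagged missing (NaN),
never interpolated — fabricated samples would bias the changepoint fits.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from .trajectory import TrackedTrajectory

__all__ = ["track_centroid", "read_tiff_stack", "write_tiff_stack"]


def read_tiff_stack(path) -> np.ndarray:
    import tifffile
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_tiff_stack(path, stack: np.ndarray) -> None:
    import tifffile
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def _frame_centroid(frame: np.ndarray, threshold_mode) -> tuple[float, float]:
    """(x, y) intensity-weighted centroid of above-threshold pixels, px.

    The median of the ROI is subtracted first (flat background estimate for
    a blob occupying a minority of the ROI); the centroid weights are the
    background-subtracted intensities of pixels above threshold.  Returns
    NaNs when nothing rises above threshold.
    """
    f = frame.astype(float)
    f = f - np.median(f)
    np.clip(f, 0.0, None, out=f)
    if threshold_mode == "otsu":
        if np.ptp(f) == 0:
            return (np.nan, np.nan)
        thr = threshold_otsu(f)
    elif np.isscalar(threshold_mode):
        thr = float(threshold_mode)
    else:
        raise ValueError("threshold_mode must be 'otsu' or a number")
    mask = f > thr
    if not mask.any():
        return (np.nan, np.nan)
    w = np.where(mask, f, 0.0)
    total = w.sum()
    rows, cols = np.nonzero(mask)
    cy = float((rows * w[rows, cols]).sum() / total)
    cx = float((cols * w[rows, cols]).sum() / total)
    return (cx, cy)


def track_centroid(stack: np.ndarray, roi: tuple[int, int, int, int] | None = None,
                   threshold_mode="otsu", pixel_size: float = 1.0,
                   frame_rate: float = 1.0, source: str = "") -> TrackedTrajectory:
    """Track the object's center of mass across a stack.

    Parameters
    ----------
    stack : (n_frames, ny, nx) array
    roi : (x0, y0, x1, y1) in pixels, half-open, or None for the full frame.
    threshold_mode : 'otsu' (within-ROI Otsu after median background
        subtraction) or a fixed numeric threshold on the subtracted image.
    pixel_size : μm per pixel.
    frame_rate : Hz; frame i is assigned time i/frame_rate.

    Frames with no above-threshold pixel are flagged missing (NaN position).
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be (n_frames, ny, nx) with >= 1 frame")
    ny, nx = stack.shape[1:]
    if roi is None:
        roi = (0, 0, nx, ny)
    x0, y0, x1, y1 = roi
    if not (0 <= x0 < x1 <= nx and 0 <= y0 < y1 <= ny):
        raise ValueError(f"roi {roi} outside image bounds ({nx} x {ny})")

    n = stack.shape[0]
    xs = np.empty(n)
    ys = np.empty(n)
    for i in range(n):
        cx, cy = _frame_centroid(stack[i, y0:y1, x0:x1], threshold_mode)
        xs[i] = (cx + x0) * pixel_size
        ys[i] = (cy + y0) * pixel_size

    times = np.arange(n) / frame_rate
    if n == 1:
        # TrackedTrajectory requires >= 2 samples; duplicate the frame time
        # is not meaningful, so return a 2-sample trace only for n >= 2.
        raise ValueError("need at least 2 frames to build a trajectory; "
                         "use frame_centroid for single frames")
    return TrackedTrajectory(times, xs, ys, pixel_size=pixel_size,
                             frame_rate=frame_rate, source=source or "track_centroid")


def frame_centroid(frame: np.ndarray, roi=None, threshold_mode="otsu"
                   ) -> tuple[float, float]:
    """Centroid (x, y, px) of a single frame; NaNs if nothing above threshold."""
    frame = np.asarray(frame)
    if roi is not None:
        x0, y0, x1, y1 = roi
        sub = frame[y0:y1, x0:x1]
        cx, cy = _frame_centroid(sub, threshold_mode)
        return cx + x0, cy + y0
    return _frame_centroid(frame, threshold_mode)
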