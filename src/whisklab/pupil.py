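"""Video pupillometry: per-frame pupil diameter by thresholding + circles.

Each grayscale eye frame is contrast-normalized (1st/99th percentiles to
[0, 1]), binarized (automatic between-class-variance threshold by
default), and the dark-region boundary is fed to a circular Hough
transform; the strongest circle gives center and diameter.  Frames with no
confident circle are invalid; short invalid gaps (< 400 ms) are linearly
interpolated.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import erosion
from skimage.transform import hough_circle, hough_circle_peaks
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import PupilTrace

__all__ = ["normalize_frame", "binarize_frame", "detect_pupil",
           "pupil_trace", "PupilDetector"]


def normalize_frame(frame: np.ndarray) -> np.ndarray:
    """Rescale intensities so the 1st/99th percentiles map to [0, 1]."""
    f = np.asarray(frame, dtype=float)
    lo, hi = np.percentile(f, [1, 99])
    if hi <= lo:
        raise ValueError("constant image cannot be normalized")
    return np.clip((f - lo) / (hi - lo), 0.0, 1.0)


def binarize_frame(frame: np.ndarray,
                   threshold: Optional[float] = None) -> np.ndarray:
    """Dark-pixel mask of a normalized frame (automatic threshold default)."""
    f = normalize_frame(frame)
    thr = threshold_otsu(f) if threshold is None else threshold
    return f < thr


def detect_pupil(frame: np.ndarray, radius_range: Tuple[int, int],
                 threshold: Optional[float] = None,
                 confidence_floor: float = 0.4):
    """Locate the pupil in one frame; returns ((x, y), diameter) or None.

    The dark (pupil) region's boundary pixels form the edge map for a
    circular Hough accumulator over ``radius_range``; the strongest circle
    is returned unless its normalized accumulator score falls below
    ``confidence_floor``.
    """
    r_lo, r_hi = radius_range
    if r_hi <= 0 or r_lo >= min(frame.shape) or r_lo > r_hi:
        raise ValueError("radius range must lie within the image")
    try:
        mask = binarize_frame(frame, threshold)
    except ValueError:
        return None
    edges = mask & ~erosion(mask)
    if not edges.any():
        return None
    radii = np.arange(max(int(r_lo), 1), int(r_hi) + 1)
    accum = hough_circle(edges, radii)
    accums, cx, cy, rad = hough_circle_peaks(accum, radii, total_num_peaks=1)
    if accums.size == 0 or accums[0] < confidence_floor:
        return None
    return (float(cx[0]), float(cy[0])), float(2 * rad[0])


def pupil_trace(frames: np.ndarray, frame_rate: float,
                radius_range: Tuple[int, int],
                threshold: Optional[float] = None,
                confidence_floor: float = 0.4,
                max_gap: float = 0.4) -> PupilTrace:
    """Per-frame pupil diameters with interpolation of short dropouts.

    Invalid runs shorter than ``max_gap`` seconds (blinks, detection
    failures) are linearly interpolated but stay flagged invalid; longer
    gaps are left as NaN.  Raises if no frame yields a detection.
    """
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    diam = np.full(n, np.nan)
    centers = np.full((n, 2), np.nan)
    for i in range(n):
        hit = detect_pupil(frames[i], radius_range, threshold,
                           confidence_floor)
        if hit is not None:
            (x, y), d = hit
            diam[i] = d
            centers[i] = (x, y)
    valid = np.isfinite(diam)
    if not valid.any():
        raise ValueError("pupil not detected in any frame")
    max_frames = int(round(max_gap * frame_rate))
    bad = ~valid
    edges = np.flatnonzero(np.diff(np.r_[0, bad.astype(int), 0]))
    good_idx = np.flatnonzero(valid)
    for i0, i1 in zip(edges[::2], edges[1::2]):
        interior = i0 > 0 and i1 < n
        if (i1 - i0) < max_frames and interior:
            diam[i0:i1] = np.interp(np.arange(i0, i1), good_idx,
                                    diam[good_idx])
    return PupilTrace(diameter=diam, frame_rate=frame_rate, center=centers,
                      valid=valid)


class PupilDetector(BaseEstimator, TransformerMixin):
    """Transformer from an eye-frame stack to per-frame pupil diameters.

    Parameters mirror :func:`pupil_trace`.  ``transform`` returns the
    diameter vector; the full :class:`PupilTrace` (centers, validity) is
    stored as ``trace_`` after :meth:`fit`.
    """

    def __init__(self, frame_rate: float = 125.0,
                 radius_range: Tuple[int, int] = (10, 40),
                 threshold: Optional[float] = None,
                 confidence_floor: float = 0.4, max_gap: float = 0.4):
        self.frame_rate = frame_rate
        self.radius_range = radius_range
        self.threshold = threshold
        self.confidence_floor = confidence_floor
        self.max_gap = max_gap

    def fit(self, X, y=None):
        self.trace_ = pupil_trace(X, self.frame_rate, self.radius_range,
                                  self.threshold, self.confidence_floor,
                                  self.max_gap)
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        if not hasattr(self, "trace_"):
            self.fit(X)
        return self.trace_.diameter
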