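"""Freezing classification from video frame stacks or pixel-change traces.

Freezing — immobility except for respiration — is operationalized as a
sustained run of frames whose changed-pixel count stays below a threshold:
the per-frame number of pixels whose intensity changed relative to the
previous frame is Gaussian-smoothed (sigma = 3 frames), and a mouse counts
as freezing wherever at least ``min_run`` consecutive smoothed values fall
strictly below the threshold (default 38 frames = 1.5 s at 25 fps; default
threshold 983 changed pixels for whole-frame counting, i.e. 0.5% of a
512x384 frame, or 100 pixels when counting is restricted to a region of
interest around the animal to discard patch-cord motion).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: default whole-frame pixel count (512 x 384), of which 0.5% = 983 pixels
DEFAULT_FRAME_PIXELS = 196_608
DEFAULT_GLOBAL_THRESHOLD = 983
DEFAULT_ROI_THRESHOLD = 100
DEFAULT_FPS = 25.0
DEFAULT_PIXEL_DELTA = 10  # intensity change (out of 255) making a pixel "changed"


@dataclass
class PixelChangeTrace:
    """Per-frame changed-pixel counts.

    ``values[0] = 0`` by convention (no previous frame to compare with).
    """

    values: np.ndarray
    fps: float = DEFAULT_FPS
    frame_pixels: int = DEFAULT_FRAME_PIXELS
    roi_mode: str = "global"  # 'global' | 'roi'
    smoothed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace must be 1-D with length >= 2")
        if np.any(self.values < 0):
            raise ValueError("changed-pixel counts must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class FreezingResult:
    """Freezing classification of a trace.

    ``bouts`` are maximal, disjoint half-open frame intervals
    ``[start, end)`` of length >= min_run; ``frame_labels`` is True exactly
    on frames inside a bout.
    """

    bouts: list
    frame_labels: np.ndarray
    fps: float
    threshold_px: float
    min_run_frames: int

    @property
    def percent_freezing_total(self) -> float:
        return 100.0 * self.frame_labels.mean()


@dataclass
class SessionProtocol:
    """Timing of conditioned-stimulus (CS) presentations within a session.

    ``cs_windows`` is a list of (start_s, duration_s); the pre-CS window of
    each CS is the ``pre_cs_s`` seconds preceding its onset.  Phase split:
    'early' = first half of CS presentations, 'late' = last half (with the
    default 20 CS protocol: first 10 / last 10).
    """

    cs_windows: list = field(default_factory=list)
    pre_cs_s: float = 30.0
    cs_duration_s: float = 30.0

    @classmethod
    def tone_train(cls, n_cs: int = 20, first_onset_s: float = 180.0,
                   cs_duration_s: float = 30.0, interval_s: float = 60.0):
        """Regular train of tones: `n_cs` CS of `cs_duration_s`, separated
        by `interval_s` of silence."""
        onsets = [first_onset_s + i * (cs_duration_s + interval_s)
                  for i in range(n_cs)]
        return cls(cs_windows=[(t, cs_duration_s) for t in onsets],
                   cs_duration_s=cs_duration_s)


def min_run_from_duration(duration_s: float = 1.5, fps: float = DEFAULT_FPS) -> int:
    """Minimum run length in frames for a freezing bout: ceil(duration * fps)."""
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration and fps must be positive")
    return int(math.ceil(duration_s * fps))


def check_threshold_consistency(threshold_px: float, frame_pixels: int,
                                fraction: float = 0.005,
                                rel_tol: float = 0.10) -> bool:
    """Warn when a global threshold deviates > `rel_tol` from
    ``fraction * frame_pixels`` (the 0.5%-of-all-pixels rule)."""
    expected = round(fraction * frame_pixels)
    ok = abs(threshold_px - expected) <= rel_tol * expected
    if not ok:
        warnings.warn(
            f"threshold {threshold_px} px deviates more than "
            f"{rel_tol:.0%} from {fraction:.1%} of {frame_pixels} pixels "
            f"(= {expected} px)", stacklevel=2)
    return ok


def _largest_moving_blob_bbox(diff_mask: np.ndarray, dilate_px: int):
    """Bounding slice of the largest connected changed-pixel blob, dilated."""
    labels, n = ndimage.label(diff_mask)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    sl = ndimage.find_objects(labels == biggest)[0]
    h, w = diff_mask.shape
    r0 = max(sl[0].start - dilate_px, 0)
    r1 = min(sl[0].stop + dilate_px, h)
    c0 = max(sl[1].start - dilate_px, 0)
    c1 = min(sl[1].stop + dilate_px, w)
    return (slice(r0, r1), slice(c0, c1))


def pixel_change(frames: np.ndarray, roi: str | np.ndarray | None = None,
                 pixel_delta: int = DEFAULT_PIXEL_DELTA,
                 fps: float = DEFAULT_FPS,
                 roi_dilate_px: int = 8) -> PixelChangeTrace:
    """Count changed pixels between consecutive frames.

    Parameters
    ----------
    frames : (n, h, w) uint8 array
        Grayscale frame stack, >= 2 frames.
    roi : None | 'track' | boolean mask
        ``None`` counts over the whole frame.  ``'track'`` derives, per
        frame, a dilated bounding region around the largest moving blob and
        counts only inside it (discarding e.g. patch-cord motion elsewhere).
        A boolean (h, w) mask restricts counting to a fixed region.
    pixel_delta : int
        Absolute intensity change (0-255 scale) above which a pixel counts
        as changed.

    An empty tracked ROI on some frame falls back to the global count for
    that frame, with a logged warning.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (n>=2, h, w) frame stack of uniform shape")
    n, h, w = frames.shape
    f = frames.astype(np.int16)
    diffs = np.abs(f[1:] - f[:-1])
    changed = diffs > pixel_delta

    values = np.zeros(n, dtype=float)
    roi_mode = "global"
    if roi is None:
        values[1:] = changed.reshape(n - 1, -1).sum(axis=1)
    elif isinstance(roi, np.ndarray):
        if roi.shape != (h, w):
            raise ValueError("ROI mask shape mismatch")
        roi_mode = "roi"
        values[1:] = changed[:, roi].sum(axis=1)
    elif roi == "track":
        roi_mode = "roi"
        n_fallback = 0
        for t in range(n - 1):
            bbox = _largest_moving_blob_bbox(changed[t], roi_dilate_px)
            if bbox is None:
                values[t + 1] = changed[t].sum()
                n_fallback += 1
            else:
                values[t + 1] = changed[t][bbox].sum()
        if n_fallback:
            logger.warning("empty ROI on %d frames; fell back to global count",
                           n_fallback)
    else:
        raise ValueError(f"unknown roi specification {roi!r}")

    return PixelChangeTrace(values=values, fps=fps, frame_pixels=h * w,
                            roi_mode=roi_mode)


def smooth_trace(trace: PixelChangeTrace,
                 sigma_frames: float = 3.0) -> PixelChangeTrace:
    """Gaussian smoothing of the pixel-change trace.

    Discrete Gaussian kernel truncated at +-4 sigma and renormalized to sum
    to 1; boundaries handled by edge replication, so constant traces are
    preserved exactly.
    """
    if sigma_frames <= 0:
        raise ValueError("sigma must be positive")
    radius = int(math.ceil(4.0 * sigma_frames))
    if trace.n_frames <= radius:
        warnings.warn("trace shorter than the smoothing kernel radius",
                      stacklevel=2)
    smoothed = ndimage.gaussian_filter1d(trace.values, sigma=sigma_frames,
                                         mode="nearest", radius=radius)
    return PixelChangeTrace(values=smoothed, fps=trace.fps,
                            frame_pixels=trace.frame_pixels,
                            roi_mode=trace.roi_mode, smoothed=True)


def detect_freezing(trace: PixelChangeTrace,
                    threshold_px: float | None = None,
                    min_run_frames: int = 38) -> FreezingResult:
    """Label freezing frames by run-length thresholding.

    A frame is freezing iff it belongs to a maximal run of >= ``min_run``
    consecutive frames whose value is strictly below ``threshold_px``.  The
    default threshold is 983 px in global mode and 100 px in ROI mode.
    """
    if min_run_frames < 1:
        raise ValueError("min_run_frames must be >= 1")
    if threshold_px is None:
        threshold_px = (DEFAULT_ROI_THRESHOLD if trace.roi_mode == "roi"
                        else DEFAULT_GLOBAL_THRESHOLD)
    if trace.roi_mode == "global":
        check_threshold_consistency(threshold_px, trace.frame_pixels)

    below = trace.values < threshold_px
    labels = np.zeros(trace.n_frames, dtype=bool)
    bouts = []
    # maximal runs of sub-threshold frames
    padded = np.concatenate([[False], below, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_run_frames:
            bouts.append((int(start), int(stop)))
            labels[start:stop] = True
    return FreezingResult(bouts=bouts, frame_labels=labels, fps=trace.fps,
                          threshold_px=float(threshold_px),
                          min_run_frames=int(min_run_frames))


def percent_freezing(result: FreezingResult,
                     protocol: SessionProtocol) -> pd.DataFrame:
    """Per-window freezing percentages for a CS protocol.

    For each CS presentation, reports the percentage of freezing frames
    during the CS window and during the ``pre_cs_s`` seconds preceding it,
    plus the phase ('early' = first half of the CS train, 'late' = second
    half).
    """
    fps = result.fps
    n_frames = result.frame_labels.size
    rows = []
    n_cs = len(protocol.cs_windows)
    for i, (start_s, dur_s) in enumerate(protocol.cs_windows):
        phase = "early" if i < n_cs / 2 else "late"
        for kind, (w0, w1) in (
                ("cs", (start_s, start_s + dur_s)),
                ("pre_cs", (start_s - protocol.pre_cs_s, start_s))):
            f0 = int(round(w0 * fps))
            f1 = int(round(w1 * fps))
            if f0 < 0 or f1 > n_frames:
                raise ValueError(
                    f"window [{w0}, {w1}] s outside trace extent "
                    f"({n_frames / fps:.1f} s)")
            frac = result.frame_labels[f0:f1].mean() if f1 > f0 else np.nan
            rows.append({"cs_index": i, "window": kind, "phase": phase,
                         "start_s": w0, "end_s": w1,
                         "percent_freezing": 100.0 * frac})
    return pd.DataFrame(rows)


def phase_means(windows: pd.DataFrame) -> pd.DataFrame:
    """Early/late phase mean freezing percentage per window kind."""
    return (windows.groupby(["phase", "window"], as_index=False)
            ["percent_freezing"].mean())
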