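"""Maternal and fetal movement time courses from frame-to-frame mask change.

Maternal movement: threshold the R2*-weighted images into a mask of bright
maternal features, remove the uterine mask, and count the voxels that differ
between consecutive frames. Fetal movement: the same differencing on a
bright amniotic-fluid mask restricted to the intra-uterine contents. Counts
are normalised by the session-mean mask size and expressed in %, and a scan
is high-movement when either mean over the non-contracting frames exceeds
2%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import DynamicSeries, LABEL_BACKGROUND, LABEL_CONTENT

HIGH_MOVEMENT_THRESHOLD_PCT = 2.0


@dataclass
class MotionTrace:
    """Per-frame movement percentages and the session-level flag."""

    maternal_pct: np.ndarray
    fetal_pct: np.ndarray
    high_movement_scan: bool | None = None
    noncontracting_mean_maternal_pct: float | None = None
    noncontracting_mean_fetal_pct: float | None = None
    maternal_threshold: float | None = None
    fetal_threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"maternal_pct": self.maternal_pct, "fetal_pct": self.fetal_pct}
        )


def _session_threshold(
    frame0: np.ndarray, mode: str, percentile: float, within: np.ndarray | None
) -> float:
    """A single threshold held fixed across the session."""
    vals = frame0 if within is None else frame0[within]
    vals = vals[np.isfinite(vals)]
    if mode == "percentile":
        vals = vals[vals > 0]
        if vals.size == 0:
            raise ValueError("no positive intensities to threshold")
        return float(np.percentile(vals, percentile))
    if mode == "otsu":
        if vals.size < 2 or np.ptp(vals) == 0:
            raise ValueError("degenerate intensities for Otsu thresholding")
        return float(threshold_otsu(vals))
    raise ValueError(f"unknown threshold mode {mode!r}")


def mask_difference_trace(masks: np.ndarray) -> np.ndarray:
    """Symmetric-difference trace (%) of a (n_frames, ...) boolean stack.

    Frame 0 is defined as 0; the per-frame voxel difference count is
    normalised by the session-mean mask size.
    """
    n = masks.shape[0]
    sizes = masks.reshape(n, -1).sum(axis=1)
    mean_size = float(sizes.mean())
    out = np.zeros(n)
    if mean_size == 0:
        warnings.warn("movement mask empty throughout the session")
        return out
    for f in range(1, n):
        diff = np.count_nonzero(masks[f] != masks[f - 1])
        out[f] = diff / mean_size * 100.0
    return out


def maternal_trace(
    series: DynamicSeries,
    threshold_mode: str = "percentile",
    percentile: float = 90.0,
    uterine_dilation: int = 2,
) -> tuple[np.ndarray, float]:
    """Maternal movement trace (%) and the threshold used.

    The bright-feature mask uses a fixed session-level threshold (default:
    90th percentile of the positive frame-0 intensities) minus the uterine
    mask (all non-background labels). The uterine mask is dilated a little
    before removal so bright intra-uterine voxels flickering across the
    segmented boundary are not mistaken for moving maternal features.
    """
    thr = _session_threshold(series.signal[0], threshold_mode, percentile, None)
    uterine = series.labels != LABEL_BACKGROUND
    if uterine_dilation > 0:
        structure = np.ones((1, 3, 3, 3), dtype=bool)  # dilate in space only
        uterine = ndimage.binary_dilation(
            uterine, structure=structure, iterations=uterine_dilation
        )
    masks = (series.signal > thr) & ~uterine
    return mask_difference_trace(masks), thr


def fetal_trace(
    series: DynamicSeries,
    threshold_mode: str = "otsu",
    percentile: float = 75.0,
) -> tuple[np.ndarray, float]:
    """Fetal movement trace (%) from the bright-fluid mask within the contents."""
    content0 = series.labels[0] == LABEL_CONTENT
    if not content0.any():
        warnings.warn("no intra-uterine contents in frame 0; fetal trace is zero")
        return np.zeros(series.n_frames), float("nan")
    thr = _session_threshold(series.signal[0], threshold_mode, percentile, content0)
    masks = (series.signal > thr) & (series.labels == LABEL_CONTENT)
    return mask_difference_trace(masks), thr


def flag_high_movement(
    maternal_pct: np.ndarray,
    fetal_pct: np.ndarray,
    event_intervals: list[tuple[int, int]] | None = None,
    threshold_pct: float = HIGH_MOVEMENT_THRESHOLD_PCT,
) -> tuple[bool | None, float | None, float | None]:
    """High-movement flag from the means over non-contracting frames."""
    n = len(maternal_pct)
    outside = np.ones(n, dtype=bool)
    for s, e in event_intervals or []:
        outside[s : e + 1] = False
    if not outside.any():
        warnings.warn("no non-contracting frames: high-movement flag undetermined")
        return None, None, None
    m_mean = float(np.mean(np.asarray(maternal_pct)[outside]))
    f_mean = float(np.mean(np.asarray(fetal_pct)[outside]))
    return (m_mean > threshold_pct or f_mean > threshold_pct), m_mean, f_mean


def motion_trace(
    series: DynamicSeries,
    event_intervals: list[tuple[int, int]] | None = None,
    maternal_mode: str = "percentile",
    fetal_mode: str = "otsu",
) -> MotionTrace:
    """Full motion screening for one session."""
    m_pct, m_thr = maternal_trace(series, threshold_mode=maternal_mode)
    f_pct, f_thr = fetal_trace(series, threshold_mode=fetal_mode)
    flag, m_mean, f_mean = flag_high_movement(m_pct, f_pct, event_intervals)
    return MotionTrace(
        maternal_pct=m_pct,
        fetal_pct=f_pct,
        high_movement_scan=flag,
        noncontracting_mean_maternal_pct=m_mean,
        noncontracting_mean_fetal_pct=f_mean,
        maternal_threshold=m_thr,
        fetal_threshold=f_thr,
    )


def mark_motion_affected(
    events,
    maternal_pct: np.ndarray,
    fetal_pct: np.ndarray,
    frame_threshold_pct: float = 10.0,
):
    """Flag events containing a frame with pronounced maternal/fetal movement."""
    m = np.asarray(maternal_pct)
    f = np.asarray(fetal_pct)
    for ev in events:
        sl = slice(ev.start_index, ev.end_index + 1)
        ev.motion_affected = bool(
            np.max(m[sl], initial=0.0) > frame_threshold_pct
            or np.max(f[sl], initial=0.0) > frame_threshold_pct
        )
    return events
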