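"""Assembly, smoothing and normalisation of per-frame measurement series.

Smoothing is a centred moving average over sample index (the acquisition is
irregular in time but the span is defined in time points); the window
shrinks symmetrically at the series edges. The relaxation-rate change is
computed from the mean placental signal as dR2*(t) = -(1/TE) ln(S(t)/Sb)
with Sb taken at the earliest rest frame, which need not be frame 0 when
acquisition starts during a contraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DynamicSeries, LABEL_PLACENTA
from .geometry import FrameMeasurements, measure_frame, sphericity

SERIES_NAMES = (
    "v_placenta",
    "v_content",
    "a_placenta",
    "a_bed",
    "a_wall",
    "sphericity",
    "s_mean",
    "dr2s",
)


def smooth(series: np.ndarray, span: int = 5) -> np.ndarray:
    """Centred moving average with symmetric edge shrinkage.

    At each end the window shrinks to stay symmetric (span 1 at the
    endpoints, 3 at the second points, ...), so the output has the same
    length as the input and a constant series is unchanged.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError(f"span must be odd and >= 1, got {span}")
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n == 0:
        return x.copy()
    half = span // 2
    out = np.empty_like(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def smooth_preserving_gaps(series: np.ndarray, span: int = 5) -> np.ndarray:
    """Smooth each contiguous finite run independently, leaving NaNs alone."""
    x = np.asarray(series, dtype=float)
    out = np.full_like(x, np.nan)
    finite = np.isfinite(x)
    if not finite.any():
        return out
    idx = np.flatnonzero(finite)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        block = idx[s : e + 1]
        out[block] = smooth(x[block], span)
    return out


def delta_r2star(
    s_mean: np.ndarray, sb: float, te_ms: float
) -> np.ndarray:
    """dR2*(t) = -(1/TE) ln(S(t)/Sb) in ms^-1."""
    s = np.asarray(s_mean, dtype=float)
    if te_ms <= 0:
        raise ValueError("te_ms must be positive")
    if not sb > 0:
        raise ValueError(f"baseline signal must be positive, got {sb}")
    finite = np.isfinite(s)
    bad = np.flatnonzero(finite & (s <= 0))
    if bad.size:
        raise ValueError(f"non-positive signal at frame index {int(bad[0])}")
    out = np.full_like(s, np.nan)
    out[finite] = -np.log(s[finite] / sb) / te_ms
    return out


def percent_of_rest(series: np.ndarray, baseline_index: int) -> np.ndarray:
    """Series as a percentage of its value at the earliest rest frame."""
    x = np.asarray(series, dtype=float)
    ref = x[baseline_index]
    if not np.isfinite(ref) or ref == 0:
        raise ValueError("baseline value must be finite and non-zero")
    return x / ref * 100.0


def find_earliest_rest(
    v_placenta: np.ndarray,
    timestamps_s: np.ndarray,
    rest_tolerance_pct: float = 2.0,
) -> int:
    """Index of the earliest rest frame of the placental volume series."""
    from .events import DetectionParams, rest_segments

    x = np.asarray(v_placenta, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if x.size == 1:
        return 0
    params = DetectionParams(rest_tolerance_pct=rest_tolerance_pct)
    ref, rest = rest_segments(x, np.asarray(timestamps_s, dtype=float), params)
    if not rest.any():
        raise ValueError(
            "no rest segment found in the whole session; supply a baseline "
            "index manually"
        )
    # prefer frames tight against the reference so a release tail smeared in
    # by smoothing is not mistaken for the earliest rest volume
    with np.errstate(invalid="ignore", divide="ignore"):
        dev_pct = np.abs(ref - x) / ref * 100.0
    strict = rest & (dev_pct <= params.anchor_tolerance_pct)
    hits = np.flatnonzero(strict if strict.any() else rest)
    return int(hits[0])


@dataclass
class TimeCourse:
    """Analysis-ready per-frame series for one session."""

    timestamps_s: np.ndarray
    raw: dict[str, np.ndarray]
    smoothed: dict[str, np.ndarray]
    baseline_index: int
    te_ms: float
    smooth_span: int = 5
    measurements: list[FrameMeasurements] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return int(self.timestamps_s.shape[0])

    @property
    def duration_s(self) -> float:
        return float(self.timestamps_s[-1] - self.timestamps_s[0])

    def percent_of_rest(self, name: str) -> np.ndarray:
        return percent_of_rest(self.smoothed[name], self.baseline_index)

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"timestamp_s": self.timestamps_s}
        for name in SERIES_NAMES:
            if name in self.raw:
                data[name] = self.raw[name]
            if name in self.smoothed:
                data[f"{name}_smooth"] = self.smoothed[name]
        for name in ("v_placenta", "v_content", "a_bed", "a_wall"):
            if name in self.smoothed:
                try:
                    data[f"{name}_pct"] = self.percent_of_rest(name)
                except ValueError:
                    pass
        df = pd.DataFrame(data)
        df.attrs["baseline_index"] = self.baseline_index
        return df


def mean_placental_signal(series: DynamicSeries) -> np.ndarray:
    """Per-frame mean signal over that frame's placenta mask."""
    out = np.full(series.n_frames, np.nan)
    for f in range(series.n_frames):
        mask = series.labels[f] == LABEL_PLACENTA
        if mask.any():
            out[f] = float(series.signal[f][mask].mean())
    return out


def build_timecourse(
    series: DynamicSeries,
    smooth_span: int = 5,
    rest_tolerance_pct: float = 2.0,
    area_frames: np.ndarray | str | None = "all",
    baseline_index: int | None = None,
) -> TimeCourse:
    """Measure every frame and assemble smoothed, normalised time courses.

    ``area_frames`` selects the frames for which the (expensive) surface
    reconstruction runs: "all", None (volumes only), or an index array.
    """
    n = series.n_frames
    if isinstance(area_frames, str):
        if area_frames != "all":
            raise ValueError("area_frames must be 'all', None or an index array")
        area_set = set(range(n))
    elif area_frames is None:
        area_set = set()
    else:
        area_set = {int(i) for i in np.asarray(area_frames).ravel()}

    raw: dict[str, np.ndarray] = {
        name: np.full(n, np.nan)
        for name in ("v_placenta", "v_content", "a_placenta", "a_bed", "a_wall",
                     "sphericity")
    }
    measurements: list[FrameMeasurements] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-placenta warnings handled below
        for f in range(n):
            m = measure_frame(
                series.labels[f],
                series.grid,
                timestamp_s=float(series.timestamps_s[f]),
                compute_areas=f in area_set,
            )
            measurements.append(m)
            raw["v_placenta"][f] = m.placental_volume_mm3
            raw["v_content"][f] = m.nonplacental_content_volume_mm3
            if m.areas_computed:
                raw["a_placenta"][f] = m.placental_surface_area_mm2
                raw["a_bed"][f] = m.placental_bed_area_mm2
                raw["a_wall"][f] = m.nonplacental_wall_area_mm2
    if any(m.empty_placenta for m in measurements):
        warnings.warn("session contains frames with an empty placenta mask")
    raw["s_mean"] = mean_placental_signal(series)

    smoothed = {
        name: smooth_preserving_gaps(raw[name], smooth_span)
        for name in ("v_placenta", "v_content", "a_placenta", "a_bed", "a_wall",
                     "s_mean")
    }
    # sphericity from the smoothed volume and area series
    sph_raw = np.full(n, np.nan)
    sph_smooth = np.full(n, np.nan)
    for f in range(n):
        if raw["v_placenta"][f] > 0 and raw["a_placenta"][f] > 0:
            sph_raw[f] = sphericity(raw["v_placenta"][f], raw["a_placenta"][f])
        if (
            np.isfinite(smoothed["v_placenta"][f])
            and np.isfinite(smoothed["a_placenta"][f])
            and smoothed["v_placenta"][f] > 0
            and smoothed["a_placenta"][f] > 0
        ):
            sph_smooth[f] = sphericity(
                smoothed["v_placenta"][f], smoothed["a_placenta"][f]
            )
    raw["sphericity"] = sph_raw
    smoothed["sphericity"] = sph_smooth

    if baseline_index is None:
        baseline_index = find_earliest_rest(
            smoothed["v_placenta"], series.timestamps_s, rest_tolerance_pct
        )
    sb = smoothed["s_mean"][baseline_index]
    if np.isfinite(sb) and sb > 0:
        dr2s = delta_r2star(smoothed["s_mean"], float(sb), series.te_ms)
    else:
        dr2s = np.full(n, np.nan)
    raw["dr2s"] = delta_r2star(
        raw["s_mean"], float(sb), series.te_ms
    ) if np.isfinite(sb) and sb > 0 else np.full(n, np.nan)
    smoothed["dr2s"] = dr2s

    return TimeCourse(
        timestamps_s=np.asarray(series.timestamps_s, dtype=float),
        raw=raw,
        smoothed=smoothed,
        baseline_index=int(baseline_index),
        te_ms=series.te_ms,
        smooth_span=smooth_span,
        measurements=measurements,
    )
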