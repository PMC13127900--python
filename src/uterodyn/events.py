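"""Contraction detection and per-event feature extraction.

Events are drops of the (smoothed) placental-volume series below a running
rest reference. Each event gets a local baseline per series, linear in time
between the last rest frame before and the first rest frame after the event,
held constant on a side truncated by the scan boundary. Event duration is
the time between the two half-maximum crossings of the baseline-to-series
deviation, interpolated on the irregular timestamps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DetectionParams:
    drop_threshold_pct: float = 5.0
    min_consecutive: int = 2
    merge_gap_frames: int = 2
    rest_tolerance_pct: float = 2.0
    # events extend outward until the drop falls below this; the flanking
    # baseline anchors must sit below it too, so anchor frames are nearly
    # uncontaminated by the event tails smeared in by smoothing
    boundary_tolerance_pct: float = 0.5
    # flanking baseline anchors prefer frames this close to the reference
    anchor_tolerance_pct: float = 0.25
    # ... and at least this many frames clear of the event, so their
    # smoothed values are not contaminated by the event tail (set to half
    # the smoothing span)
    anchor_margin_frames: int = 2
    reference_window: int = 31
    reference_quantile: float = 0.75
    n_reference_iterations: int = 3

    def __post_init__(self) -> None:
        if self.drop_threshold_pct <= 0:
            raise ValueError("drop_threshold_pct must be positive")
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")
        if self.rest_tolerance_pct <= 0:
            raise ValueError("rest_tolerance_pct must be positive")
        if not 0 < self.boundary_tolerance_pct <= self.rest_tolerance_pct:
            raise ValueError(
                "boundary_tolerance_pct must lie in (0, rest_tolerance_pct]"
            )


@dataclass
class ContractionEvent:
    """One detected contraction with its extracted features."""

    start_index: int
    end_index: int
    pre_rest_index: int | None = None
    post_rest_index: int | None = None
    truncated_start: bool = False
    truncated_end: bool = False
    peak_index: int | None = None
    local_baseline: np.ndarray | None = None  # volume baseline over the event
    halfmax_duration_min: float | None = None
    halfmax_lower_bound: bool = False
    max_volume_drop_pct: float | None = None
    max_wall_area_change_pct: float | None = None
    max_sphericity_change: float | None = None
    dr2s_change_per_ms: float | None = None
    motion_affected: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("start_index must be <= end_index")

    @property
    def truncated(self) -> bool:
        return self.truncated_start or self.truncated_end

    def window(self) -> tuple[int, int]:
        """Index window spanning the event plus its flanking rest frames."""
        lo = self.pre_rest_index if self.pre_rest_index is not None else self.start_index
        hi = self.post_rest_index if self.post_rest_index is not None else self.end_index
        return int(lo), int(hi)


def _rolling_quantile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).quantile(q).to_numpy()


def rest_segments(
    series: np.ndarray, timestamps_s: np.ndarray, params: DetectionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Running rest reference and boolean rest-frame mask.

    Starts from a robust rolling upper quantile (contractions only ever pull
    the series down) and iteratively re-interpolates the reference through
    the frames that sit within the rest tolerance of it, which absorbs slow
    drifts without following the contractions themselves.
    """
    x = np.asarray(series, dtype=float)
    t = np.asarray(timestamps_s, dtype=float)
    window = min(params.reference_window, x.size)
    ref = _rolling_quantile(x, window, params.reference_quantile)
    rest = np.zeros(x.size, dtype=bool)
    for _ in range(params.n_reference_iterations):
        with np.errstate(invalid="ignore", divide="ignore"):
            dev_pct = (ref - x) / ref * 100.0
        rest = np.abs(dev_pct) <= params.rest_tolerance_pct
        if not rest.any():
            return ref, rest
        # running median of the rest values: a frame caught inside an event
        # tail cannot pin the reference to itself
        med = _rolling_median(x[rest], 5)
        ref = np.interp(t, t[rest], med)
    return ref, rest


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def detect_events(
    series: np.ndarray,
    timestamps_s: np.ndarray,
    params: DetectionParams | None = None,
) -> list[ContractionEvent]:
    """Detect contraction candidates on a smoothed placental-volume series."""
    params = params or DetectionParams()
    x = np.asarray(series, dtype=float)
    t = np.asarray(timestamps_s, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("series too short for detection (need >= 3 frames)")
    ref, rest = rest_segments(x, t, params)
    if not rest.any():
        warnings.warn("no rest segment found: whole session flagged as one "
                      "truncated event")
        return [
            ContractionEvent(
                start_index=0,
                end_index=n - 1,
                truncated_start=True,
                truncated_end=True,
            )
        ]
    with np.errstate(invalid="ignore", divide="ignore"):
        dev_pct = (ref - x) / ref * 100.0
    candidate = dev_pct > params.drop_threshold_pct

    runs = _runs(candidate)
    runs = [(s, e) for s, e in runs if e - s + 1 >= params.min_consecutive]
    runs = _merge_runs(runs, params.merge_gap_frames)

    events: list[ContractionEvent] = []
    anchor_strict = rest & (np.abs(dev_pct) <= params.anchor_tolerance_pct)
    anchor_loose = rest & (dev_pct <= params.boundary_tolerance_pct)
    for s, e in runs:
        # extend to where the series re-approaches the rest reference
        while s > 0 and dev_pct[s - 1] > params.boundary_tolerance_pct:
            s -= 1
        while e < n - 1 and dev_pct[e + 1] > params.boundary_tolerance_pct:
            e += 1
        margin = params.anchor_margin_frames
        pre_idx = _coalesce(
            _last_true(anchor_strict, s - margin),
            _last_true(anchor_loose, s - margin),
            _last_true(rest, s),
        )
        post_idx = _coalesce(
            _first_true(anchor_strict, e + margin),
            _first_true(anchor_loose, e + margin),
            _first_true(rest, e),
        )
        events.append(
            ContractionEvent(
                start_index=int(s),
                end_index=int(e),
                pre_rest_index=pre_idx,
                post_rest_index=post_idx,
                truncated_start=pre_idx is None,
                truncated_end=post_idx is None,
            )
        )
    return events


def _last_true(mask: np.ndarray, before: int) -> int | None:
    hits = np.flatnonzero(mask[: max(0, before)])
    return int(hits[-1]) if hits.size else None


def _first_true(mask: np.ndarray, after: int) -> int | None:
    hits = np.flatnonzero(mask[after + 1 :])
    return int(hits[0]) + after + 1 if hits.size else None


def _coalesce(*values):
    for v in values:
        if v is not None:
            return v
    return None


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def _merge_runs(
    runs: list[tuple[int, int]], merge_gap_frames: int
) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe - 1 <= merge_gap_frames:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def local_baseline(
    event: ContractionEvent,
    series: np.ndarray,
    timestamps_s: np.ndarray,
    global_rest_index: int | None = None,
) -> np.ndarray:
    """Local baseline values over the event's full window.

    Linear in time between the series values at the flanking rest frames;
    constant on a truncated side; constant at the global earliest-rest value
    when both sides are truncated.
    """
    x = np.asarray(series, dtype=float)
    t = np.asarray(timestamps_s, dtype=float)
    lo, hi = event.window()
    tt = t[lo : hi + 1]
    pre, post = event.pre_rest_index, event.post_rest_index
    if pre is None and post is None:
        if global_rest_index is None:
            warnings.warn(
                "event truncated on both sides and no global rest index: "
                "using the first frame as baseline"
            )
            global_rest_index = 0
        return np.full(tt.size, x[global_rest_index])
    if pre is None:
        return np.full(tt.size, x[post])
    if post is None:
        return np.full(tt.size, x[pre])
    return np.interp(tt, [t[pre], t[post]], [x[pre], x[post]])


def halfmax_duration(
    event: ContractionEvent,
    series: np.ndarray,
    timestamps_s: np.ndarray,
    baseline: np.ndarray | None = None,
    global_rest_index: int | None = None,
) -> tuple[float, bool]:
    """Half-maximum duration in minutes and a truncation lower-bound flag.

    The deviation d(t) = baseline(t) - series(t) is evaluated over the event
    window; the crossing times of d = d_max / 2 on the rising and falling
    flanks are found by linear interpolation between adjacent (irregular)
    timestamps.
    """
    x = np.asarray(series, dtype=float)
    t = np.asarray(timestamps_s, dtype=float)
    lo, hi = event.window()
    if baseline is None:
        baseline = local_baseline(event, x, t, global_rest_index)
    d = baseline - x[lo : hi + 1]
    tt = t[lo : hi + 1]
    core = slice(event.start_index - lo, event.end_index - lo + 1)
    d_core = d[core]
    if not np.isfinite(d_core).any() or np.nanmax(d_core) <= 0:
        raise ValueError("event has no positive deviation from its baseline")
    peak_local = int(np.nanargmax(d_core)) + (event.start_index - lo)
    half = d[peak_local] / 2.0
    lower_bound = False

    t_rise = tt[0]
    rising_truncated = True
    for j in range(peak_local, 0, -1):
        if d[j - 1] < half <= d[j]:
            frac = (half - d[j - 1]) / (d[j] - d[j - 1])
            t_rise = tt[j - 1] + frac * (tt[j] - tt[j - 1])
            rising_truncated = False
            break
    if rising_truncated:
        lower_bound = True

    t_fall = tt[-1]
    falling_truncated = True
    for j in range(peak_local, d.size - 1):
        if d[j + 1] < half <= d[j]:
            frac = (d[j] - half) / (d[j] - d[j + 1])
            t_fall = tt[j] + frac * (tt[j + 1] - tt[j])
            falling_truncated = False
            break
    if falling_truncated:
        lower_bound = True

    return float((t_fall - t_rise) / 60.0), lower_bound


def event_features(
    event: ContractionEvent,
    series_map: dict[str, np.ndarray],
    timestamps_s: np.ndarray,
    global_rest_index: int | None = None,
    dr2s_mode: str = "at_volume_peak",
) -> ContractionEvent:
    """Fill in an event's features from the session's smoothed series.

    Each series gets its own local baseline by the same interpolation rule.
    Ratio features (volume, areas) are percentages of the local baseline;
    sphericity and dR2* changes are absolute. The dR2* change is read at the
    frame of maximum volume deviation by default ("at_volume_peak"), or as
    the largest absolute excursion ("extremum").
    """
    if dr2s_mode not in ("at_volume_peak", "extremum"):
        raise ValueError(f"unknown dr2s_mode {dr2s_mode!r}")
    t = np.asarray(timestamps_s, dtype=float)
    lo, hi = event.window()
    core = slice(event.start_index - lo, event.end_index - lo + 1)

    v = np.asarray(series_map["v_placenta"], dtype=float)
    base_v = local_baseline(event, v, t, global_rest_index)
    with np.errstate(invalid="ignore", divide="ignore"):
        drop_pct = (base_v - v[lo : hi + 1]) / base_v * 100.0
    drop_core = drop_pct[core]
    if np.isfinite(drop_core).any():
        peak_local = int(np.nanargmax(drop_core)) + (event.start_index - lo)
        event.peak_index = peak_local + lo
        event.max_volume_drop_pct = float(drop_pct[peak_local])
    event.local_baseline = base_v

    try:
        dur, lb = halfmax_duration(event, v, t, baseline=base_v,
                                   global_rest_index=global_rest_index)
        event.halfmax_duration_min = dur
        event.halfmax_lower_bound = lb
    except ValueError:
        event.halfmax_duration_min = None

    if "a_wall" in series_map:
        a = np.asarray(series_map["a_wall"], dtype=float)
        base_a = local_baseline(event, a, t, global_rest_index)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = (a[lo : hi + 1] - base_a) / base_a * 100.0
        event.max_wall_area_change_pct = _signed_extremum(rel[core])

    if "sphericity" in series_map:
        s = np.asarray(series_map["sphericity"], dtype=float)
        base_s = local_baseline(event, s, t, global_rest_index)
        diff = s[lo : hi + 1] - base_s
        event.max_sphericity_change = _signed_extremum(diff[core])

    if "dr2s" in series_map:
        r = np.asarray(series_map["dr2s"], dtype=float)
        base_r = local_baseline(event, r, t, global_rest_index)
        diff = r[lo : hi + 1] - base_r
        if dr2s_mode == "extremum":
            event.dr2s_change_per_ms = _signed_extremum(diff[core])
        elif event.peak_index is not None:
            val = diff[event.peak_index - lo]
            event.dr2s_change_per_ms = float(val) if np.isfinite(val) else None
    return event


def _signed_extremum(values: np.ndarray) -> float | None:
    """Value with the largest magnitude, sign preserved; None if all-NaN."""
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).any():
        return None
    k = int(np.nanargmax(np.abs(v)))
    return float(v[k])


def contraction_rate(n_events: int, session_duration_s: float) -> float:
    """Detected contractions per hour."""
    if session_duration_s <= 0:
        raise ValueError("session duration must be positive")
    return 3600.0 * n_events / session_duration_s


def events_to_frame(
    events: list[ContractionEvent], timestamps_s: np.ndarray | None = None
) -> pd.DataFrame:
    rows = []
    for i, ev in enumerate(events):
        row = {
            "event_index": i,
            "start_index": ev.start_index,
            "end_index": ev.end_index,
            "pre_rest_index": ev.pre_rest_index,
            "post_rest_index": ev.post_rest_index,
            "truncated_start": ev.truncated_start,
            "truncated_end": ev.truncated_end,
            "peak_index": ev.peak_index,
            "halfmax_duration_min": ev.halfmax_duration_min,
            "halfmax_lower_bound": ev.halfmax_lower_bound,
            "max_volume_drop_pct": ev.max_volume_drop_pct,
            "max_wall_area_change_pct": ev.max_wall_area_change_pct,
            "max_sphericity_change": ev.max_sphericity_change,
            "dr2s_change_per_ms": ev.dr2s_change_per_ms,
            "motion_affected": ev.motion_affected,
        }
        if timestamps_s is not None:
            row["start_s"] = float(timestamps_s[ev.start_index])
            row["end_s"] = float(timestamps_s[ev.end_index])
        rows.append(row)
    return pd.DataFrame(rows)
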