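"""Session-level orchestration: series -> time course -> events -> labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import (
    ClassificationParams,
    ClassifiedEvent,
    classify_events,
    classify_session,
)
from .core import DynamicSeries
from .events import (
    ContractionEvent,
    DetectionParams,
    detect_events,
    event_features,
)
from .motion import MotionTrace, mark_motion_affected, motion_trace
from .timecourse import TimeCourse, build_timecourse


@dataclass(frozen=True)
class AnalysisParams:
    smooth_span: int = 5
    detection: DetectionParams = field(default_factory=DetectionParams)
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    area_mode: str = "events"  # "all" | "events" | "none"
    dr2s_mode: str = "at_volume_peak"
    compute_motion: bool = True
    motion_frame_threshold_pct: float = 10.0


@dataclass
class SessionAnalysis:
    timecourse: TimeCourse
    events: list[ContractionEvent]
    classified: list[ClassifiedEvent]
    motion: MotionTrace | None
    rates: dict
    params: AnalysisParams


def event_area_frames(
    events: list[ContractionEvent], n_frames: int, margin: int
) -> np.ndarray:
    """Frames needing surface areas: event windows padded by the smooth span."""
    need = np.zeros(n_frames, dtype=bool)
    for ev in events:
        lo, hi = ev.window()
        need[max(0, lo - margin) : min(n_frames, hi + 1 + margin)] = True
    return np.flatnonzero(need)


def analyze_session(
    series: DynamicSeries, params: AnalysisParams | None = None
) -> SessionAnalysis:
    """Run the full analysis pipeline on one dynamic series.

    With area_mode="events" the expensive surface reconstruction only runs
    on frames inside (padded) event windows — sphericity and wall-area
    features are local to events, so nothing downstream changes.
    """
    params = params or AnalysisParams()
    t = np.asarray(series.timestamps_s, dtype=float)

    if params.area_mode not in ("all", "events", "none"):
        raise ValueError(f"unknown area_mode {params.area_mode!r}")
    first_pass_areas = "all" if params.area_mode == "all" else None
    tc = build_timecourse(
        series,
        smooth_span=params.smooth_span,
        rest_tolerance_pct=params.detection.rest_tolerance_pct,
        area_frames=first_pass_areas,
    )
    events = detect_events(tc.smoothed["v_placenta"], t, params.detection)

    if params.area_mode == "events" and events:
        frames = event_area_frames(events, tc.n_frames, margin=params.smooth_span)
        tc = build_timecourse(
            series,
            smooth_span=params.smooth_span,
            rest_tolerance_pct=params.detection.rest_tolerance_pct,
            area_frames=frames,
            baseline_index=tc.baseline_index,
        )

    for ev in events:
        event_features(
            ev,
            tc.smoothed,
            t,
            global_rest_index=tc.baseline_index,
            dr2s_mode=params.dr2s_mode,
        )

    motion = None
    if params.compute_motion:
        intervals = [(ev.start_index, ev.end_index) for ev in events]
        motion = motion_trace(series, intervals)
        mark_motion_affected(
            events,
            motion.maternal_pct,
            motion.fetal_pct,
            params.motion_frame_threshold_pct,
        )

    classifiable = [
        ev
        for ev in events
        if ev.max_volume_drop_pct is not None
        and ev.max_sphericity_change is not None
    ]
    classified = classify_events(classifiable, params.classification)
    duration = tc.duration_s if tc.duration_s > 0 else float("nan")
    rates = (
        classify_session(classified, duration)
        if np.isfinite(duration)
        else {}
    )
    return SessionAnalysis(
        timecourse=tc,
        events=events,
        classified=classified,
        motion=motion,
        rates=rates,
        params=params,
    )
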