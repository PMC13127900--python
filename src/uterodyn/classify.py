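"""Rule-based classification of contractions as placental or uterine.

A contraction qualifies for classification only when its placental volume
drop exceeds the 10% gate (strictly); gated events with a sphericity
increase of strictly more than 0.005 are placental, the rest uterine.
Boundary values (exactly 10%, exactly 0.005) are deliberately
non-placental / sub-threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .events import ContractionEvent, contraction_rate

RULE_VERSION = "volume-gate-10pct/sphericity-0.005/v1"

LABEL_PLACENTAL = "placental"
LABEL_UTERINE = "uterine"
LABEL_SUBTHRESHOLD = "sub-threshold"


@dataclass(frozen=True)
class ClassificationParams:
    volume_gate_pct: float = 10.0
    sphericity_threshold: float = 0.005
    use_wall_area: bool = False
    wall_area_threshold_pct: float | None = None

    def __post_init__(self) -> None:
        if self.use_wall_area and self.wall_area_threshold_pct is None:
            raise ValueError(
                "use_wall_area requires an explicit wall_area_threshold_pct "
                "(no validated default exists)"
            )


@dataclass
class ClassifiedEvent:
    event: ContractionEvent
    passes_volume_gate: bool
    label: str
    rule_version: str = RULE_VERSION


def classify_event(
    event: ContractionEvent, params: ClassificationParams | None = None
) -> ClassifiedEvent:
    """Apply the volume-gate + sphericity rule to one completed event."""
    params = params or ClassificationParams()
    if event.max_volume_drop_pct is None or event.max_sphericity_change is None:
        raise ValueError(
            "event features incomplete: need max_volume_drop_pct and "
            "max_sphericity_change"
        )
    gated = event.max_volume_drop_pct > params.volume_gate_pct
    if not gated:
        label = LABEL_SUBTHRESHOLD
    elif event.max_sphericity_change > params.sphericity_threshold:
        label = LABEL_PLACENTAL
    elif (
        params.use_wall_area
        and event.max_wall_area_change_pct is not None
        and event.max_wall_area_change_pct > params.wall_area_threshold_pct
    ):
        # optional secondary criterion, off by default
        label = LABEL_PLACENTAL
    else:
        label = LABEL_UTERINE
    return ClassifiedEvent(event=event, passes_volume_gate=gated, label=label)


def classify_events(
    events: list[ContractionEvent], params: ClassificationParams | None = None
) -> list[ClassifiedEvent]:
    params = params or ClassificationParams()
    return [classify_event(ev, params) for ev in events]


def classify_session(
    classified: list[ClassifiedEvent], session_duration_s: float
) -> dict:
    """Counts and per-hour rates overall, gated, and per label."""
    n_all = len(classified)
    n_gated = sum(1 for c in classified if c.passes_volume_gate)
    n_plac = sum(1 for c in classified if c.label == LABEL_PLACENTAL)
    n_uter = sum(1 for c in classified if c.label == LABEL_UTERINE)
    return {
        "n_events": n_all,
        "n_gated": n_gated,
        "n_placental": n_plac,
        "n_uterine": n_uter,
        "rate_all_per_h": contraction_rate(n_all, session_duration_s),
        "rate_gated_per_h": contraction_rate(n_gated, session_duration_s),
        "rate_placental_per_h": contraction_rate(n_plac, session_duration_s),
        "rate_uterine_per_h": contraction_rate(n_uter, session_duration_s),
    }


def classified_to_frame(
    classified: list[ClassifiedEvent], timestamps_s=None
) -> pd.DataFrame:
    from .events import events_to_frame

    df = events_to_frame([c.event for c in classified], timestamps_s)
    df["passes_volume_gate"] = [c.passes_volume_gate for c in classified]
    df["label"] = [c.label for c in classified]
    df["rule_version"] = [c.rule_version for c in classified]
    return df
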