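"""Seeded random scenario suites for validation studies.

Each scenario is a 30-minute-style session with a handful of well-separated
contraction events of mixed kinds, plateaued (Tukey) profiles so the
injected peak amplitude is attained exactly at the sampled frames, and the
default acquisition geometry.
"""

from __future__ import annotations

import numpy as np

from .model import EventSpec, ScenarioConfig

DEFAULT_KINDS = ("placental", "uterine_uniform", "uterine_local")


def sample_scenario(
    seed: int,
    n_frames: int = 120,
    n_events_range: tuple[int, int] = (1, 4),
    amplitude_range: tuple[float, float] = (0.12, 0.30),
    duration_range_s: tuple[float, float] = (210.0, 360.0),
    kinds: tuple[str, ...] = DEFAULT_KINDS,
    noise_sd_fraction: float = 0.02,
    taper_fraction: float = 0.25,
    min_gap_s: float = 120.0,
    edge_margin_s: float = 100.0,
    **config_kwargs,
) -> ScenarioConfig:
    """Draw one random scenario (deterministic in ``seed``)."""
    rng = np.random.default_rng(seed)
    base = ScenarioConfig(n_frames=n_frames, **config_kwargs)
    nominal = n_frames * base.tr_mean_s
    n_events = int(rng.integers(n_events_range[0], n_events_range[1] + 1))
    events: list[EventSpec] = []
    t = edge_margin_s
    for _ in range(n_events):
        duration = float(rng.uniform(*duration_range_s))
        latest = nominal - edge_margin_s - duration
        if t > latest:
            break
        onset = float(rng.uniform(t, min(latest, t + 400.0)))
        kind = str(rng.choice(kinds))
        events.append(
            EventSpec(
                kind=kind,
                onset_s=onset,
                duration_s=duration,
                amplitude=float(rng.uniform(*amplitude_range)),
                profile="tukey",
                profile_params={"taper_fraction": taper_fraction},
            )
        )
        t = onset + duration + min_gap_s
    return ScenarioConfig(
        n_frames=n_frames,
        events=tuple(events),
        noise_sd_fraction=noise_sd_fraction,
        rng_seed=seed,
        timing_seed=seed,
        **config_kwargs,
    )


def sample_suite(
    n_sessions: int, base_seed: int = 0, **kwargs
) -> list[ScenarioConfig]:
    """A list of scenarios with distinct derived seeds."""
    seeds = np.random.SeedSequence(base_seed).generate_state(n_sessions)
    return [sample_scenario(int(s), **kwargs) for s in seeds]
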