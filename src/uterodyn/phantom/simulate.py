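"""End-to-end synthetic session generation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import DynamicSeries
from .model import (
    SIGNAL_MATERNAL_FEATURE,
    SIGNAL_PLACENTA_REST,
    PointCache,
    ScenarioConfig,
    UteroPhantom,
)
from .raster import grid_sample_points, majority_label

GROUND_TRUTH_COLUMNS = [
    "event_id",
    "kind",
    "onset_s",
    "offset_s",
    "halfmax_duration_s",
    "peak_volume_drop_frac",
    "sphericity_delta",
    "truncated_start",
    "truncated_end",
]


def sample_timestamps(config: ScenarioConfig) -> np.ndarray:
    """Respiratory-triggered irregular sampling times.

    Gaps are tr_min_s plus an exponential excess with mean tr_mean_s -
    tr_min_s, which respects both the stated minimum and mean repetition
    times. Seeded by ``timing_seed`` so the sampled geometry (and therefore
    every label volume) is independent of the noise seed.
    """
    rng = np.random.default_rng(config.timing_seed)
    if config.n_frames == 1:
        return np.zeros(1)
    excess = config.tr_mean_s - config.tr_min_s
    gaps = config.tr_min_s + rng.exponential(excess, size=config.n_frames - 1)
    return np.concatenate([[0.0], np.cumsum(gaps)])


def ground_truth_table(
    phantom: UteroPhantom, timestamps: np.ndarray
) -> pd.DataFrame:
    """Analytic per-event ground truth (closed form, no rasterisation)."""
    t_end = float(timestamps[-1])
    rows = []
    for i, ev in enumerate(sorted(phantom.config.events, key=lambda e: e.onset_s)):
        rows.append(
            {
                "event_id": i,
                "kind": ev.kind,
                "onset_s": ev.onset_s,
                "offset_s": ev.offset_s,
                "halfmax_duration_s": ev.analytic_halfmax_s(),
                "peak_volume_drop_frac": ev.amplitude,
                "sphericity_delta": ev.sphericity_delta,
                "truncated_start": ev.onset_s < timestamps[0],
                "truncated_end": ev.offset_s > t_end,
            }
        )
    return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


def _core_box(points: np.ndarray, extent_mm: np.ndarray, margin_mm: float):
    """Index slices of the sampling box that can contain non-background."""
    slices = []
    for ax in range(3):
        # collapse to per-index coordinate bound across subsamples
        coords = points[..., ax]
        axes_to_reduce = tuple(d for d in range(coords.ndim) if d != ax + 1)
        lo = coords.min(axis=axes_to_reduce)
        hi = coords.max(axis=axes_to_reduce)
        keep = np.flatnonzero(
            (hi >= -extent_mm[ax] - margin_mm) & (lo <= extent_mm[ax] + margin_mm)
        )
        if keep.size == 0:
            slices.append(slice(0, 0))
        else:
            slices.append(slice(int(keep[0]), int(keep[-1]) + 1))
    return tuple(slices)


def simulate_session(
    config: ScenarioConfig, n_subsamples: int = 5, compute_signal: bool = True
) -> tuple[DynamicSeries, pd.DataFrame]:
    """Simulate one dynamic session.

    Returns the series (label + signal volumes with timestamps) and the
    analytic ground-truth event table. Identical configs give bit-identical
    output; configs differing only in ``rng_seed`` share label volumes and
    differ only in the signal (noise and scene dressing).
    """
    phantom = UteroPhantom(config)
    grid = config.grid
    timestamps = sample_timestamps(config)
    rng = np.random.default_rng(config.rng_seed)

    points, shape = grid_sample_points(grid, n_subsamples)
    box = _core_box(points, phantom.max_outer_extent_mm(), margin_mm=2.0)
    core_points = points[:, box[0], box[1], box[2], :]
    core_shape = core_points.shape[:-1]
    cache = PointCache(core_points.reshape(-1, 3))

    # Scene dressing is signal-only: fetal/maternal features never alter labels.
    if compute_signal:
        fetal_sets = [phantom.draw_fetal_blobs(rng)]
        n_fetal_events = sum(1 for _, k, _ in config.motion_events if k == "fetal")
        for _ in range(n_fetal_events):
            fetal_sets.append(phantom.draw_fetal_blobs(rng))
        maternal_blobs = phantom.draw_maternal_blobs(rng, grid)
    else:
        fetal_sets, maternal_blobs = [], np.empty((0, 4))

    maternal_steps = np.zeros((config.n_frames, 3))
    fetal_set_index = np.zeros(config.n_frames, dtype=int)
    n_fetal_seen = 0
    for frame, kind, magnitude in sorted(config.motion_events):
        if kind == "maternal":
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            maternal_steps[frame, :2] += magnitude * direction
        else:
            n_fetal_seen += 1
            fetal_set_index[frame:] = n_fetal_seen
    maternal_offsets = np.cumsum(maternal_steps, axis=0)

    flat_points = points.reshape(-1, 3)
    fetal_members = [
        _membership(cache.pts, blobs) for blobs in fetal_sets
    ]
    maternal_members: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def maternal_membership(offset: np.ndarray):
        key = tuple(np.round(offset, 6))
        if key not in maternal_members:
            blobs = maternal_blobs.copy()
            blobs[:, :3] += offset
            full = _membership(flat_points, blobs).reshape(points.shape[:-1])
            core = full[:, box[0], box[1], box[2]].reshape(-1)
            maternal_members[key] = (full, core)
        return maternal_members[key]

    noise_sd = config.noise_sd_fraction * SIGNAL_PLACENTA_REST
    labels_4d = np.zeros((config.n_frames, *shape), dtype=np.uint8)
    signal_4d = np.zeros((config.n_frames, *shape), dtype=float)
    for f, t in enumerate(timestamps):
        st = phantom.state_at(float(t))
        core_labels = phantom._labels_from_state(cache, st).reshape(core_shape)
        frame_labels = np.zeros(points.shape[:-1], dtype=np.uint8)
        frame_labels[:, box[0], box[1], box[2]] = core_labels
        labels_4d[f] = majority_label(frame_labels)
        if compute_signal:
            full_mat, core_mat = maternal_membership(maternal_offsets[f])
            sig = np.where(full_mat, np.float32(SIGNAL_MATERNAL_FEATURE), 0.0)
            sig[:, box[0], box[1], box[2]] = phantom.signal_from_labels(
                core_labels.reshape(-1),
                st,
                in_fetus=fetal_members[fetal_set_index[f]],
                in_maternal=core_mat,
            ).reshape(core_shape)
            frame_sig = sig.mean(axis=0)
            if noise_sd > 0:
                frame_sig = frame_sig + rng.normal(
                    0.0, noise_sd, size=frame_sig.shape
                )
            signal_4d[f] = frame_sig

    series = DynamicSeries(
        timestamps_s=timestamps,
        labels=labels_4d,
        signal=signal_4d,
        grid=grid,
        te_ms=config.te_ms,
        tr_min_s=config.tr_min_s,
        provenance={"source": "uterodyn.phantom", "rng_seed": config.rng_seed},
    )
    return series, ground_truth_table(phantom, timestamps)


def _membership(points: np.ndarray, blobs: np.ndarray) -> np.ndarray:
    from .model import _in_any_ball

    return _in_any_ball(points, blobs)
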