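"""Rasterisation of a continuous shape model onto the gapped multislice grid.

Each slice samples a band of ``slice_thickness_mm`` centred on the slice
plane: labels use >=3 point subsamples across the band with a majority vote,
signal averages the same subsamples. In-plane sampling is at voxel centres.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ..core import GridGeometry


def slice_subsample_offsets(grid: GridGeometry, n_subsamples: int = 3) -> np.ndarray:
    """z offsets (mm) of the within-slice subsample planes."""
    if n_subsamples < 3:
        raise ValueError("need at least 3 subsamples across the slice thickness")
    th = grid.slice_thickness_mm
    # symmetric interior points across the band, e.g. -th/3, 0, +th/3 for n=3
    return (np.arange(n_subsamples) - (n_subsamples - 1) / 2.0) * (th / n_subsamples)


def grid_sample_points(
    grid: GridGeometry, n_subsamples: int = 3
) -> tuple[np.ndarray, tuple[int, ...]]:
    """All sample points as (n_sub, nx, ny, nz, 3) world-mm coordinates."""
    xs, ys, zs = grid.axis_coordinates_mm()
    offs = slice_subsample_offsets(grid, n_subsamples)
    pts = np.empty((len(offs), len(xs), len(ys), len(zs), 3))
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    for i, dz in enumerate(offs):
        pts[i, ..., 0] = gx
        pts[i, ..., 1] = gy
        pts[i, ..., 2] = gz + dz
    return pts, (len(xs), len(ys), len(zs))


def majority_label(samples: np.ndarray) -> np.ndarray:
    """Per-voxel majority over the subsample axis (axis 0).

    For three samples: any pair agreeing wins, otherwise the middle (slice
    centre) sample. For more samples, the per-voxel mode with the central
    sample breaking ties.
    """
    n = samples.shape[0]
    if n == 3:
        s0, s1, s2 = samples[0], samples[1], samples[2]
        out = s1.copy()
        pair = s0 == s2
        out[pair] = s0[pair]
        return out
    centre = samples[n // 2]
    counts = np.stack([(samples == v).sum(axis=0) for v in range(4)])
    best = counts.argmax(axis=0).astype(samples.dtype)
    maxc = counts.max(axis=0)
    centre_count = np.take_along_axis(
        counts, centre[None].astype(np.intp), axis=0
    )[0]
    return np.where(centre_count == maxc, centre, best)


def rasterize_to_slices(
    label_fn: Callable[[np.ndarray], np.ndarray],
    grid: GridGeometry,
    n_subsamples: int = 3,
    points: np.ndarray | None = None,
) -> np.ndarray:
    """Rasterise ``label_fn(points_mm) -> labels`` onto the gapped grid."""
    if points is None:
        points, _ = grid_sample_points(grid, n_subsamples)
    flat = points.reshape(-1, 3)
    labels = np.asarray(label_fn(flat)).reshape(points.shape[:-1])
    return majority_label(labels)
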