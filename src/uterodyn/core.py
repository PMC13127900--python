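"""Core data structures shared across the pipeline.

The acquisition is multislice and gapped: slices of finite thickness are
spaced further apart than they are thick, so the third voxel dimension of a
label/signal array steps by ``slice_spacing_mm`` while each slice only
samples a ``slice_thickness_mm`` band centred on its plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

LABEL_BACKGROUND = 0
LABEL_PLACENTA = 1
LABEL_WALL = 2
LABEL_CONTENT = 3

VALID_LABELS = (LABEL_BACKGROUND, LABEL_PLACENTA, LABEL_WALL, LABEL_CONTENT)

LABEL_LEGEND = {
    LABEL_BACKGROUND: "background",
    LABEL_PLACENTA: "placenta",
    LABEL_WALL: "non_placental_uterine_wall",
    LABEL_CONTENT: "intra_uterine_contents",
}


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of the anisotropic, gapped multislice sampling grid.

    Arrays indexed ``[i, j, k]`` map to world mm via the (diagonal) affine;
    the grid is centred on the world origin.
    """

    shape: tuple[int, int, int]
    in_plane_mm: tuple[float, float] = (2.4, 2.4)
    slice_thickness_mm: float = 6.0
    slice_spacing_mm: float = 10.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if any(v <= 0 for v in self.in_plane_mm):
            raise ValueError("in-plane voxel size must be positive")
        if self.slice_thickness_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("slice thickness and spacing must be positive")
        if self.slice_spacing_mm < self.slice_thickness_mm:
            raise ValueError(
                "slice spacing must be at least the slice thickness "
                f"({self.slice_spacing_mm} < {self.slice_thickness_mm})"
            )

    @property
    def steps_mm(self) -> tuple[float, float, float]:
        return (self.in_plane_mm[0], self.in_plane_mm[1], self.slice_spacing_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        # Gap-aware: each slice stands in for its full inter-slice band.
        return self.in_plane_mm[0] * self.in_plane_mm[1] * self.slice_spacing_mm

    @property
    def origin_mm(self) -> np.ndarray:
        steps = np.asarray(self.steps_mm)
        return -(np.asarray(self.shape) - 1) / 2.0 * steps

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.steps_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def axis_coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis."""
        origin = self.origin_mm
        steps = self.steps_mm
        return tuple(
            origin[ax] + steps[ax] * np.arange(self.shape[ax]) for ax in range(3)
        )


@dataclass
class DynamicSeries:
    """An ordered dynamic series of co-registered label and signal volumes."""

    timestamps_s: np.ndarray
    labels: np.ndarray  # (n_frames, *grid.shape) uint8
    signal: np.ndarray  # (n_frames, *grid.shape) float
    grid: GridGeometry
    te_ms: float
    tr_min_s: float | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.labels = np.asarray(self.labels)
        self.signal = np.asarray(self.signal, dtype=float)
        n = self.timestamps_s.shape[0]
        if self.labels.shape != (n, *self.grid.shape):
            raise ValueError(
                f"label array shape {self.labels.shape} does not match "
                f"{n} frames on grid {self.grid.shape}"
            )
        if self.signal.shape != self.labels.shape:
            raise ValueError("label and signal volumes must share grid shape")
        if n > 1:
            gaps = np.diff(self.timestamps_s)
            if np.any(gaps <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if self.tr_min_s is not None and np.any(gaps < self.tr_min_s - 1e-9):
                raise ValueError(
                    f"inter-frame gap below minimum repetition time {self.tr_min_s} s"
                )
        bad = np.setdiff1d(np.unique(self.labels), np.asarray(VALID_LABELS))
        if bad.size:
            raise ValueError(f"undeclared label values present: {bad.tolist()}")
        if self.te_ms <= 0:
            raise ValueError("te_ms must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.timestamps_s.shape[0])

    @property
    def duration_s(self) -> float:
        return float(self.timestamps_s[-1] - self.timestamps_s[0])
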