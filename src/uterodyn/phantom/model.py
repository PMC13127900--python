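"""Parametric utero-placental phantom with closed-form ground truth.

The uterus is an ellipsoidal shell; the placenta is a spherical-cap slab on
the interior wall, subtending a configurable cap angle about the +y axis.
Contractions morph the cap angle and thickness analytically, so placental
volume, event timing and half-maximum widths are known in closed form
without touching a rasterised image:

* placental events shrink the cap (bed shortening) and thicken/balloon the
  placenta, driving sphericity up and freeing non-placental wall area;
* uterine events thicken the wall (locally or uniformly) and thin the
  placenta, driving sphericity down;
* in both cases the intra-uterine contents are incompressible: the cavity
  rescales so the fetal/fluid volume is conserved and any placental volume
  loss is blood expelled from the uterus.

In normalised coordinates u = x / (lambda * semiaxes) the cavity is the unit
ball and the placental cap slab is {1 - that <= |u| <= 1, angle(u, +y) <=
theta}, whose u-space volume is (2*pi/3) * (1 - cos theta) * (1 - (1 -
that)^3); world volume is abc * lambda^3 times that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from ..core import (
    GridGeometry,
    LABEL_BACKGROUND,
    LABEL_CONTENT,
    LABEL_PLACENTA,
    LABEL_WALL,
)
from .profiles import RaisedCosineProfile, TukeyProfile, make_profile

EventKind = Literal["placental", "uterine_local", "uterine_uniform"]

# Rest-state tissue signals (a.u.) chosen so simple session-level thresholds
# separate amniotic fluid, fetal tissue and bright extra-uterine features.
SIGNAL_PLACENTA_REST = 100.0
SIGNAL_WALL = 90.0
SIGNAL_FLUID = 180.0
SIGNAL_FETUS = 60.0
SIGNAL_MATERNAL_FEATURE = 240.0

DEFAULT_PLACENTAL_SPHERICITY_DELTA = 0.015


@dataclass(frozen=True)
class EventSpec:
    """One simulated contraction event."""

    kind: EventKind
    onset_s: float
    duration_s: float
    amplitude: float
    sphericity_delta: float | None = None
    r2s_delta_per_ms: float = 0.005
    profile: str = "raised_cosine"
    profile_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("placental", "uterine_local", "uterine_uniform"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not 0.0 <= self.amplitude <= 0.5:
            raise ValueError("amplitude must lie in [0, 0.5]")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.onset_s < 0:
            raise ValueError("onset_s must be non-negative")
        if self.sphericity_delta is not None:
            if self.kind == "placental" and self.sphericity_delta <= 0:
                raise ValueError("placental events require sphericity_delta > 0")
            if self.kind != "placental" and self.sphericity_delta > 0:
                raise ValueError("uterine events require sphericity_delta <= 0")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s

    def profile_fn(self) -> RaisedCosineProfile | TukeyProfile:
        return make_profile(self.profile, **self.profile_params)

    @property
    def is_placental(self) -> bool:
        return self.kind == "placental"

    def envelope(self, t: np.ndarray | float) -> np.ndarray:
        x = (np.asarray(t, dtype=float) - self.onset_s) / self.duration_s
        return self.profile_fn()(x)

    def analytic_halfmax_s(self) -> float:
        return self.profile_fn().halfmax_fraction * self.duration_s


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parametric description of one synthetic session."""

    grid_shape: tuple[int, int, int] = (96, 96, 24)
    voxel_size_mm: tuple[float, float, float] = (2.4, 2.4, 6.0)
    slice_spacing_mm: float = 10.0
    n_frames: int = 120
    te_ms: float = 25.0
    tr_min_s: float = 9.0
    tr_mean_s: float = 15.0
    # sized so the placenta holds ~6000 voxels on the default grid: in-plane
    # quantisation jitter of the gapped rasterisation stays well below 0.5%
    uterus_semiaxes_mm: tuple[float, float, float] = (88.0, 78.0, 66.0)
    wall_thickness_mm: float = 12.0
    placenta_cap_angle_deg: float = 70.0
    placenta_thickness_mm: float = 34.0
    events: tuple[EventSpec, ...] = ()
    noise_sd_fraction: float = 0.0
    motion_events: tuple[tuple[int, str, float], ...] = ()
    rng_seed: int = 0
    # Sampling times are seeded separately from the signal noise so that two
    # seeds differing only in rng_seed produce bit-identical label volumes.
    timing_seed: int = 20260101
    wall_thickening_uniform: float = 0.4
    wall_thickening_local: float = 0.8
    n_fetal_blobs: int = 5
    fetal_blob_radius_mm: float = 18.0
    n_maternal_blobs: int = 6
    maternal_blob_radius_mm: float = 12.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(
            self, "motion_events", tuple(tuple(m) for m in self.motion_events)
        )
        self.validate()

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if any(v <= 0 for v in self.voxel_size_mm) or self.slice_spacing_mm <= 0:
            raise ValueError("voxel sizes must be strictly positive")
        if self.slice_spacing_mm < self.voxel_size_mm[2]:
            raise ValueError("slice spacing must be >= slice thickness")
        if any(a <= 0 for a in self.uterus_semiaxes_mm):
            raise ValueError("uterus semi-axes must be strictly positive")
        if not 0.0 < self.placenta_cap_angle_deg < 180.0:
            raise ValueError("placenta_cap_angle_deg must lie in (0, 180)")
        if self.wall_thickness_mm <= 0 or self.placenta_thickness_mm <= 0:
            raise ValueError("thicknesses must be strictly positive")
        if self.wall_thickness_mm < max(self.voxel_size_mm[:2]):
            raise ValueError(
                "grid too coarse to represent the uterine wall: thickness "
                f"{self.wall_thickness_mm} mm is below one in-plane voxel "
                f"({max(self.voxel_size_mm[:2])} mm)"
            )
        if self.placenta_thickness_mm >= min(self.uterus_semiaxes_mm):
            raise ValueError("placenta thicker than the uterine cavity")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be >= 0")
        if not 0 < self.tr_min_s <= self.tr_mean_s:
            raise ValueError("need 0 < tr_min_s <= tr_mean_s")
        if self.te_ms <= 0:
            raise ValueError("te_ms must be positive")
        nominal = self.n_frames * self.tr_mean_s
        for ev in self.events:
            if ev.onset_s >= nominal:
                raise ValueError(
                    f"event onset {ev.onset_s} s lies beyond the nominal session "
                    f"duration {nominal} s"
                )
        by_kind: dict[str, list[EventSpec]] = {}
        for ev in self.events:
            by_kind.setdefault(ev.kind, []).append(ev)
        for kind, evs in by_kind.items():
            evs = sorted(evs, key=lambda e: e.onset_s)
            for prev, nxt in zip(evs, evs[1:]):
                if nxt.onset_s < prev.offset_s:
                    raise ValueError(
                        f"overlapping {kind} events at {prev.onset_s}-{prev.offset_s} s "
                        f"and {nxt.onset_s}-{nxt.offset_s} s"
                    )
        for frame, mkind, magnitude in self.motion_events:
            if not 0 <= int(frame) < self.n_frames:
                raise ValueError(f"motion event frame {frame} outside session")
            if mkind not in ("maternal", "fetal"):
                raise ValueError(f"unknown motion kind {mkind!r}")
            if magnitude <= 0:
                raise ValueError("motion magnitude must be positive")

    @property
    def grid(self) -> GridGeometry:
        return GridGeometry(
            shape=tuple(int(s) for s in self.grid_shape),
            in_plane_mm=(self.voxel_size_mm[0], self.voxel_size_mm[1]),
            slice_thickness_mm=self.voxel_size_mm[2],
            slice_spacing_mm=self.slice_spacing_mm,
        )

    def with_events(self, events: Sequence[EventSpec]) -> "ScenarioConfig":
        return replace(self, events=tuple(events))


# ---------------------------------------------------------------------------
# Closed-form cap-slab helpers (u-space sphere approximation used only to
# translate a requested sphericity change into a cap-angle morph factor).


def cap_slab_volume(theta: float, that: float, radius: float = 1.0) -> float:
    return (
        (2.0 * math.pi / 3.0)
        * radius**3
        * (1.0 - math.cos(theta))
        * (1.0 - (1.0 - that) ** 3)
    )


def cap_slab_area(theta: float, that: float, radius: float = 1.0) -> float:
    outer = 2.0 * math.pi * radius**2 * (1.0 - math.cos(theta))
    inner = outer * (1.0 - that) ** 2
    rim = math.pi * math.sin(theta) * radius**2 * (1.0 - (1.0 - that) ** 2)
    return outer + inner + rim


def cap_slab_sphericity(theta: float, that: float) -> float:
    v = cap_slab_volume(theta, that)
    a = cap_slab_area(theta, that)
    return math.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / a


class UteroPhantom:
    """Continuous-time, continuous-space phantom for one scenario."""

    def __init__(self, config: ScenarioConfig):
        self.config = config
        a, b, c = config.uterus_semiaxes_mm
        self.semiaxes = np.asarray([a, b, c], dtype=float)
        self.theta0 = math.radians(config.placenta_cap_angle_deg)
        # Nominal cap thickness fraction along the cap axis (+y).
        self.that0 = config.placenta_thickness_mm / b
        if not 0 < self.that0 < 1:
            raise ValueError("placenta thickness incompatible with cavity size")
        self.abc = float(np.prod(self.semiaxes))
        self.v_cavity0 = (4.0 * math.pi / 3.0) * self.abc
        self.v_placenta0 = self.abc * cap_slab_volume(self.theta0, self.that0)
        self.v_content0 = self.v_cavity0 - self.v_placenta0
        self._cap_scales = [self._solve_cap_scale(ev) for ev in config.events]

    # -- analytic ground truth -------------------------------------------

    def placental_volume_factor(self, t: float | np.ndarray) -> np.ndarray:
        """Fractional placental volume relative to rest (product over events)."""
        t = np.asarray(t, dtype=float)
        factor = np.ones_like(t)
        for ev in self.config.events:
            factor = factor * (1.0 - ev.amplitude * ev.envelope(t))
        return factor

    def analytic_placental_volume(self, t: float | np.ndarray) -> np.ndarray:
        return self.v_placenta0 * self.placental_volume_factor(t)

    # -- shape state ------------------------------------------------------

    def _solve_cap_scale(self, ev: EventSpec) -> float:
        """Cap-angle morph factor s: theta(peak) = theta0 * (1 + s).

        Placental events need s < 0 (bed shortening); the magnitude is chosen
        by root-finding on the closed-form cap-slab sphericity so the peak
        sphericity change approximates ev.sphericity_delta. Uterine events
        keep s = 0 unless a more negative sphericity change was requested.
        """
        target = ev.sphericity_delta
        if ev.kind != "placental" and target is None:
            return 0.0
        if ev.kind == "placental" and target is None:
            target = DEFAULT_PLACENTAL_SPHERICITY_DELTA
        s_rest = cap_slab_sphericity(self.theta0, self.that0)

        def peak_delta(scale: float) -> float | None:
            theta = self.theta0 * (1.0 + scale)
            lam3 = 1.0 - ev.amplitude * self.v_placenta0 / self.v_cavity0
            try:
                that = self._solve_that(1.0 - ev.amplitude, lam3, theta)
            except ValueError:
                return None  # cap too small to hold the event-time volume
            return cap_slab_sphericity(theta, that) - s_rest - target

        if ev.kind == "placental":
            hi = 0.0
            lo = hi
            for step in np.arange(0.02, 0.76, 0.02):
                if peak_delta(-step) is None:
                    break
                lo = -float(step)
            if lo == hi:
                raise ValueError("cap morph infeasible for placental event")
        else:
            natural = peak_delta(0.0)
            if natural is None or natural <= 0.0:
                return 0.0  # natural thinning already at/below the target
            lo, hi = 0.0, min(0.9, math.pi / self.theta0 - 1.0 - 1e-3)
            while hi > lo + 1e-3 and peak_delta(hi) is None:
                hi *= 0.9
        flo, fhi = peak_delta(lo), peak_delta(hi)
        if flo is None or fhi is None:
            return lo if fhi is None else hi
        if flo * fhi > 0:
            # Unreachable target: clamp to the closest feasible extreme.
            return lo if abs(flo) < abs(fhi) else hi
        return float(brentq(peak_delta, lo, hi, xtol=1e-6))

    def _solve_that(self, volume_factor: float, lam3: float, theta: float) -> float:
        """Cap thickness fraction delivering the target placental volume."""
        g = (
            volume_factor
            * self.v_placenta0
            / (lam3 * self.abc * (2.0 * math.pi / 3.0) * (1.0 - math.cos(theta)))
        )
        if not 0.0 < g < 1.0:
            raise ValueError(
                "cap morph infeasible: requested placental volume does not fit "
                "the morphed cap (reduce amplitude or sphericity_delta)"
            )
        return 1.0 - (1.0 - g) ** (1.0 / 3.0)

    def state_at(self, t: float) -> dict:
        """Geometric state (cavity scale, cap angle/thickness, wall field)."""
        cfg = self.config
        volume_factor = float(self.placental_volume_factor(t))
        lam3 = 1.0 - (1.0 - volume_factor) * self.v_placenta0 / self.v_cavity0
        theta = self.theta0
        wall_uniform = 1.0
        wall_local = 0.0
        dr2s = 0.0
        for ev, cap_scale in zip(cfg.events, self._cap_scales):
            p = float(ev.envelope(t))
            if p <= 0.0:
                continue
            theta *= 1.0 + cap_scale * p
            dr2s += ev.r2s_delta_per_ms * p
            if ev.kind == "uterine_uniform":
                wall_uniform *= 1.0 + cfg.wall_thickening_uniform * p
            elif ev.kind == "uterine_local":
                wall_local = max(wall_local, cfg.wall_thickening_local * p)
            else:
                wall_uniform *= max(0.5, 1.0 - 0.15 * p)
        that = self._solve_that(volume_factor, lam3, theta)
        return {
            "lam": lam3 ** (1.0 / 3.0),
            "theta": theta,
            "that": that,
            "wall_uniform": wall_uniform,
            "wall_local": wall_local,
            "dr2s_per_ms": dr2s,
            "volume_factor": volume_factor,
        }

    # -- spatial evaluation ----------------------------------------------

    def max_outer_extent_mm(self) -> np.ndarray:
        """Per-axis bound on the outer wall surface over any event state."""
        cfg = self.config
        wmax = cfg.wall_thickness_mm * (1.0 + cfg.wall_thickening_uniform) * (
            1.0 + cfg.wall_thickening_local
        )
        return self.semiaxes + wmax

    def labels_at(self, points_mm: np.ndarray, t: float) -> np.ndarray:
        """Tissue labels at world points (N, 3) and time t."""
        st = self.state_at(t)
        return self._labels_from_state(PointCache(points_mm), st)

    def _labels_from_state(self, cache: "PointCache", st: dict) -> np.ndarray:
        """Vectorised label evaluation; hot path, works on flat point caches."""
        axes = self.semiaxes * st["lam"]
        inv2 = (1.0 / axes**2).astype(np.float32)
        r2 = cache.x2 * inv2[0] + cache.y2 * inv2[1] + cache.z2 * inv2[2]
        labels = np.zeros(r2.shape, dtype=np.uint8)
        inside = r2 <= 1.0
        labels[inside] = LABEL_CONTENT
        # placental cap slab: shell r >= 1 - that within angle theta of +y
        cap_cand = np.flatnonzero(inside & (r2 >= (1.0 - st["that"]) ** 2))
        if cap_cand.size:
            r = np.sqrt(r2[cap_cand])
            uy = cache.y[cap_cand] * np.float32(1.0 / axes[1])
            in_cap = uy >= r * np.float32(math.cos(st["theta"]))
            labels[cap_cand[in_cap]] = LABEL_PLACENTA
        # wall: radial band of w_eff beyond the cavity surface
        w_base = self.config.wall_thickness_mm * st["wall_uniform"]
        w_bound = w_base * (1.0 + st["wall_local"])
        rmax2 = (1.0 + w_bound / float(axes.min())) ** 2
        wall_cand = np.flatnonzero((~inside) & (r2 <= rmax2))
        if wall_cand.size:
            r = np.sqrt(r2[wall_cand])
            rho = cache.rho[wall_cand]
            dist_out = rho / r * (r - 1.0)
            w_eff = np.float32(w_base)
            if st["wall_local"] > 0.0:
                # local bulge opposite the placenta (about the -y axis)
                uy = cache.y[wall_cand] * np.float32(1.0 / axes[1])
                cos_patch = np.clip(-uy / r, -1.0, 1.0)
                psi_patch = np.arccos(cos_patch)
                half_width = math.radians(60.0)
                bump = np.where(
                    psi_patch < half_width,
                    np.cos(0.5 * math.pi * psi_patch / half_width) ** 2,
                    0.0,
                ).astype(np.float32)
                w_eff = w_eff * (1.0 + np.float32(st["wall_local"]) * bump)
            labels[wall_cand[dist_out <= w_eff]] = LABEL_WALL
        return labels

    def signal_at(
        self,
        points_mm: np.ndarray,
        t: float,
        labels: np.ndarray | None = None,
        fetal_blobs: np.ndarray | None = None,
        maternal_blobs: np.ndarray | None = None,
        maternal_offset_mm: np.ndarray | None = None,
        state: dict | None = None,
    ) -> np.ndarray:
        """Noise-free R2*-weighted signal at world points (N, 3)."""
        pts = np.asarray(points_mm, dtype=np.float32)
        st = state if state is not None else self.state_at(t)
        if labels is None:
            labels = self._labels_from_state(PointCache(pts), st)
        in_fetus = (
            _in_any_ball(pts, fetal_blobs)
            if fetal_blobs is not None and len(fetal_blobs)
            else None
        )
        in_maternal = None
        if maternal_blobs is not None and len(maternal_blobs):
            centres = maternal_blobs.copy()
            if maternal_offset_mm is not None:
                centres[:, :3] += np.asarray(maternal_offset_mm, dtype=float)
            in_maternal = _in_any_ball(pts, centres)
        return self.signal_from_labels(labels, st, in_fetus, in_maternal)

    def signal_from_labels(
        self,
        labels: np.ndarray,
        st: dict,
        in_fetus: np.ndarray | None = None,
        in_maternal: np.ndarray | None = None,
    ) -> np.ndarray:
        """Signal from label samples plus precomputed blob memberships."""
        s_plac = SIGNAL_PLACENTA_REST * math.exp(
            -self.config.te_ms * st["dr2s_per_ms"]
        )
        lut = np.zeros(4, dtype=np.float32)
        lut[LABEL_PLACENTA] = s_plac
        lut[LABEL_WALL] = SIGNAL_WALL
        lut[LABEL_CONTENT] = SIGNAL_FLUID
        sig = lut[labels]
        if in_fetus is not None:
            sig[(labels == LABEL_CONTENT) & in_fetus] = SIGNAL_FETUS
        if in_maternal is not None:
            sig[(labels == LABEL_BACKGROUND) & in_maternal] = SIGNAL_MATERNAL_FEATURE
        return sig

    # -- stochastic scene dressing ----------------------------------------

    def draw_fetal_blobs(self, rng: np.random.Generator) -> np.ndarray:
        """(n, 4) array of world blob centres + radius inside the contents."""
        cfg = self.config
        n = cfg.n_fetal_blobs
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii_u = 0.55 * rng.uniform(0.2, 1.0, size=n) ** (1.0 / 3.0)
        centres = dirs * radii_u[:, None] * self.semiaxes
        out = np.empty((n, 4))
        out[:, :3] = centres
        out[:, 3] = cfg.fetal_blob_radius_mm
        return out

    def draw_maternal_blobs(
        self, rng: np.random.Generator, grid: GridGeometry
    ) -> np.ndarray:
        """Bright extra-uterine features placed in the background."""
        cfg = self.config
        half_extent = (np.asarray(grid.shape) - 1) / 2.0 * np.asarray(grid.steps_mm)
        margin = cfg.maternal_blob_radius_mm * 0.5
        clearance = cfg.wall_thickness_mm * 2.0 + cfg.maternal_blob_radius_mm + 4.0
        blobs = []
        for _ in range(4000):
            if len(blobs) >= cfg.n_maternal_blobs:
                break
            p = rng.uniform(-1.0, 1.0, size=3) * (half_extent - margin)
            u = p / self.semiaxes
            r = float(np.linalg.norm(u))
            if r <= 1e-9:
                continue
            dist_out = float(np.linalg.norm(p)) / r * (r - 1.0)
            if dist_out >= clearance:
                blobs.append(p)
        if len(blobs) < cfg.n_maternal_blobs:
            raise ValueError(
                "field of view too small to place maternal features outside "
                "the uterus"
            )
        out = np.empty((len(blobs), 4))
        out[:, :3] = np.asarray(blobs)
        out[:, 3] = cfg.maternal_blob_radius_mm
        return out


class PointCache:
    """Precomputed per-point quantities reused across frames (hot path)."""

    __slots__ = ("pts", "y", "x2", "y2", "z2", "rho")

    def __init__(self, points_mm: np.ndarray):
        pts = np.asarray(points_mm, dtype=np.float32)
        if pts.ndim != 2 or pts.shape[1] != 3:
            pts = pts.reshape(-1, 3)
        self.pts = pts
        self.y = pts[:, 1]
        self.x2 = pts[:, 0] ** 2
        self.y2 = pts[:, 1] ** 2
        self.z2 = pts[:, 2] ** 2
        self.rho = np.sqrt(self.x2 + self.y2 + self.z2)


def _in_any_ball(points: np.ndarray, balls: np.ndarray) -> np.ndarray:
    """Membership of (N, 3) points in any of the (M, 4) x/y/z/radius balls."""
    inside = np.zeros(points.shape[:-1], dtype=bool)
    for cx, cy, cz, rad in balls:
        d2 = (
            (points[..., 0] - cx) ** 2
            + (points[..., 1] - cy) ** 2
            + (points[..., 2] - cz) ** 2
        )
        inside |= d2 <= rad * rad
    return inside
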