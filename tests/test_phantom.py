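import math

import numpy as np
import numpy.testing as npt
import pytest

from uterodyn.core import (
    GridGeometry,
    LABEL_BACKGROUND,
    LABEL_CONTENT,
    LABEL_PLACENTA,
    LABEL_WALL,
)
from uterodyn.geometry import measure_frame
from uterodyn.phantom import (
    EventSpec,
    ScenarioConfig,
    UteroPhantom,
    make_profile,
    rasterize_to_slices,
    sample_timestamps,
    simulate_session,
)

from conftest import SMALL_GEOMETRY, TUKEY, make_config


def numeric_cap_slab_volume(semiaxes, theta, that, step_mm=1.0):
    """Independent oracle: continuous-model volume by dense point counting."""
    a, b, c = semiaxes
    xs = np.arange(-a, a + step_mm, step_mm)
    ys = np.arange(-b, b + step_mm, step_mm)
    zs = np.arange(-c, c + step_mm, step_mm)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    r = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)
    with np.errstate(invalid="ignore"):
        cos_psi = np.where(r > 0, (Y / b) / np.maximum(r, 1e-12), 1.0)
    inside = (r <= 1.0) & (r >= 1.0 - that) & (cos_psi >= math.cos(theta))
    return inside.sum() * step_mm**3


class TestConfigValidation:
    def test_valid_default(self):
        assert make_config(n_frames=5).n_frames == 5

    def test_overlapping_same_type_events_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            make_config(
                n_frames=100,
                events=(
                    EventSpec("placental", 100, 300, 0.1),
                    EventSpec("placental", 250, 300, 0.1),
                ),
            )

    def test_overlapping_different_types_allowed(self):
        cfg = make_config(
            n_frames=100,
            events=(
                EventSpec("placental", 100, 300, 0.1),
                EventSpec("uterine_uniform", 250, 300, 0.1),
            ),
        )
        assert len(cfg.events) == 2

    def test_wall_thinner_than_voxel_rejected(self):
        with pytest.raises(ValueError, match="too coarse"):
            make_config(wall_thickness_mm=1.0)

    @pytest.mark.parametrize("angle", [0.0, 180.0, -10.0, 200.0])
    def test_cap_angle_range(self, angle):
        with pytest.raises(ValueError):
            make_config(placenta_cap_angle_deg=angle)

    def test_slice_spacing_below_thickness_rejected(self):
        with pytest.raises(ValueError):
            make_config(slice_spacing_mm=4.0)

    def test_event_beyond_session_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            make_config(n_frames=10, events=(EventSpec("placental", 1e5, 60, 0.1),))

    def test_motion_event_frame_out_of_range(self):
        with pytest.raises(ValueError):
            make_config(n_frames=10, motion_events=((99, "maternal", 5.0),))

    def test_amplitude_bounds(self):
        with pytest.raises(ValueError):
            EventSpec("placental", 0, 60, 0.6)
        with pytest.raises(ValueError):
            EventSpec("placental", 0, -5, 0.1)

    def test_sphericity_delta_sign_enforced(self):
        with pytest.raises(ValueError):
            EventSpec("placental", 0, 60, 0.1, sphericity_delta=-0.01)
        with pytest.raises(ValueError):
            EventSpec("uterine_local", 0, 60, 0.1, sphericity_delta=0.01)


class TestProfiles:
    def test_raised_cosine_halfmax(self):
        p = make_profile("raised_cosine")
        assert p.halfmax_fraction == 0.5
        npt.assert_allclose(p(np.array([0.25, 0.5, 0.75])), [0.5, 1.0, 0.5])
        assert p(np.array([-0.1, 1.1])).tolist() == [0.0, 0.0]

    def test_tukey_plateau_and_halfmax(self):
        p = make_profile("tukey", taper_fraction=0.25)
        assert p.halfmax_fraction == 0.75
        npt.assert_allclose(p(np.array([0.3, 0.5, 0.7])), 1.0)
        npt.assert_allclose(p(np.array([0.125, 0.875])), 0.5)

    def test_unknown_profile(self):
        with pytest.raises(ValueError):
            make_profile("boxcar")


class TestTimestamps:
    def test_minimum_and_monotonicity(self):
        cfg = make_config(n_frames=200)
        t = sample_timestamps(cfg)
        gaps = np.diff(t)
        assert t[0] == 0.0
        assert np.all(gaps >= cfg.tr_min_s)
        # mean repetition time approximately honoured
        assert abs(gaps.mean() - cfg.tr_mean_s) < 2.0

    def test_single_frame(self):
        assert sample_timestamps(make_config(n_frames=1)).tolist() == [0.0]


class TestRasterize:
    def test_sphere_volume_oracle(self, default_grid):
        r = 50.0
        lab = rasterize_to_slices(
            lambda p: (np.sum(p**2, axis=-1) <= r * r).astype(np.uint8),
            default_grid,
        )
        vol = measure_frame(lab, default_grid, compute_areas=False)
        expected = 4.0 / 3.0 * math.pi * r**3
        assert abs(vol.placental_volume_mm3 / expected - 1) < 0.03

    def test_empty_model(self, default_grid):
        lab = rasterize_to_slices(
            lambda p: np.zeros(p.shape[0], dtype=np.uint8), default_grid
        )
        assert not lab.any()

    def test_halfspace_splits_at_slice_plane(self, default_grid):
        zs = default_grid.axis_coordinates_mm()[2]
        z0 = (zs[11] + zs[12]) / 2.0  # midway between two slice centres
        lab = rasterize_to_slices(
            lambda p: (p[:, 2] < z0).astype(np.uint8), default_grid
        )
        below = zs < z0
        assert np.all(lab[:, :, below] == 1)
        assert np.all(lab[:, :, ~below] == 0)

    def test_subsample_minimum(self, default_grid):
        with pytest.raises(ValueError):
            rasterize_to_slices(
                lambda p: np.zeros(p.shape[0], dtype=np.uint8),
                default_grid,
                n_subsamples=2,
            )


class TestSimulateSession:
    def test_no_dynamics_frames_identical(self, quiet_session):
        _, series, gt = quiet_session
        assert len(gt) == 0
        for f in range(1, series.n_frames):
            npt.assert_array_equal(series.labels[f], series.labels[0])
            npt.assert_array_equal(series.signal[f], series.signal[0])

    def test_rest_volume_matches_continuous_oracle(self, quiet_session):
        config, series, _ = quiet_session
        ph = UteroPhantom(config)
        oracle = numeric_cap_slab_volume(
            config.uterus_semiaxes_mm, ph.theta0, ph.that0
        )
        measured = (
            (series.labels[0] == LABEL_PLACENTA).sum()
            * config.grid.voxel_volume_mm3
        )
        assert abs(measured / oracle - 1) < 0.02

    def test_peak_drop_matches_amplitude(self):
        cfg = make_config(
            n_frames=50,
            events=(EventSpec("placental", 180.0, 240.0, 0.2, **TUKEY),),
        )
        series, gt = simulate_session(cfg, compute_signal=False)
        assert len(gt) == 1 and gt.loc[0, "kind"] == "placental"
        assert gt.loc[0, "peak_volume_drop_frac"] == 0.2
        v = (series.labels == LABEL_PLACENTA).sum(axis=(1, 2, 3)).astype(float)
        rest = v[series.timestamps_s < 170].mean()
        drop = 1.0 - v.min() / rest
        # rasterization tolerance; looser here than on the full-size grid
        # because the compact test phantom has ~4x fewer placental voxels
        assert abs(drop - 0.2) < 0.02

    def test_seed_changes_noise_not_labels(self):
        base = dict(
            n_frames=6,
            events=(EventSpec("placental", 20.0, 60.0, 0.15),),
            noise_sd_fraction=0.02,
        )
        s1, _ = simulate_session(make_config(rng_seed=1, **base))
        s2, _ = simulate_session(make_config(rng_seed=2, **base))
        npt.assert_array_equal(s1.labels, s2.labels)
        assert not np.array_equal(s1.signal, s2.signal)

    def test_bit_identical_reruns(self):
        cfg = make_config(
            n_frames=6,
            events=(EventSpec("placental", 20.0, 60.0, 0.15),),
            noise_sd_fraction=0.02,
            motion_events=((3, "fetal", 1.0),),
        )
        s1, g1 = simulate_session(cfg)
        s2, g2 = simulate_session(cfg)
        npt.assert_array_equal(s1.labels, s2.labels)
        npt.assert_array_equal(s1.signal, s2.signal)
        npt.assert_array_equal(s1.timestamps_s, s2.timestamps_s)
        assert g1.equals(g2)

    def test_monotone_amplitude(self):
        mins = []
        for amp in (0.1, 0.2, 0.3):
            cfg = make_config(
                n_frames=40,
                events=(EventSpec("placental", 150.0, 240.0, amp, **TUKEY),),
            )
            series, _ = simulate_session(cfg, compute_signal=False)
            mins.append((series.labels == LABEL_PLACENTA).sum(axis=(1, 2, 3)).min())
        assert mins[0] > mins[1] > mins[2]

    def test_content_conservation(self, small_session):
        _, series, _ = small_session
        content = (series.labels == LABEL_CONTENT).sum(axis=(1, 2, 3)).astype(float)
        assert np.abs(content / content[0] - 1).max() < 0.02

    def test_ground_truth_halfmax_closed_form(self):
        cfg = make_config(
            n_frames=40,
            events=(EventSpec("placental", 150.0, 180.0, 0.2),),
        )
        _, gt = simulate_session(cfg, compute_signal=False)
        # raised cosine crosses half amplitude at quarter/three-quarter phase
        assert gt.loc[0, "halfmax_duration_s"] == pytest.approx(90.0)

    def test_truncated_event_flagged(self):
        cfg = make_config(
            n_frames=20, events=(EventSpec("placental", 250.0, 400.0, 0.2),)
        )
        _, gt = simulate_session(cfg, compute_signal=False)
        assert bool(gt.loc[0, "truncated_end"])


class TestSignStructure:
    @pytest.fixture(scope="class")
    @staticmethod
    def morph_measurements():
        out = {}
        for kind in ("placental", "uterine_uniform", "uterine_local"):
            cfg = make_config(
                n_frames=3, events=(EventSpec(kind, 0.0, 90.0, 0.2, **TUKEY),)
            )
            ph = UteroPhantom(cfg)
            frames = {}
            for name, t in (("rest", 1e6), ("peak", 45.0)):
                lab = rasterize_to_slices(
                    lambda p, t=t: ph.labels_at(p, t), cfg.grid
                )
                frames[name] = measure_frame(lab, cfg.grid)
            out[kind] = frames
        return out

    def test_placental_event_signs(self, morph_measurements):
        from uterodyn.geometry import sphericity

        rest, peak = (
            morph_measurements["placental"]["rest"],
            morph_measurements["placental"]["peak"],
        )
        s_rest = sphericity(
            rest.placental_volume_mm3, rest.placental_surface_area_mm2
        )
        s_peak = sphericity(
            peak.placental_volume_mm3, peak.placental_surface_area_mm2
        )
        assert s_peak - s_rest > 0.005
        assert peak.nonplacental_wall_area_mm2 > rest.nonplacental_wall_area_mm2
        assert peak.placental_bed_area_mm2 < rest.placental_bed_area_mm2

    @pytest.mark.parametrize("kind", ["uterine_uniform", "uterine_local"])
    def test_uterine_event_signs(self, morph_measurements, kind):
        from uterodyn.geometry import sphericity

        rest, peak = (
            morph_measurements[kind]["rest"],
            morph_measurements[kind]["peak"],
        )
        s_rest = sphericity(
            rest.placental_volume_mm3, rest.placental_surface_area_mm2
        )
        s_peak = sphericity(
            peak.placental_volume_mm3, peak.placental_surface_area_mm2
        )
        assert s_peak - s_rest <= 0.0
        assert peak.placental_volume_mm3 < rest.placental_volume_mm3

    def test_uterine_wall_area_does_not_increase(self, morph_measurements):
        for kind in ("uterine_uniform", "uterine_local"):
            rest = morph_measurements[kind]["rest"]
            peak = morph_measurements[kind]["peak"]
            assert peak.nonplacental_wall_area_mm2 <= rest.nonplacental_wall_area_mm2


class TestLabelsHygiene:
    def test_only_declared_labels(self, small_session):
        _, series, _ = small_session
        assert set(np.unique(series.labels)) <= {
            LABEL_BACKGROUND,
            LABEL_PLACENTA,
            LABEL_WALL,
            LABEL_CONTENT,
        }

    def test_timestamp_gaps_respect_minimum(self, small_session):
        config, series, _ = small_session
        assert np.all(np.diff(series.timestamps_s) >= config.tr_min_s)
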