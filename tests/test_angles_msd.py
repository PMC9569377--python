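"""Jump-angle anisotropy, border angles, MSD fitting."""

import numpy as np
import pytest
from scipy import stats
from shapely.geometry import Polygon

from conftest import brownian_track
from morphotrack.angles_msd import (
    AngleSample,
    angle_to_border,
    fold_anisotropy,
    jump_angles,
    msd_curve,
    msd_fit,
)
from morphotrack.tracking import Track


def track_from_points(points):
    points = np.asarray(points, dtype=float)
    return Track(frames=np.arange(len(points)), xy=points)


class TestJumpAngles:
    def test_collinear_forward_is_zero(self):
        tr = track_from_points([(0, 0), (1, 0), (2, 0)])
        sample = jump_angles([tr], min_jump=0.1)
        assert sample.n_angles == 1
        assert sample.angles[0] == pytest.approx(0.0, abs=1e-9)

    def test_reversal_is_180(self):
        tr = track_from_points([(0, 0), (1, 0), (0, 0)])
        sample = jump_angles([tr], min_jump=0.1)
        assert sample.angles[0] == pytest.approx(180.0)

    def test_left_right_turns_signed(self):
        right = track_from_points([(0, 0), (1, 0), (1, -1)])  # clockwise
        left = track_from_points([(0, 0), (1, 0), (1, 1)])
        a_right = jump_angles([right], min_jump=0.1).angles[0]
        a_left = jump_angles([left], min_jump=0.1).angles[0]
        assert a_left == pytest.approx(90.0)
        assert a_right == pytest.approx(270.0)

    def test_short_jumps_excluded(self):
        tr = track_from_points([(0, 0), (0.05, 0), (1, 0)])
        assert jump_angles([tr], min_jump=0.166).n_angles == 0

    def test_gap_interrupted_angles_excluded(self):
        tr = Track(frames=[0, 1, 3], xy=[(0, 0), (1, 0), (2, 0)])
        assert jump_angles([tr], min_jump=0.1).n_angles == 0

    def test_brownian_angles_are_uniform(self):
        tracks = [
            brownian_track(500, 5.0, seed=s, noise=0.0) for s in range(40)
        ]
        sample = jump_angles(tracks, min_jump=0.05)
        assert sample.n_angles > 10_000
        counts, _ = np.histogram(sample.angles, bins=36, range=(0, 360))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_histogram_symmetric_about_180(self):
        tracks = [brownian_track(400, 3.0, seed=s) for s in range(30)]
        sample = jump_angles(tracks, min_jump=0.05)
        counts, _ = np.histogram(sample.angles, bins=36, range=(0, 360))
        left, right = counts[:18], counts[18:][::-1]
        # left and right turns equally likely for reversible dynamics
        diff = np.abs(left - right) / np.sqrt(left + right + 1)
        assert diff.mean() < 3


class TestFoldAnisotropy:
    def test_uniform_angles_give_unity(self):
        rng = np.random.default_rng(0)
        sample = AngleSample(angles=rng.uniform(0, 360, 100_000))
        assert abs(fold_anisotropy(sample) - 1.0) < 0.05

    def test_all_reversals_flagged_infinite(self):
        sample = AngleSample(angles=np.full(100, 180.0))
        with pytest.warns(UserWarning):
            assert fold_anisotropy(sample) == np.inf

    def test_invariant_under_global_rotation(self):
        rng = np.random.default_rng(1)
        tracks = [brownian_track(200, 3.0, seed=s) for s in range(10)]
        theta = np.deg2rad(37.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        rotated = [
            Track(frames=t.frames.copy(), xy=t.xy @ rot.T) for t in tracks
        ]
        f1 = fold_anisotropy(jump_angles(tracks, min_jump=0.05))
        f2 = fold_anisotropy(jump_angles(rotated, min_jump=0.05))
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_confined_channel_increases_reversals(self):
        from morphotrack import geometry as G
        from morphotrack.simulator import SimConfig, run_simulation

        # 0.2 µm wide channel vs open field
        mask = np.zeros((400, 2000), dtype=np.uint8)
        mask[190:210, :] = 1
        channel = G.TissueGeometry(mask, 0.01)
        open_field = G.TissueGeometry(
            np.ones((2000, 2000), dtype=np.uint8), 0.01
        )
        fs = {}
        for name, geom in (("channel", channel), ("open", open_field)):
            cfg = SimConfig(n_agents=30, n_steps=150, tau=0.0, seed=3)
            res = run_simulation(geom, None, cfg)
            tracks = [
                Track(frames=np.arange(res.positions.shape[0]),
                      xy=res.positions[:, i, :])
                for i in range(res.positions.shape[1])
            ]
            fs[name] = fold_anisotropy(jump_angles(tracks, min_jump=0.166))
        assert fs["channel"] > 1.05
        assert fs["channel"] > fs["open"]
        assert abs(fs["open"] - 1.0) < 0.2


class TestAngleToBorder:
    def test_parallel_and_perpendicular(self):
        # densely sampled square border: local tangent is well defined
        side = np.linspace(0, 10, 51)
        verts = (
            [(x, 0.0) for x in side[:-1]]
            + [(10.0, y) for y in side[:-1]]
            + [(x, 10.0) for x in side[::-1][:-1]]
            + [(0.0, y) for y in side[::-1][:-1]]
        )
        poly = Polygon(verts)
        parallel = np.array([(4.0, 0.5), (5.0, 0.5)])
        perpendicular = np.array([(4.5, 0.2), (4.5, 1.2)])
        assert angle_to_border(parallel, poly) == pytest.approx(0.0, abs=1e-6)
        assert angle_to_border(perpendicular, poly) == pytest.approx(90.0, abs=1e-6)

    def test_matches_nearest_edge_oracle_away_from_corners(self):
        side = np.linspace(0, 10, 101)
        verts = (
            [(x, 0.0) for x in side[:-1]]
            + [(10.0, y) for y in side[:-1]]
            + [(x, 10.0) for x in side[::-1][:-1]]
            + [(0.0, y) for y in side[::-1][:-1]]
        )
        poly = Polygon(verts)
        edges = np.asarray(poly.exterior.coords)
        rng = np.random.default_rng(2)
        checked = 0
        for _ in range(200):
            mid = rng.uniform(1.5, 8.5, 2)
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            jump = np.array([mid - 0.1 * direction, mid + 0.1 * direction])
            # oracle: acute angle to the closest edge segment
            mids = 0.5 * (edges[:-1] + edges[1:])
            j = np.argmin(((mids - mid) ** 2).sum(axis=1))
            e = edges[j + 1] - edges[j]
            e = e / np.linalg.norm(e)
            cosang = abs(float(direction @ e))
            oracle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            got = angle_to_border(jump, poly)
            assert got == pytest.approx(oracle, abs=1e-6)
            checked += 1
        assert checked == 200

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(Exception):
            angle_to_border(
                np.array([(0, 0), (1, 0)]), Polygon([(0, 0), (1, 0), (1, 0)])
            )


class TestMsd:
    def test_stationary_track_gives_noise_floor(self):
        rng = np.random.default_rng(3)
        eps = 0.02
        xy = rng.normal(0.0, eps, size=(50, 2)) + 5.0
        tr = Track(frames=np.arange(50), xy=xy)
        res = msd_fit(tr, frame_cycle_time=0.0117)
        assert abs(res.D) < 0.02
        assert res.intercept == pytest.approx(4 * eps**2, rel=0.5)
        assert not res.discarded

    def test_bound_diffusion_recovered_within_10pct(self):
        results = [
            msd_fit(brownian_track(25, 0.5, seed=s), frame_cycle_time=0.0117)
            for s in range(100)
        ]
        mean_d = np.mean([r.D for r in results])
        assert abs(mean_d - 0.5) / 0.5 < 0.1

    def test_estimator_unbiased_at_scale(self):
        results = [
            msd_fit(brownian_track(30, 0.3, seed=1000 + s), frame_cycle_time=0.0117)
            for s in range(1000)
        ]
        mean_d = np.mean([r.D for r in results])
        assert abs(mean_d - 0.3) / 0.3 < 0.02

    def test_coordinate_scaling_quadruples_d(self):
        tr = brownian_track(30, 0.4, seed=5)
        doubled = Track(frames=tr.frames.copy(), xy=2.0 * tr.xy)
        d1 = msd_fit(tr, frame_cycle_time=0.0117).D
        d2 = msd_fit(doubled, frame_cycle_time=0.0117).D
        assert d2 == pytest.approx(4 * d1, rel=1e-9)

    def test_short_tracks_rejected_and_fast_flagged(self):
        with pytest.raises(ValueError):
            msd_fit(brownian_track(10, 0.5, seed=6))
        fast = msd_fit(brownian_track(40, 5.0, seed=7), frame_cycle_time=0.0117)
        assert fast.discarded

    def test_msd_curve_uses_overlapping_pairs(self):
        tr = track_from_points([(0, 0), (1, 0), (2, 0), (3, 0)])
        msd = msd_curve(tr, max_lag=3)
        assert msd[0] == pytest.approx(1.0)
        assert msd[1] == pytest.approx(4.0)
        assert msd[2] == pytest.approx(9.0)
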