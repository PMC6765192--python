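"""Speed classes, time budgets and the geometric path features."""

import math

import numpy as np
import pytest

import zebranvu as z
from zebranvu.features import EllipseFit, FeatureConfig
from zebranvu.segmentation import segment_by_zone, filter_short_segments
from conftest import brute_force_ellipse_area

SQ2 = math.sqrt(2.0)


class TestSpeeds:
    def test_simple_displacement(self):
        traj = z.Trajectory("t", t=[0, 1], x=[0, 7], y=[0, 0])
        np.testing.assert_allclose(z.instantaneous_speeds(traj), [7.0])

    def test_stationary(self):
        traj = z.Trajectory("t", t=[0, 1, 2], x=[1, 1, 1], y=[2, 2, 2])
        np.testing.assert_allclose(z.instantaneous_speeds(traj), [0.0, 0.0])

    def test_uniform_circular_motion_closed_form(self):
        r, theta, dt = 5.0, 0.3, 0.5
        ang = np.arange(20) * theta
        traj = z.Trajectory("t", t=np.arange(20) * dt, x=r * np.cos(ang), y=r * np.sin(ang))
        expected = 2 * r * math.sin(theta / 2) / dt
        np.testing.assert_allclose(z.instantaneous_speeds(traj), expected, rtol=1e-12)


class TestClassifySpeed:
    @pytest.mark.parametrize(
        "speed,expected",
        [(3.2, "inactive"), (4.8, "low"), (6.4, "high"), (0.0, "inactive"),
         (3.3, "low"), (6.39, "low"), (20.0, "high")],
    )
    def test_band_edges(self, speed, expected):
        assert z.classify_speed(np.array([speed]))[0] == expected

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            z.classify_speed(np.array([-1.0]))


def _schedule_trajectory():
    """Piecewise-constant 3-min schedule with hand-computable budgets.

    Minute 1: light, stationary.  Minute 2: light, 7 mm/s (high).
    Minute 3: dark, 4 mm/s (low).
    """
    t = np.arange(181.0)
    x = np.where(t < 120, -5.0, 5.0)
    y = np.zeros(181)
    sel = (t >= 61) & (t <= 120)
    y[sel & (t % 2 == 1)] = 7.0
    sel3 = t >= 121
    y[sel3] = 0.0
    y[sel3 & (t % 2 == 1)] = 4.0
    y[120] = 0.0
    return z.Trajectory("sched", t=t, x=x, y=y)


class TestTimeBudgets:
    def test_hand_computed_schedule(self, well):
        traj = _schedule_trajectory()
        labels = z.assign_zone(traj, well)
        classes = z.classify_speed(z.instantaneous_speeds(traj))
        out = z.time_budgets(traj, labels, classes, bin_s=60.0)
        assert out["pct_time_light"] == pytest.approx(200.0 / 3.0, abs=1e-12)
        light = out["zones"]["light"]
        assert light["pct_inactive"] == pytest.approx(50.0, abs=1e-12)
        assert light["pct_low"] == pytest.approx(0.0, abs=1e-12)
        assert light["pct_high"] == pytest.approx(50.0, abs=1e-12)
        dark = out["zones"]["dark"]
        assert dark["pct_low"] == pytest.approx(100.0, abs=1e-12)

    def test_half_time_in_light(self, well):
        t = np.arange(121.0)
        x = np.where(t < 60, -5.0, 5.0)
        traj = z.Trajectory("t", t=t, x=x, y=np.zeros(121))
        labels = z.assign_zone(traj, well)
        classes = z.classify_speed(z.instantaneous_speeds(traj))
        out = z.time_budgets(traj, labels, classes, bin_s=60.0)
        assert out["pct_time_light"] == pytest.approx(50.0)

    def test_normalisation_independent_of_light_share(self, well):
        """Always-fast-in-light gives pct_high(light) = 100 whatever the light share."""
        traj = _schedule_trajectory()
        labels = z.assign_zone(traj, well)
        classes = np.array(["high"] * 180)
        out = z.time_budgets(traj, labels, classes, bin_s=60.0)
        assert out["zones"]["light"]["pct_high"] == pytest.approx(100.0)
        assert out["pct_time_light"] == pytest.approx(200.0 / 3.0)

    def test_zone_percentages_sum_to_100(self, well):
        from zebranvu.synth import BehaviourParams, simulate_trajectory

        traj, _ = simulate_trajectory(BehaviourParams(seed=23, duration=300.0), well)
        labels = z.assign_zone(traj, well)
        classes = z.classify_speed(z.instantaneous_speeds(traj))
        out = z.time_budgets(traj, labels, classes)
        for zone in ("light", "dark"):
            b = out["zones"][zone]
            if b is not None:
                assert b["pct_inactive"] + b["pct_low"] + b["pct_high"] == pytest.approx(
                    100.0, abs=1e-9
                )

    def test_too_short_recording_rejected(self, well):
        traj = z.Trajectory("t", t=[0, 1, 2], x=[0, 0, 0], y=[0, 0, 0])
        labels = z.assign_zone(traj, well)
        with pytest.raises(ValueError, match="shorter than one bin"):
            z.time_budgets(traj, labels, np.array(["inactive", "inactive"]))


class TestMinEnclosingEllipse:
    def test_rectangle_corners(self):
        fit = z.min_enclosing_ellipse(np.array([[2, 1], [2, -1], [-2, 1], [-2, -1]], float))
        assert fit.centre == pytest.approx((0.0, 0.0), abs=1e-7)
        assert fit.a == pytest.approx(2 * SQ2, abs=1e-4)
        assert fit.b == pytest.approx(SQ2, abs=1e-4)

    def test_points_on_circle(self):
        ang = np.linspace(0, 2 * math.pi, 9)[:-1]
        pts = 3.5 * np.column_stack([np.cos(ang), np.sin(ang)])
        fit = z.min_enclosing_ellipse(pts)
        assert fit.a == pytest.approx(3.5, rel=1e-5)
        assert fit.b == pytest.approx(3.5, rel=1e-5)

    def test_two_points_degenerate(self):
        fit = z.min_enclosing_ellipse(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert fit.degenerate
        assert fit.a == pytest.approx(2.5)
        assert fit.b == 0.0
        assert fit.centre == pytest.approx((1.5, 2.0))

    def test_collinear_degenerate(self):
        pts = np.column_stack([np.linspace(0, 10, 50), np.linspace(0, 5, 50)])
        fit = z.min_enclosing_ellipse(pts)
        assert fit.degenerate
        assert fit.a == pytest.approx(math.hypot(10, 5) / 2, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            z.min_enclosing_ellipse(np.empty((0, 2)))

    def test_containment_and_minimality_vs_oracle(self):
        """Fit contains every point and matches the SLSQP area oracle to <1%."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = rng.normal(size=(int(rng.integers(5, 13)), 2))
            fit = z.min_enclosing_ellipse(pts, tol=1e-7)
            assert fit.form(pts).max() <= 1 + 10 * 1e-7
            area = math.pi * fit.a * fit.b
            oracle = brute_force_ellipse_area(pts)
            assert area <= 1.01 * oracle
            assert area >= oracle * (1 - 1e-3)


class TestDerivedFeatures:
    def test_eccentricity_circle_zero(self):
        assert z.eccentricity(EllipseFit((0, 0), 5.0, 5.0, 0.0)) == 0.0

    def test_eccentricity_rectangle_ellipse(self):
        fit = z.min_enclosing_ellipse(np.array([[2, 1], [2, -1], [-2, 1], [-2, -1]], float))
        assert z.eccentricity(fit) == pytest.approx(math.sqrt(3) / 2, abs=1e-6)

    def test_eccentricity_degenerate_is_one(self):
        fit = z.min_enclosing_ellipse(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert z.eccentricity(fit) == 1.0

    def test_eccentricity_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            z.eccentricity(EllipseFit((0, 0), 0.0, 0.0, 0.0, degenerate=False))

    def test_mpde_rectangle(self):
        pts = np.array([[2, 1], [2, -1], [-2, 1], [-2, -1]], float)
        fit = z.min_enclosing_ellipse(pts)
        assert z.mpde(pts, fit) == pytest.approx(math.sqrt(5), abs=1e-6)

    def test_mpde_coincident_points(self):
        pts = np.array([[1.0, 2.0]] * 4)
        fit = z.min_enclosing_ellipse(pts)
        assert z.mpde(pts, fit) == 0.0

    def test_mpde_matches_direct_loop(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(30, 2))
        fit = z.min_enclosing_ellipse(pts)
        direct = np.mean([math.hypot(p[0] - fit.centre[0], p[1] - fit.centre[1]) for p in pts])
        assert z.mpde(pts, fit) == pytest.approx(direct, abs=1e-12)

    def test_mpdc_examples(self, well):
        assert z.mpdc(np.array([[3.0, 4.0], [0.0, 5.0]]), well) == pytest.approx(5.0)
        assert z.mpdc(np.array([[0.0, 0.0]]), well) == 0.0
        pts = np.array([[3.0, 0.0], [0.0, 4.0], [5.0, 0.0]])
        assert z.mpdc(pts, well) == pytest.approx(4.0)

    def test_rigid_motion_invariance(self, well):
        """ε and MPDE are rigid-motion invariant; MPDC invariant under
        rotations about the well centre."""
        rng = np.random.default_rng(11)
        pts = rng.uniform(-4, 4, size=(15, 2))
        phi = 0.7
        R = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        moved = pts @ R.T + np.array([1.3, -2.1])
        rotated = pts @ R.T  # about the well centre (origin)
        f0, f1 = z.min_enclosing_ellipse(pts), z.min_enclosing_ellipse(moved)
        assert z.eccentricity(f1) == pytest.approx(z.eccentricity(f0), abs=1e-6)
        assert z.mpde(moved, f1) == pytest.approx(z.mpde(pts, f0), abs=1e-6)
        f2 = z.min_enclosing_ellipse(rotated)
        assert z.mpdc(rotated, well) == pytest.approx(z.mpdc(pts, well), abs=1e-9)
        assert z.eccentricity(f2) == pytest.approx(z.eccentricity(f0), abs=1e-6)


class TestLarvaFeatures:
    @staticmethod
    def _traj(group=z.TreatmentGroup("mannitol", False)):
        from zebranvu.synth import BehaviourParams, simulate_trajectory

        traj, _ = simulate_trajectory(BehaviourParams(seed=31, duration=300.0))
        traj.group = group
        return traj

    def test_zone_means_equal_direct_per_segment_means(self, well):
        """Per-zone feature means equal an independent per-segment recomputation."""
        traj = self._traj()
        rec = z.larva_features(traj, well)
        labels = z.assign_zone(traj, well)
        segs = segment_by_zone(traj, labels)
        kept, _ = filter_short_segments(segs)
        for zone in ("light", "dark"):
            zsegs = [s for s in kept if s.zone == zone]
            zf = rec.overall.zones[zone]
            if not zsegs:
                assert zf is None or zf.mean_eccentricity is None
                continue
            eccs, mpdcs = [], []
            for s in zsegs:
                pts = traj.points[s.start : s.end + 1]
                eccs.append(z.eccentricity(z.min_enclosing_ellipse(pts)))
                mpdcs.append(np.hypot(pts[:, 0], pts[:, 1]).mean())
            assert zf.mean_eccentricity == pytest.approx(np.mean(eccs), abs=1e-9)
            assert zf.mean_mpdc == pytest.approx(np.mean(mpdcs), abs=1e-9)

    def test_unvisited_zone_is_absent_not_zero(self, well):
        t = np.arange(121.0)
        x = -5 + 0.5 * np.sin(t)
        traj = z.Trajectory("t", t=t, x=x, y=np.zeros(121),
                            group=z.TreatmentGroup("mannitol", False))
        rec = z.larva_features(traj, well)
        assert rec.overall.zones["dark"] is None
        assert rec.overall.zones["light"] is not None

    def test_blocks_produced_when_configured(self, well):
        traj = self._traj()
        rec = z.larva_features(traj, well, FeatureConfig(block_s=150.0))
        assert len(rec.blocks) == 3  # blocks are whole 1-min bins: 2+2+1
        for fs in rec.blocks.values():
            assert 0.0 <= fs.pct_time_light <= 100.0
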