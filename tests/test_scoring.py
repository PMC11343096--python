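import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ommatidia.scoring import (DEFAULT_N_REQUESTED, EyeScore, LocalDisorder,
                               NeighborFan, build_neighbor_fans,
                               local_disorder, score_eye, score_points,
                               select_most_ordered)
from ommatidia.synthetic import LatticeSpec, generate_centers


def hexagon_fan(lengths=(10.0,) * 6, bearings=(0, 60, 120, 180, 240, 300)):
    """Fan with prescribed geometry, neighbors indexed 1..6 around center 0."""
    order = np.argsort(bearings)
    b = np.asarray(bearings, dtype=float)[order]
    l = np.asarray(lengths, dtype=float)[order]
    gaps = np.diff(np.append(b, b[0] + 360.0))
    return NeighborFan(center_index=0,
                       neighbor_indices=tuple(int(i) + 1 for i in order),
                       lengths=tuple(l), bearings=tuple(b), gaps=tuple(gaps))


def brute_force_six_nearest(points, i):
    """O(n^2) oracle: indices of the six nearest others of point i."""
    d = np.hypot(*(points - points[i]).T)
    d[i] = np.inf
    return set(np.argsort(d, kind="stable")[:6].tolist())


class TestBuildNeighborFans:
    def test_seven_point_hexagon_gives_single_regular_fan(self):
        ang = np.radians(np.arange(0, 360, 60))
        pts = np.vstack([[0.0, 0.0],
                         np.column_stack([10 * np.cos(ang),
                                          10 * np.sin(ang)])])
        fans = build_neighbor_fans(pts)
        assert len(fans) == 1
        fan = fans[0]
        assert fan.center_index == 0
        assert np.allclose(fan.lengths, 10.0)
        assert np.allclose(fan.gaps, 60.0)

    def test_lattice_interior_neighbors_at_spacing(self):
        spec = LatticeSpec(seed=0)
        pts = generate_centers(spec)
        fans = build_neighbor_fans(pts)
        assert fans, "a clean lattice must yield stable ommatidia"
        # interior fans: all six neighbors at exactly the lattice spacing
        interior = [f for f in fans
                    if np.allclose(f.lengths, spec.spacing_px, atol=1e-6)]
        assert len(interior) >= (spec.rows - 2) * (spec.cols - 2)
        for f in interior[:5]:
            assert np.allclose(f.gaps, 60.0, atol=1e-6)

    def test_matches_brute_force_knn_on_random_points(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 100, size=(200, 2))
        fans = build_neighbor_fans(pts)
        assert fans, "dense random points must yield some stable fans"
        for fan in fans:
            assert set(fan.neighbor_indices) == \
                brute_force_six_nearest(pts, fan.center_index)

    def test_fewer_than_seven_points_is_empty_not_error(self):
        assert build_neighbor_fans(np.zeros((0, 2))) == []
        rng = np.random.default_rng(0)
        assert build_neighbor_fans(rng.uniform(0, 10, (6, 2))) == []

    def test_gaps_sum_to_full_circle(self):
        rng = np.random.default_rng(7)
        fans = build_neighbor_fans(rng.uniform(0, 50, (80, 2)))
        for fan in fans:
            assert math.isclose(sum(fan.gaps), 360.0, abs_tol=1e-6)
            assert all(l > 0 for l in fan.lengths)


class TestLocalDisorder:
    def test_regular_hexagon_has_zero_disorder(self):
        ld = local_disorder(hexagon_fan())
        assert ld.odi_d == 0.0
        assert ld.odi_a == 0.0
        assert ld.odi_local == 0.0

    def test_single_long_vector_contributes_its_excess(self):
        # five lengths 10, one 12: sum over five longest of (l - v_min) = 2
        ld = local_disorder(hexagon_fan(lengths=(12, 10, 10, 10, 10, 10)))
        assert ld.odi_d == pytest.approx(2.0)
        assert ld.odi_a == pytest.approx(0.0)

    def test_single_displaced_bearing_contributes_gap_excess(self):
        # bearings 0,70,120,...: gaps {70,50,60,60,60,60}; theta_min = 50;
        # five largest gaps minus theta_min: 20 + 10*4 = 60
        ld = local_disorder(hexagon_fan(bearings=(0, 70, 120, 180, 240, 300)))
        assert ld.odi_d == pytest.approx(0.0)
        assert ld.odi_a == pytest.approx(60.0)

    def test_agrees_with_direct_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            lengths = rng.uniform(5, 20, 6)
            bearings = np.sort(rng.uniform(0, 360, 6))
            fan = hexagon_fan(lengths=lengths, bearings=bearings)
            ld = local_disorder(fan)
            v_min = min(fan.lengths)
            gaps = sorted(fan.gaps)
            assert ld.odi_d == pytest.approx(
                sum(sorted(fan.lengths)[1:]) - 5 * v_min)
            assert ld.odi_a == pytest.approx(sum(gaps[1:]) - 5 * gaps[0])
            assert ld.odi_local == ld.odi_d + ld.odi_a


class TestSelectMostOrdered:
    def test_ties_broken_by_ascending_index(self):
        locals_ = [LocalDisorder(center_index=i, odi_d=0.0, odi_a=0.0)
                   for i in (4, 1, 3, 0, 2)]
        picked = select_most_ordered(locals_, 3)
        assert [l.center_index for l in picked] == [0, 1, 2]

    def test_selects_smallest_disorder(self):
        vals = {0: 4.0, 1: 1.5, 2: 3.2, 3: 0.9}
        locals_ = [LocalDisorder(center_index=i, odi_d=v, odi_a=0.0)
                   for i, v in vals.items()]
        picked = select_most_ordered(locals_, 2)
        assert [l.odi_local for l in picked] == [0.9, 1.5]

    def test_saturates_at_available_count(self):
        locals_ = [LocalDisorder(center_index=i, odi_d=float(i), odi_a=0.0)
                   for i in range(4)]
        assert len(select_most_ordered(locals_, 100)) == 4
        assert select_most_ordered([], 5) == []


class TestScoreEye:
    def test_zero_disorder_propagates(self):
        locals_ = [LocalDisorder(center_index=i, odi_d=0.0, odi_a=0.0)
                   for i in range(110)]
        score = score_eye(locals_, z=120, n_requested=100)
        assert score.odi == 0.0
        assert score.p == 0.0
        assert score.n_used == 100
        assert score.z == 120

    def test_formula_on_two_ommatidia(self):
        locals_ = [LocalDisorder(center_index=0, odi_d=2.0, odi_a=0.0),
                   LocalDisorder(center_index=1, odi_d=0.0, odi_a=60.0)]
        score = score_eye(locals_, z=7, n_requested=2)
        assert score.odi_d_total == pytest.approx(2.0)
        assert score.odi_a_total == pytest.approx(60.0)
        assert score.odi == pytest.approx(62.0)
        # independent arithmetic: (62 / 2) * (2 / 7)
        assert score.p == pytest.approx(62.0 / 7.0)

    def test_default_n_requested_is_200(self):
        locals_ = [LocalDisorder(center_index=i, odi_d=1.0, odi_a=0.0)
                   for i in range(5)]
        assert score_eye(locals_, z=10).n_requested == 200
        assert DEFAULT_N_REQUESTED == 200

    def test_no_detections_flags_p_undefined(self):
        score = score_eye([], z=0, n_requested=50)
        assert score.z == 0
        assert score.odi == 0.0
        assert score.p is None

    def test_stable_subset_precondition_enforced(self):
        locals_ = [LocalDisorder(center_index=i, odi_d=0.0, odi_a=0.0)
                   for i in range(5)]
        with pytest.raises(ValueError):
            score_eye(locals_, z=3)
        with pytest.raises(ValueError):
            score_eye(locals_, z=10, n_requested=0)

    def test_odi_nondecreasing_in_n_requested(self):
        rng = np.random.default_rng(11)
        locals_ = [LocalDisorder(center_index=i, odi_d=float(d), odi_a=0.0)
                   for i, d in enumerate(rng.uniform(0, 5, 40))]
        odis = [score_eye(locals_, z=40, n_requested=n).odi
                for n in range(1, 60)]
        assert all(b >= a for a, b in zip(odis, odis[1:]))


class TestGeometricInvariance:
    @staticmethod
    def _score_all(pts):
        fans = build_neighbor_fans(pts)
        return {f.center_index: local_disorder(f) for f in fans}

    def test_rigid_motion_leaves_scores_unchanged(self):
        rng = np.random.default_rng(21)
        pts = rng.uniform(0, 100, size=(120, 2))
        theta = np.radians(37.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([250.0, -40.0])
        base, trans = self._score_all(pts), self._score_all(moved)
        assert base.keys() == trans.keys()
        for i in base:
            assert base[i].odi_d == pytest.approx(trans[i].odi_d, abs=1e-9)
            assert base[i].odi_a == pytest.approx(trans[i].odi_a, abs=1e-9)
        s0, s1 = score_points(pts), score_points(moved)
        assert s0.odi == pytest.approx(s1.odi, abs=1e-9)
        assert s0.p == pytest.approx(s1.p, abs=1e-9)

    def test_scaling_scales_distance_index_only(self):
        rng = np.random.default_rng(22)
        pts = rng.uniform(0, 100, size=(90, 2))
        s = 3.7
        base, scaled = self._score_all(pts), self._score_all(pts * s)
        assert base.keys() == scaled.keys()
        for i in base:
            assert scaled[i].odi_d == pytest.approx(s * base[i].odi_d,
                                                    rel=1e-9, abs=1e-9)
            assert scaled[i].odi_a == pytest.approx(base[i].odi_a,
                                                    rel=1e-9, abs=1e-9)


class TestScoreProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_disorder_indices_never_negative(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(7, 120))
        pts = rng.uniform(0, 60, size=(n, 2))
        fans = build_neighbor_fans(pts)
        for fan in fans:
            ld = local_disorder(fan)
            assert ld.odi_d >= 0.0
            assert ld.odi_a >= 0.0
        score = score_points(pts)
        assert score.odi_d_total >= 0.0
        assert score.odi_a_total >= 0.0
        assert score.odi == pytest.approx(
            score.odi_d_total + score.odi_a_total, abs=1e-9)
        assert score.n_used <= score.z


class TestEyeScoreInvariants:
    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ValueError):
            EyeScore(odi_d_total=1.0, odi_a_total=1.0, odi=3.0, z=10,
                     n_requested=5, n_used=5, p=0.1)

    def test_n_used_cannot_exceed_z(self):
        with pytest.raises(ValueError):
            EyeScore(odi_d_total=0.0, odi_a_total=0.0, odi=0.0, z=3,
                     n_requested=5, n_used=5, p=0.0)
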