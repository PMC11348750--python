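"""Candidate paths, simplification, scoring, persistence clustering and
false-connection pruning."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rootcrown as rc
from rootcrown.skeleton import SkeletonVertex, _edge
from rootcrown.stem import classify_stem
from rootcrown.whorls import (
    CandidatePath,
    cluster_whorls,
    dedup_by_boundary_edge,
    find_candidate_paths,
    mean_shift_1d,
    prune_false_connections,
    rdp_simplify,
    score_value,
    turning_point,
)

from conftest import build_skeleton, random_skeleton, straight_stem


def bruteforce_candidates(skeleton, stem, cls):
    """Independent oracle: minimal path lengths junction -> boundary edge,
    honoring the unusable-edge rules, by exhaustive simple-path enumeration."""
    stem_edges = stem.edges()
    g = nx.Graph()
    g.add_nodes_from(skeleton.vertices)
    for e in skeleton.edges:
        if e in stem_edges or (not cls.inside[e[0]] and not cls.inside[e[1]]):
            continue
        g.add_edge(*e, length=skeleton.edge_length(e))
    expected = {}
    for v in cls.junctions_on_stem:
        for a, b in cls.boundary_edges:
            inner, outer = (a, b) if cls.inside[a] else (b, a)
            best = None
            for path in nx.all_simple_paths(g, v, inner):
                length = sum(
                    g[p][q]["length"] for p, q in zip(path[:-1], path[1:])
                )
                if best is None or length < best[0]:
                    best = (length, path)
            if v == inner:
                best = (0.0, [v])
            if best is None:
                continue  # unreachable: no candidate expected
            if len(best[1]) < 2 or best[1][-2] == outer:
                continue  # degenerate cases the detector rejects
            expected[(v, _edge(inner, outer))] = best[0]
    return expected


class TestCandidatePaths:
    def test_no_boundary_edges_gives_empty_list(self):
        sk, stem = straight_stem(thickness=3.0)
        cls = classify_stem(sk, stem)
        assert find_candidate_paths(sk, stem, cls) == []

    def test_y_fixture_single_path_ending_in_boundary_edge(self):
        # stem of 4, junction at vertex 1, branch 1-4-5-6 walking outward;
        # with r = 2 the boundary (2.4 mm) is crossed on edge (5, 6)
        sk, stem = straight_stem(n=4, thickness=2.0)
        for vid, x in ((4, 1.0), (5, 2.0), (6, 6.0)):
            sk.add_vertex(SkeletonVertex(vid, (x, 0.0, -2.0 - 0.5 * x), 0.8))
        sk.add_edge(1, 4)
        sk.add_edge(4, 5)
        sk.add_edge(5, 6)
        cls = classify_stem(sk, stem)
        assert cls.boundary_edges == {(5, 6)}
        paths = find_candidate_paths(sk, stem, cls)
        assert len(paths) == 1
        p = paths[0]
        assert p.start_vertex == 1
        assert p.vertex_ids == [1, 4, 5, 6]
        assert p.boundary_edge == (5, 6)
        assert p.start_arc == pytest.approx(2.0)

    def test_lengths_match_bruteforce_enumeration(self):
        rng = np.random.default_rng(29)
        checked = 0
        for _ in range(60):
            sk, stem = random_skeleton(rng, n_extra=rng.integers(4, 9))
            cls = classify_stem(sk, stem)
            expected = bruteforce_candidates(sk, stem, cls)
            got = {}
            for p in find_candidate_paths(sk, stem, cls):
                length = sum(
                    sk.edge_length(_edge(a, b))
                    for a, b in zip(p.vertex_ids[:-2], p.vertex_ids[1:-1])
                )
                key = (p.start_vertex, p.boundary_edge)
                got[key] = min(length, got.get(key, np.inf))
            assert set(got) == set(expected)
            for key in expected:
                assert got[key] == pytest.approx(expected[key], rel=1e-9)
            checked += len(expected)
        assert checked > 20  # the random family must actually exercise paths

    def test_interior_never_uses_stem_edges(self, ref_crown):
        skeleton, stem, _ = ref_crown
        cls = classify_stem(skeleton, stem)
        stem_edges = stem.edges()
        for p in find_candidate_paths(skeleton, stem, cls):
            interior = {
                _edge(a, b)
                for a, b in zip(p.vertex_ids[:-1], p.vertex_ids[1:])
            }
            assert not (interior & stem_edges)


class TestRdp:
    def test_collinear_points_keep_forced_split(self):
        pts = np.array([[i, 0, 0] for i in range(5)], float)
        out = rdp_simplify(pts, 0.5)
        assert len(out) == 3
        assert (out[0] == pts[0]).all() and (out[-1] == pts[-1]).all()

    def test_right_angle_elbow_keeps_all_three_points(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        out = rdp_simplify(pts, 0.1)
        assert len(out) == 3
        np.testing.assert_array_equal(out, pts)

    def test_properties_on_random_polylines(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = rng.integers(3, 30)
            pts = rng.uniform(-10, 10, (n, 3))
            eps = rng.uniform(0.1, 5.0)
            out = rdp_simplify(pts, eps)
            assert len(out) >= 3
            in_set = {tuple(p) for p in pts}
            assert all(tuple(p) in in_set for p in out)  # subset of input
            # every input point within eps of the simplified polyline
            for p in pts:
                d = min(
                    _point_to_segment(p, out[i], out[i + 1])
                    for i in range(len(out) - 1)
                )
                assert d <= eps + 1e-9

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            rdp_simplify(np.zeros((1, 3)), 1.0)


def _point_to_segment(p, a, b):
    ab = b - a
    denom = ab @ ab
    if denom == 0:
        return np.linalg.norm(p - a)
    t = np.clip((p - a) @ ab / denom, 0, 1)
    return np.linalg.norm(p - (a + t * ab))


class TestTurningPoint:
    def test_straight_line_angle_zero(self):
        pt, angle = turning_point(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float))
        assert angle == pytest.approx(0.0)
        np.testing.assert_array_equal(pt, [1, 0, 0])

    def test_right_angle(self):
        pt, angle = turning_point(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], float))
        assert angle == pytest.approx(math.pi / 2)
        np.testing.assert_array_equal(pt, [1, 0, 0])

    def test_matches_bruteforce_max_over_interior_angles(self):
        rng = np.random.default_rng(37)
        for _ in range(50):
            pts = rng.uniform(-5, 5, (6, 3))
            pt, angle = turning_point(pts)
            angles = []
            for i in range(1, 5):
                u = pts[i] - pts[i - 1]
                w = pts[i + 1] - pts[i]
                cosv = u @ w / (np.linalg.norm(u) * np.linalg.norm(w))
                angles.append(math.acos(np.clip(cosv, -1, 1)))
            assert angle == pytest.approx(max(angles))
            np.testing.assert_array_equal(pt, pts[1 + int(np.argmax(angles))])

    def test_tie_breaks_to_smallest_index(self):
        # two identical right angles: the first (closest to the stem) wins
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]], float
        )
        pt, angle = turning_point(pts)
        np.testing.assert_array_equal(pt, [1, 0, 0])


class TestScore:
    def test_no_turn_far_from_stem_scores_one(self):
        # alpha = 0 and the turning point >= 10 voxels beyond the surface
        assert score_value(0.0, dist_mm=10.0, r_v_mm=2.0, pitch_mm=0.44) == 1.0

    def test_right_angle_at_stem_surface(self):
        s = score_value(math.pi / 2, dist_mm=2.0, r_v_mm=2.0, pitch_mm=0.44)
        assert s == pytest.approx(math.exp(-2), rel=1e-12)

    def test_midrange_corner(self):
        # alpha = pi/4 and 5 voxels beyond the surface -> e^-1
        s = score_value(math.pi / 4, dist_mm=2.0 + 5 * 0.44, r_v_mm=2.0, pitch_mm=0.44)
        assert s == pytest.approx(math.exp(-1), rel=1e-12)

    def test_full_reversal_at_surface_is_the_floor(self):
        s = score_value(math.pi, dist_mm=1.0, r_v_mm=1.0, pitch_mm=0.44)
        assert s == pytest.approx(math.exp(-3), rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        alpha=st.floats(0, math.pi),
        dist=st.floats(0, 50),
        r=st.floats(0.1, 5),
        pitch=st.floats(0.1, 1.0),
    )
    def test_bounds(self, alpha, dist, r, pitch):
        s = score_value(alpha, dist, r, pitch)
        assert math.exp(-3) - 1e-12 <= s <= 1.0 + 1e-12

    def test_monotonicity(self):
        # decreasing in alpha at fixed distance; non-decreasing in distance
        for d in (0.0, 2.0, 4.0):
            scores = [
                score_value(a, 2.0 + d, 2.0, 0.44)
                for a in np.linspace(0, math.pi, 10)
            ]
            assert all(x > y for x, y in zip(scores, scores[1:]))
        for a in (0.0, 1.0, math.pi):
            scores = [
                score_value(a, 2.0 + d, 2.0, 0.44)
                for d in np.linspace(0, 8, 10)
            ]
            assert all(x <= y + 1e-15 for x, y in zip(scores, scores[1:]))


def _dummy_path(start_arc, score, edge=(100, 101), ids=None):
    ids = ids or [0, 100, 101]
    pts = np.array([[i, 0, 0] for i in range(len(ids))], float)
    return CandidatePath(
        start_vertex=ids[0],
        vertex_ids=ids,
        boundary_edge=edge,
        polyline=pts,
        simplified=pts,
        turning_pt=pts[1],
        turning_angle=0.0,
        score=score,
        start_arc=start_arc,
    )


class TestDedup:
    def test_single_path_unchanged(self):
        p = _dummy_path(0.0, 0.5)
        assert dedup_by_boundary_edge([p]) == [p]

    def test_highest_score_kept(self):
        lo = _dummy_path(0.0, 0.4, ids=[0, 7, 100, 101])
        hi = _dummy_path(5.0, 0.9, ids=[1, 100, 101])
        kept = dedup_by_boundary_edge([lo, hi])
        assert kept == [hi]

    def test_matches_groupby_argmax_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            paths = []
            for k in range(rng.integers(1, 15)):
                edge = (int(rng.integers(0, 4)) * 2, int(rng.integers(0, 4)) * 2 + 1)
                paths.append(
                    _dummy_path(
                        float(rng.uniform(0, 100)),
                        float(rng.uniform(0.05, 1.0)),
                        edge=edge,
                        ids=[k, edge[0], edge[1]],
                    )
                )
            kept = dedup_by_boundary_edge(paths)
            by_edge = {}
            for p in paths:
                by_edge.setdefault(p.boundary_edge, []).append(p)
            assert len(kept) == len(by_edge)
            for p in kept:
                assert p.score == max(q.score for q in by_edge[p.boundary_edge])


class TestClustering:
    def test_mean_shift_groups_by_gap(self):
        labels = mean_shift_1d(np.array([0.0, 1.0, 2.0, 40.0, 41.0]), 10.0)
        assert list(labels) == [0, 0, 0, 1, 1]

    def test_identical_paths_single_whorl_full_persistence(self):
        paths = [_dummy_path(10.0, 0.5, ids=[0, 100 + i, 101 + i]) for i in range(4)]
        whorls, ladder = cluster_whorls(paths, 10.0)
        assert len(whorls) == 1
        assert whorls[0].n_nodal_roots == 4
        lo, hi = ladder.selected_run
        assert hi - lo == len(ladder.deltas)

    def test_low_score_outlier_between_two_groups(self):
        # high-scoring extremes, mid-scoring interiors: once the outlier's
        # threshold is passed, the 2-cluster signature persists to the top
        scores_a, scores_b = (0.9, 0.5, 0.9), (0.9, 0.6, 0.9)
        paths = []
        for i, (arc, s) in enumerate(zip((0.0, 1.0, 2.0), scores_a)):
            paths.append(_dummy_path(arc, s, ids=[i, 200 + i, 201 + i]))
        for i, (arc, s) in enumerate(zip((40.0, 41.0, 42.0), scores_b)):
            paths.append(_dummy_path(arc, s, ids=[10 + i, 300 + i, 301 + i]))
        paths.append(_dummy_path(20.0, 0.05, ids=[99, 400, 401]))  # outlier
        whorls, ladder = cluster_whorls(paths, 10.0)
        assert len(whorls) == 2
        assert whorls[0].n_nodal_roots == 3
        assert whorls[1].n_nodal_roots == 3
        # the selected run sits above the outlier's threshold
        assert ladder.deltas[ladder.selected_run[0]] > 0.05

    def test_membership_includes_low_score_paths_inside_interval(self):
        paths = [
            _dummy_path(0.0, 0.9, ids=[0, 200, 201]),
            _dummy_path(2.0, 0.9, ids=[1, 202, 203]),
            _dummy_path(1.0, 0.06, ids=[2, 204, 205]),  # low score, inside
        ]
        whorls, _ = cluster_whorls(paths, 10.0)
        assert len(whorls) == 1
        assert whorls[0].n_nodal_roots == 3

    def test_selection_matches_exhaustive_delta_sweep(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            paths = [
                _dummy_path(
                    float(rng.uniform(0, 120)),
                    float(rng.uniform(0.05, 1.0)),
                    ids=[k, 500 + 2 * k, 501 + 2 * k],
                )
                for k in range(rng.integers(2, 12))
            ]
            whorls, ladder = cluster_whorls(paths, 10.0)
            # oracle: recompute the run-length table independently
            sigs = ladder.signatures
            runs = []
            i = 0
            while i < len(sigs):
                j = i
                while j + 1 < len(sigs) and sigs[j + 1] == sigs[i]:
                    j += 1
                runs.append((i, j + 1))
                i = j + 1
            best = max(runs, key=lambda r: (r[1] - r[0], r[0]))
            assert ladder.selected_run == best
            assert sigs[ladder.selected_run[0]] == sigs[best[0]]

    def test_deterministic_for_fixed_input(self):
        rng = np.random.default_rng(47)
        paths = [
            _dummy_path(float(rng.uniform(0, 100)), float(rng.uniform(0, 1)),
                        ids=[k, 600 + 2 * k, 601 + 2 * k])
            for k in range(8)
        ]
        w1, l1 = cluster_whorls(paths, 10.0)
        w2, l2 = cluster_whorls(paths, 10.0)
        assert [w.location_arc for w in w1] == [w.location_arc for w in w2]
        assert l1.selected_run == l2.selected_run


class TestPruning:
    def _crown_with_bridge(self):
        """Stem + one honest nodal path + one bridged (clinging) chain."""
        sk, stem = straight_stem(n=6, thickness=2.0)
        # honest branch at junction 1 crossing the boundary at (11, 12)
        for vid, pos in ((10, (1.5, 0, -2.5)), (11, (2.3, 0, -3.0)), (12, (5, 0, -4))):
            sk.add_vertex(SkeletonVertex(vid, pos, 0.8))
        sk.add_edge(1, 10)
        sk.add_edge(10, 11)
        sk.add_edge(11, 12)
        # clinging-root bridge: junction 3 -> sharply bent chain -> vertex 12
        for vid, pos in ((20, (1.2, 0, -6.5)), (21, (2.2, 0, -6.0))):
            sk.add_vertex(SkeletonVertex(vid, pos, 0.7))
        sk.add_edge(3, 20)
        sk.add_edge(20, 21)
        sk.add_edge(21, 12)  # closes a cycle through the stem
        return sk, stem

    def test_bridge_interior_removed_and_cycle_broken(self):
        sk, stem = self._crown_with_bridge()
        assert sk.cycle_rank() == 1
        cls = classify_stem(sk, stem)
        paths = find_candidate_paths(sk, stem, cls)
        nodal = [p for p in paths if p.start_vertex == 1 and p.vertex_ids[1] == 10]
        pruned, removed = prune_false_connections(sk, stem, nodal)
        assert pruned.cycle_rank() == 0
        assert 20 not in pruned.vertices and 21 not in pruned.vertices
        # the trace runs through the degree-2 merge point and stops just
        # short of the nodal path's own edges
        assert (3, 20) in removed and (20, 21) in removed and (12, 21) in removed

    def test_nodal_path_edges_all_preserved(self):
        sk, stem = self._crown_with_bridge()
        cls = classify_stem(sk, stem)
        paths = find_candidate_paths(sk, stem, cls)
        nodal = [p for p in paths if p.start_vertex == 1 and p.vertex_ids[1] == 10]
        pruned, _ = prune_false_connections(sk, stem, nodal)
        for p in nodal:
            assert p.edges() <= pruned.edges

    def test_unchanged_when_every_edge_is_nodal(self):
        sk, stem = straight_stem(n=4, thickness=2.0)
        for vid, x in ((4, 1.0), (5, 2.0), (6, 6.0)):
            sk.add_vertex(SkeletonVertex(vid, (x, 0.0, -2.0), 0.8))
        sk.add_edge(1, 4)
        sk.add_edge(4, 5)
        sk.add_edge(5, 6)
        cls = classify_stem(sk, stem)
        paths = find_candidate_paths(sk, stem, cls)
        pruned, removed = prune_false_connections(sk, stem, paths)
        assert removed == []
        assert pruned.edges == sk.edges

    def test_stem_edges_never_removed(self, ref_crown):
        skeleton, stem, _ = ref_crown
        cls = classify_stem(skeleton, stem)
        paths = rc.dedup_by_boundary_edge(
            find_candidate_paths(skeleton, stem, cls)
        )
        whorls, _ = cluster_whorls(paths, 10.0)
        nodal = [m for w in whorls for m in w.members]
        pruned, _ = prune_false_connections(skeleton, stem, nodal)
        assert stem.edges() <= pruned.edges
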