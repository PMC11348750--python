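"""Whorl detection on a root-crown curve skeleton.

Nodal roots emerge from the stem in circumferential clusters (whorls).  On
the skeleton, each putative emergence is a *candidate path*: the shortest
skeleton path from a stem junction to a stem-boundary edge.  A genuine
nodal root bends smoothly under gravity, whereas a spurious connection to a
root clinging to the stem bends sharply just outside the stem surface.
Each candidate path is therefore simplified (Ramer-Douglas-Peucker with a
forced first split), its sharpest turn located, and scored

    S(P) = exp(-2*alpha/pi - (10 - clamp(|v - v_P| - r_v, 0, 10)) / 10)

with alpha the largest turning angle (radians), v the stem junction the
path starts from, v_P the turning point, r_v the stem thickness at v, and
the distance term measured in voxels.  S is close to 1 for straight paths
that bend far from the stem and drops toward exp(-3) for sharp bends at the
stem surface.

Whorls are the clusters of candidate-path start positions (arc length along
the stem) that persist over the longest consecutive run of score thresholds
— a parameter-free alternative to picking a single score cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .skeleton import Skeleton, StemPath, _edge, path_length
from .stem import StemClassification, arc_position

__all__ = [
    "CandidatePath",
    "Whorl",
    "ScoreLadder",
    "find_candidate_paths",
    "rdp_simplify",
    "turning_point",
    "score_path",
    "score_value",
    "dedup_by_boundary_edge",
    "mean_shift_1d",
    "cluster_whorls",
    "prune_false_connections",
    "DEFAULT_RDP_EPSILON_VOXELS",
    "DEFAULT_CLAMP_VOXELS",
    "DEFAULT_BANDWIDTH_MM",
]

logger = logging.getLogger(__name__)

#: RDP simplification tolerance, in voxels (1.32 mm at 0.44 mm pitch).
DEFAULT_RDP_EPSILON_VOXELS = 3.0
#: Clamp of the turning-point-to-stem-surface distance, voxels (4.4 mm).
DEFAULT_CLAMP_VOXELS = 10.0
#: Mean-shift bandwidth on stem arc positions, mm (about one internode or less).
DEFAULT_BANDWIDTH_MM = 10.0

Edge = Tuple[int, int]


@dataclass
class CandidatePath:
    """A scored putative nodal-root emergence."""

    start_vertex: int  # stem junction v
    vertex_ids: List[int]  # skeleton path, last edge = boundary edge
    boundary_edge: Edge
    polyline: np.ndarray  # raw positions of vertex_ids
    simplified: np.ndarray  # RDP polyline, >= 3 points
    turning_pt: np.ndarray  # v_P
    turning_angle: float  # alpha_P, radians in [0, pi]
    score: float
    start_arc: float  # mm along the stem from the top

    def edges(self) -> Set[Edge]:
        return {_edge(a, b) for a, b in zip(self.vertex_ids[:-1], self.vertex_ids[1:])}


@dataclass
class Whorl:
    """A cluster of candidate paths at one stem location."""

    members: List[CandidatePath]
    location_arc: float  # mean member start arc, mm
    location_depth: float = float("nan")  # filled once a depth reference is known
    index: Optional[int] = None  # soil-relative index, assigned later

    @property
    def n_nodal_roots(self) -> int:
        return len(self.members)

    @property
    def arc_interval(self) -> Tuple[float, float]:
        arcs = [m.start_arc for m in self.members]
        return (min(arcs), max(arcs))


@dataclass
class ScoreLadder:
    """Per-threshold clustering record used by the persistence selection."""

    deltas: List[float]  # ascending candidate scores
    signatures: List[tuple]  # clustering signature at each delta
    selected_run: Tuple[int, int] = (0, 0)  # [start, end) into deltas


# -- candidate path search -------------------------------------------------


def find_candidate_paths(
    skeleton: Skeleton,
    stem: StemPath,
    classification: StemClassification,
    rdp_epsilon_mm: Optional[float] = None,
    clamp_voxels: float = DEFAULT_CLAMP_VOXELS,
) -> List[CandidatePath]:
    """Shortest paths from every stem junction to every stem-boundary edge.

    Edge weight is Euclidean length.  Stem-path edges and edges with both
    endpoints outside the stem are unusable (treated as infinite weight).
    Each shortest path is extended by the boundary edge incident to its
    final vertex; paths that collapse below three distinct points after
    simplification are discarded.
    """
    if rdp_epsilon_mm is None:
        rdp_epsilon_mm = DEFAULT_RDP_EPSILON_VOXELS * skeleton.voxel_pitch
    inside = classification.inside
    stem_edges = stem.edges()
    g = nx.Graph()
    g.add_nodes_from(skeleton.vertices)
    for a, b in skeleton.edges:
        if _edge(a, b) in stem_edges:
            continue
        if not inside[a] and not inside[b]:
            continue
        g.add_edge(a, b, length=skeleton.edge_length((a, b)))

    # inside endpoints of boundary edges, with their outside partners
    targets: Dict[int, List[int]] = {}
    for a, b in classification.boundary_edges:
        inner, outer = (a, b) if inside[a] else (b, a)
        targets.setdefault(inner, []).append(outer)

    out: List[CandidatePath] = []
    for v in classification.junctions_on_stem:
        if v not in g:
            continue
        dists, paths = nx.single_source_dijkstra(g, v, weight="length")
        start_arc = arc_position(stem, v)
        for inner, outers in sorted(targets.items()):
            if inner not in paths:
                continue
            for outer in sorted(outers):
                node_path = paths[inner]
                if len(node_path) >= 2 and node_path[-2] == outer:
                    continue  # shortest path already used the boundary edge
                cand = _build_candidate(
                    skeleton,
                    stem,
                    v,
                    node_path + [outer],
                    _edge(inner, outer),
                    start_arc,
                    rdp_epsilon_mm,
                    clamp_voxels,
                )
                if cand is not None:
                    out.append(cand)
    return out


def _build_candidate(
    skeleton: Skeleton,
    stem: StemPath,
    v: int,
    vertex_ids: List[int],
    boundary_edge: Edge,
    start_arc: float,
    rdp_epsilon_mm: float,
    clamp_voxels: float,
) -> Optional[CandidatePath]:
    poly = skeleton.positions_array(vertex_ids)
    if len(vertex_ids) < 3:
        logger.warning(
            "candidate at junction %d collapsed to %d points; discarded",
            v,
            len(vertex_ids),
        )
        return None
    simplified = rdp_simplify(poly, rdp_epsilon_mm)
    if len(np.unique(simplified, axis=0)) < 3:
        logger.warning(
            "candidate at junction %d has < 3 distinct points after "
            "simplification; discarded",
            v,
        )
        return None
    pt, angle = turning_point(simplified)
    score = score_value(
        angle,
        dist_mm=float(np.linalg.norm(skeleton.position(v) - pt)),
        r_v_mm=skeleton.thickness(v),
        pitch_mm=skeleton.voxel_pitch,
        clamp_voxels=clamp_voxels,
    )
    return CandidatePath(
        start_vertex=v,
        vertex_ids=vertex_ids,
        boundary_edge=boundary_edge,
        polyline=poly,
        simplified=simplified,
        turning_pt=pt,
        turning_angle=angle,
        score=score,
        start_arc=start_arc,
    )


# -- simplification and scoring --------------------------------------------


def _seg_dist(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances of points to segment ab."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _rdp(points: np.ndarray, eps: float, lo: int, hi: int, keep: set) -> None:
    if hi <= lo + 1:
        return
    d = _seg_dist(points[lo + 1 : hi], points[lo], points[hi])
    i = int(np.argmax(d))
    if d[i] > eps:
        split = lo + 1 + i
        keep.add(split)
        _rdp(points, eps, lo, split, keep)
        _rdp(points, eps, split, hi, keep)


def rdp_simplify(points: np.ndarray, epsilon_mm: float, force_first: bool = True) -> np.ndarray:
    """Ramer-Douglas-Peucker simplification with a forced first split.

    The farthest point from the end-to-end segment is always inserted even
    when within tolerance, so the output has >= 3 points whenever the input
    does — the minimum needed to measure a turning angle.  Every input
    point lies within ``epsilon_mm`` of the output polyline.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    if not epsilon_mm > 0:
        raise ValueError("epsilon must be > 0")
    if len(pts) == 2:
        return pts.copy()
    keep = {0, len(pts) - 1}
    if force_first:
        d = _seg_dist(pts[1:-1], pts[0], pts[-1])
        split = 1 + int(np.argmax(d))
        keep.add(split)
        _rdp(pts, epsilon_mm, 0, split, keep)
        _rdp(pts, epsilon_mm, split, len(pts) - 1, keep)
    else:
        _rdp(pts, epsilon_mm, 0, len(pts) - 1, keep)
    return pts[sorted(keep)]


def turning_point(simplified: np.ndarray) -> Tuple[np.ndarray, float]:
    """Interior vertex with the largest turning angle, and that angle.

    The turning angle at an interior vertex is the angle between the
    incoming and outgoing segment directions: 0 for a straight
    continuation, pi for a full reversal.  Ties break to the smallest
    index (closest to the stem end).
    """
    pts = np.asarray(simplified, dtype=float)
    if len(pts) < 3:
        raise ValueError("turning point needs >= 3 points")
    best_i, best_angle = 1, -1.0
    for i in range(1, len(pts) - 1):
        u = pts[i] - pts[i - 1]
        w = pts[i + 1] - pts[i]
        nu, nw = np.linalg.norm(u), np.linalg.norm(w)
        if nu == 0 or nw == 0:
            angle = 0.0
        else:
            angle = float(np.arccos(np.clip(u @ w / (nu * nw), -1.0, 1.0)))
        if angle > best_angle:
            best_i, best_angle = i, angle
    return pts[best_i].copy(), best_angle


def score_value(
    alpha: float,
    dist_mm: float,
    r_v_mm: float,
    pitch_mm: float,
    clamp_voxels: float = DEFAULT_CLAMP_VOXELS,
) -> float:
    """Candidate-path score.

    ``alpha`` is the largest turning angle (radians); ``dist_mm`` the
    distance from the stem junction to the turning point; ``r_v_mm`` the
    stem thickness at the junction.  The surface distance
    ``dist - r_v`` is converted to voxels and clamped to [0, clamp] before
    entering the exponent, so the value lies in [exp(-3), 1].
    """
    d_vox = (dist_mm - r_v_mm) / pitch_mm
    t = min(max(d_vox, 0.0), clamp_voxels)
    return math.exp(-2.0 * alpha / math.pi - (clamp_voxels - t) / clamp_voxels)


def score_path(cand: CandidatePath, skeleton: Skeleton, clamp_voxels: float = DEFAULT_CLAMP_VOXELS) -> float:
    """Recompute the score of a candidate path from its stored geometry."""
    v = cand.start_vertex
    return score_value(
        cand.turning_angle,
        dist_mm=float(np.linalg.norm(skeleton.position(v) - cand.turning_pt)),
        r_v_mm=skeleton.thickness(v),
        pitch_mm=skeleton.voxel_pitch,
        clamp_voxels=clamp_voxels,
    )


def dedup_by_boundary_edge(paths: Sequence[CandidatePath]) -> List[CandidatePath]:
    """Keep one candidate path per boundary edge: the highest-scoring one.

    Ties break to the shorter path, then the lexicographically smallest
    vertex-id sequence, making the result deterministic.
    """
    best: Dict[Edge, CandidatePath] = {}
    for p in paths:
        q = best.get(p.boundary_edge)
        if q is None or _dedup_key(p) > _dedup_key(q):
            best[p.boundary_edge] = p
    return [best[e] for e in sorted(best)]


def _dedup_key(p: CandidatePath):
    # higher score wins; then shorter path; then smaller id sequence
    return (p.score, -path_length(p.polyline), [-i for i in p.vertex_ids])


# -- persistence clustering ------------------------------------------------


def mean_shift_1d(values: np.ndarray, bandwidth: float, tol: float = 1e-8) -> np.ndarray:
    """Flat-kernel mean shift on scalars; returns a cluster label per value.

    Each point iterates to the mean of the points within ``bandwidth`` of
    its current position; converged modes closer than ``bandwidth / 2`` are
    merged.  Deterministic: labels are ordered by ascending mode position.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return np.zeros(0, dtype=int)
    if not bandwidth > 0:
        raise ValueError("bandwidth must be > 0")
    modes = x.copy()
    for _ in range(500):
        shifted = np.array(
            [x[np.abs(x - m) <= bandwidth].mean() for m in modes]
        )
        if np.max(np.abs(shifted - modes)) < tol:
            modes = shifted
            break
        modes = shifted
    # merge modes closer than bandwidth / 2 (group by sorted gaps)
    order = np.argsort(modes, kind="stable")
    merged: List[List[int]] = []
    for idx in order:
        if merged and modes[idx] - modes[merged[-1][-1]] < bandwidth / 2:
            merged[-1].append(idx)
        else:
            merged.append([idx])
    centers = np.array([modes[grp].mean() for grp in map(np.array, merged)])
    labels = np.empty(x.size, dtype=int)
    for lab, grp in enumerate(merged):
        labels[np.array(grp)] = lab
    # relabel by ascending center so label order is spatial
    order = np.argsort(centers, kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(l)] for l in labels])


def _extreme_key(p: CandidatePath):
    # identify a path stably: by start arc, then id sequence
    return (p.start_arc, tuple(p.vertex_ids))


def _signature(paths: List[CandidatePath], labels: np.ndarray) -> tuple:
    """Clustering signature: per cluster, its lowest and highest member.

    Two clusterings are equal iff they have the same number of clusters and
    matched clusters share the same extreme (lowest / highest by stem arc)
    candidate paths.
    """
    sig = []
    for lab in range(labels.max() + 1):
        members = [p for p, l in zip(paths, labels) if l == lab]
        lo = min(members, key=_extreme_key)
        hi = max(members, key=_extreme_key)
        sig.append((_extreme_key(lo), _extreme_key(hi)))
    return tuple(sorted(sig))


def cluster_whorls(
    paths: Sequence[CandidatePath],
    bandwidth_mm: float = DEFAULT_BANDWIDTH_MM,
) -> Tuple[List[Whorl], ScoreLadder]:
    """Threshold-persistent mean-shift clustering of candidate paths.

    For every threshold delta in the ascending list of candidate scores,
    the start arcs of the paths scoring >= delta are clustered.  The
    clustering that stays identical for the most consecutive thresholds is
    selected (ties go to the run at higher thresholds, where spurious
    low-score paths have dropped out).  Each selected cluster becomes a
    whorl, and — since false connections are rare right at a whorl — every
    candidate path whose start arc falls inside the cluster's arc interval
    is counted as one of its nodal roots, regardless of score.
    """
    if not paths:
        raise ValueError("cluster_whorls needs at least one candidate path")
    paths = list(paths)
    deltas = sorted(p.score for p in paths)
    signatures: List[tuple] = []
    for delta in deltas:
        subset = [p for p in paths if p.score >= delta]
        labels = mean_shift_1d(np.array([p.start_arc for p in subset]), bandwidth_mm)
        signatures.append(_signature(subset, labels))

    # longest run of identical consecutive signatures; ties -> later run
    best = (0, 1)
    i = 0
    while i < len(signatures):
        j = i
        while j + 1 < len(signatures) and signatures[j + 1] == signatures[i]:
            j += 1
        if j + 1 - i >= best[1] - best[0]:
            best = (i, j + 1)
        i = j + 1

    winning = signatures[best[0]]
    whorls = []
    for (lo_key, hi_key) in winning:
        lo_arc, hi_arc = lo_key[0], hi_key[0]
        members = [p for p in paths if lo_arc <= p.start_arc <= hi_arc]
        members.sort(key=_extreme_key)
        whorls.append(
            Whorl(
                members=members,
                location_arc=float(np.mean([m.start_arc for m in members])),
            )
        )
    whorls.sort(key=lambda w: w.location_arc)
    ladder = ScoreLadder(deltas=deltas, signatures=signatures, selected_run=best)
    return whorls, ladder


# -- false-connection pruning ----------------------------------------------


def prune_false_connections(
    skeleton: Skeleton,
    stem: StemPath,
    nodal_paths: Sequence[CandidatePath],
) -> Tuple[Skeleton, List[Edge]]:
    """Remove stem-attached edge chains that no nodal candidate path uses.

    From every stem junction, each incident non-stem edge that does not
    belong to a nodal candidate path starts a trace through degree-2
    vertices, stopping at the next junction (degree >= 3) or a leaf.  The
    traced edges and interior vertices are removed (the two chain ends are
    kept); stem-path edges are never removed.  Returns the pruned skeleton
    and the list of removed edges.
    """
    nodal_edges: Set[Edge] = set()
    for p in nodal_paths:
        nodal_edges |= p.edges()
    stem_edges = stem.edges()
    deg = skeleton.degrees()
    junctions = [v for v in stem.vertex_ids if deg[v] >= 3]
    adj = skeleton.adjacency()

    remove_edges: Set[Edge] = set()
    remove_vertices: Set[int] = set()
    stem_set = set(stem.vertex_ids)
    for j in junctions:
        for n in adj[j]:
            first = _edge(j, n)
            if first in stem_edges or first in nodal_edges or first in remove_edges:
                continue
            chain = [j, n]
            while deg[chain[-1]] == 2 and chain[-1] not in stem_set:
                prev, cur = chain[-2], chain[-1]
                nxt = [w for w in adj[cur] if w != prev]
                if not nxt:
                    break
                # never consume a nodal-path (or stem) edge: stop short
                e = _edge(cur, nxt[0])
                if e in nodal_edges or e in stem_edges:
                    break
                chain.append(nxt[0])
            for a, b in zip(chain[:-1], chain[1:]):
                remove_edges.add(_edge(a, b))
            remove_vertices.update(chain[1:-1])

    kept_edges = skeleton.edges - remove_edges
    # interior vertices go; chain ends stay even if now isolated off-stem
    kept_ids = set(skeleton.vertices) - remove_vertices
    pruned = Skeleton(
        (skeleton.vertices[i] for i in sorted(kept_ids)),
        (e for e in kept_edges if e[0] in kept_ids and e[1] in kept_ids),
        skeleton.voxel_pitch,
    )
    if remove_edges:
        logger.info("pruned %d false-connection edges", len(remove_edges))
    return pruned, sorted(remove_edges)
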