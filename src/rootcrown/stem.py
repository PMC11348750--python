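"""Classifying skeleton vertices and edges relative to the stem.

A vertex is *inside the stem* when its Euclidean distance to the nearest
stem-path vertex ``v`` is at most ``multiplier * r_v`` (inclusive), where
``r_v`` is the thickness at that nearest vertex.  The default multiplier of
1.2 reflects that the maize stem is markedly thicker than the roots that
branch off it.  A *stem-boundary edge* has exactly one endpoint inside; a
*junction* is a stem-path vertex of skeleton degree >= 3 — the points where
nodal roots (or spurious connections) attach.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .skeleton import Skeleton, SkeletonError, SkeletonVertex, StemPath, _edge

__all__ = [
    "StemClassification",
    "classify_stem",
    "is_inside_stem",
    "stem_boundary_edges",
    "arc_position",
    "detect_stem_path",
    "DEFAULT_STEM_MULTIPLIER",
]

DEFAULT_STEM_MULTIPLIER = 1.2

Edge = Tuple[int, int]


@dataclass
class StemClassification:
    """Inside/outside partition of the skeleton relative to the stem."""

    inside: Dict[int, bool]
    boundary_edges: Set[Edge]
    junctions_on_stem: List[int]  # ordered top -> bottom


def _nearest_stem(
    positions: np.ndarray, skeleton: Skeleton, stem: StemPath
) -> Tuple[np.ndarray, np.ndarray]:
    """Distances to the nearest stem-path vertex and that vertex's thickness.

    Nearest is taken over stem-path vertices only (not the polyline between
    them), matching the vertex-based definition of the inside test.
    """
    stem_pos = skeleton.positions_array(stem.vertex_ids)
    tree = cKDTree(stem_pos)
    dist, idx = tree.query(positions)
    r = np.array([skeleton.thickness(stem.vertex_ids[i]) for i in idx])
    return np.asarray(dist, float), r


def is_inside_stem(
    vertex: SkeletonVertex,
    stem: StemPath,
    skeleton: Skeleton,
    multiplier: float = DEFAULT_STEM_MULTIPLIER,
) -> bool:
    """Inside test for a single vertex (inclusive at the threshold)."""
    dist, r = _nearest_stem(vertex.position.reshape(1, 3), skeleton, stem)
    return bool(dist[0] <= multiplier * r[0])


def classify_stem(
    skeleton: Skeleton,
    stem: StemPath,
    multiplier: float = DEFAULT_STEM_MULTIPLIER,
) -> StemClassification:
    """Compute the inside map, boundary edges and stem junctions."""
    ids = sorted(skeleton.vertices)
    pos = skeleton.positions_array(ids)
    dist, r = _nearest_stem(pos, skeleton, stem)
    inside = {vid: bool(d <= multiplier * rv) for vid, d, rv in zip(ids, dist, r)}
    boundary = stem_boundary_edges(skeleton, inside)
    deg = skeleton.degrees()
    junctions = [vid for vid in stem.vertex_ids if deg[vid] >= 3]
    return StemClassification(inside, boundary, junctions)


def stem_boundary_edges(skeleton: Skeleton, inside: Dict[int, bool]) -> Set[Edge]:
    """Edges with exactly one endpoint inside the stem."""
    return {e for e in skeleton.edges if inside[e[0]] != inside[e[1]]}


def arc_position(stem: StemPath, stem_vertex_id: int) -> float:
    """Cumulative arc length (mm) of a stem vertex from the top."""
    return float(stem.arc_lengths[stem.index_of(stem_vertex_id)])


def detect_stem_path(skeleton: Skeleton) -> StemPath:
    """Fallback stem heuristic: maximal-thickness walk from the topmost vertex.

    Starts at the vertex with the largest Z and greedily follows the
    unvisited neighbour of maximal thickness until none remains.  Intended
    for synthetic skeletons whose stem record is absent; real pipelines
    should carry an explicit stem path.
    """
    if skeleton.n_vertices < 2:
        raise SkeletonError("skeleton too small for stem detection")
    adj = skeleton.adjacency()
    start = max(skeleton.vertices, key=lambda v: skeleton.position(v)[2])
    path = [start]
    seen = {start}
    while True:
        cand = [n for n in adj[path[-1]] if n not in seen]
        if not cand:
            break
        nxt = max(cand, key=lambda n: (skeleton.thickness(n), -n))
        path.append(nxt)
        seen.add(nxt)
    if len(path) < 2:
        raise SkeletonError("stem heuristic found no path from the topmost vertex")
    return StemPath.from_skeleton(skeleton, path)
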