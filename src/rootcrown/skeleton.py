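"""Core data model for root-crown curve skeletons.

A curve skeleton is an undirected spatial graph extracted from a 3D scan of
an excavated root crown.  Every vertex carries a 3D position (mm) and a
thickness measure (mm, a radius-like quantity from the skeletonization); the
*stem path* is an ordered chain of vertices running along the root stem from
the stalk end (top) down to the tip.

Conventions used throughout the package:

* all geometry is stored in millimetres;
* the vertical axis is Z, pointing **up** — depth is measured top-down from
  a reference point (normally the first stem-path vertex), so points below
  the reference have positive depth;
* constants that are naturally expressed in voxels (simplification
  tolerance, score clamp) are converted to mm through ``Skeleton.voxel_pitch``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "SkeletonVertex",
    "Skeleton",
    "StemPath",
    "SkeletonError",
    "DEFAULT_VOXEL_PITCH_MM",
    "path_length",
    "depth_of",
]

#: Physical size of one voxel in mm (scan resolution after downsampling).
DEFAULT_VOXEL_PITCH_MM = 0.44

Edge = Tuple[int, int]


class SkeletonError(ValueError):
    """Raised for malformed skeletons, stem paths or input files."""


def _edge(a: int, b: int) -> Edge:
    """Canonical (sorted) form of an undirected edge."""
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class SkeletonVertex:
    """A skeleton vertex: integer id, 3D position (mm), thickness (mm)."""

    id: int
    position: np.ndarray
    thickness: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if not self.thickness > 0:
            raise SkeletonError(
                f"vertex {self.id}: thickness must be > 0, got {self.thickness}"
            )


class Skeleton:
    """Undirected spatial graph of a root crown.

    Vertices are keyed by integer id; edges are unordered id pairs.  The
    graph may contain cycles on input (clinging nodal roots and residual
    topological noise create them); cycle breaking happens downstream.
    """

    def __init__(
        self,
        vertices: Iterable[SkeletonVertex] = (),
        edges: Iterable[Edge] = (),
        voxel_pitch: float = DEFAULT_VOXEL_PITCH_MM,
    ) -> None:
        if not voxel_pitch > 0:
            raise SkeletonError(f"voxel_pitch must be > 0, got {voxel_pitch}")
        self.voxel_pitch = float(voxel_pitch)
        self.vertices: Dict[int, SkeletonVertex] = {}
        self.edges: Set[Edge] = set()
        for v in vertices:
            self.add_vertex(v)
        for a, b in edges:
            self.add_edge(a, b)

    # -- construction -----------------------------------------------------

    def add_vertex(self, vertex: SkeletonVertex) -> None:
        if vertex.id in self.vertices:
            raise SkeletonError(f"duplicate vertex id {vertex.id}")
        self.vertices[vertex.id] = vertex

    def add_edge(self, a: int, b: int) -> None:
        if a == b:
            raise SkeletonError(f"self-loop at vertex {a}")
        for vid in (a, b):
            if vid not in self.vertices:
                raise SkeletonError(f"edge ({a}, {b}) references unknown vertex {vid}")
        self.edges.add(_edge(a, b))

    # -- queries -----------------------------------------------------------

    def __contains__(self, vid: int) -> bool:
        return vid in self.vertices

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def position(self, vid: int) -> np.ndarray:
        return self.vertices[vid].position

    def thickness(self, vid: int) -> float:
        return self.vertices[vid].thickness

    def edge_length(self, edge: Edge) -> float:
        a, b = edge
        return float(np.linalg.norm(self.position(a) - self.position(b)))

    def neighbors(self, vid: int) -> List[int]:
        return sorted(
            (b if a == vid else a) for a, b in self.edges if vid in (a, b)
        )

    def adjacency(self) -> Dict[int, List[int]]:
        adj: Dict[int, List[int]] = {vid: [] for vid in self.vertices}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        for lst in adj.values():
            lst.sort()
        return adj

    def degree(self, vid: int) -> int:
        return sum(1 for e in self.edges if vid in e)

    def degrees(self) -> Dict[int, int]:
        deg = {vid: 0 for vid in self.vertices}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def positions_array(self, ids: Sequence[int]) -> np.ndarray:
        return np.array([self.position(i) for i in ids], dtype=float)

    def to_networkx(self) -> "nx.Graph":
        g = nx.Graph()
        for vid, v in self.vertices.items():
            g.add_node(vid, position=v.position, thickness=v.thickness)
        for a, b in self.edges:
            g.add_edge(a, b, length=self.edge_length((a, b)))
        return g

    def copy(self) -> "Skeleton":
        return Skeleton(self.vertices.values(), self.edges, self.voxel_pitch)

    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())

    def cycle_rank(self) -> int:
        """Number of independent cycles, E - V + components."""
        return self.n_edges - self.n_vertices + self.n_components()

    def validate(self) -> None:
        """Check edge references, self-loops and thickness positivity."""
        for a, b in self.edges:
            if a == b:
                raise SkeletonError(f"self-loop at vertex {a}")
            for vid in (a, b):
                if vid not in self.vertices:
                    raise SkeletonError(f"dangling edge ({a}, {b}): unknown id {vid}")

    def __iter__(self) -> Iterator[SkeletonVertex]:
        return iter(self.vertices.values())


@dataclass
class StemPath:
    """Ordered chain of stem vertices, first = top (stalk end), last = bottom.

    ``arc_lengths[i]`` is the cumulative path length in mm from the top
    vertex to ``vertex_ids[i]``; arc 0 at the top.
    """

    vertex_ids: List[int]
    arc_lengths: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @classmethod
    def from_skeleton(cls, skeleton: Skeleton, vertex_ids: Sequence[int]) -> "StemPath":
        ids = list(vertex_ids)
        if len(ids) < 2:
            raise SkeletonError("stem path needs at least 2 vertices")
        arcs = [0.0]
        for a, b in zip(ids[:-1], ids[1:]):
            if _edge(a, b) not in skeleton.edges:
                raise SkeletonError(f"stem path step ({a}, {b}) is not a skeleton edge")
            arcs.append(arcs[-1] + skeleton.edge_length((a, b)))
        return cls(ids, np.asarray(arcs))

    def __len__(self) -> int:
        return len(self.vertex_ids)

    @property
    def top(self) -> int:
        return self.vertex_ids[0]

    @property
    def bottom(self) -> int:
        return self.vertex_ids[-1]

    @property
    def length(self) -> float:
        return float(self.arc_lengths[-1])

    def index_of(self, vid: int) -> int:
        try:
            return self.vertex_ids.index(vid)
        except ValueError:
            raise SkeletonError(f"vertex {vid} is not on the stem path") from None

    def edges(self) -> Set[Edge]:
        return {
            _edge(a, b) for a, b in zip(self.vertex_ids[:-1], self.vertex_ids[1:])
        }

    def reversed(self, skeleton: Skeleton) -> "StemPath":
        return StemPath.from_skeleton(skeleton, list(reversed(self.vertex_ids)))


# -- geometry utilities ----------------------------------------------------


def path_length(points: np.ndarray) -> float:
    """Total length (mm) of a polyline: the sum of Euclidean segment lengths.

    Always at least the straight-line distance between the endpoints.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise SkeletonError(f"polyline needs >= 2 3D points, got shape {pts.shape}")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def depth_of(position: np.ndarray, top_reference: np.ndarray) -> float:
    """Top-down depth (mm) of a point relative to a reference point.

    0 at the reference (normally the stem-path top vertex), increasing
    downward (−Z); points above the reference get negative depths.
    """
    return float(np.asarray(top_reference, float)[2] - np.asarray(position, float)[2])
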