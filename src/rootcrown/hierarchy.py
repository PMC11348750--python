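"""Cycle breaking and hierarchy labeling of a pruned skeleton.

Residual cycles (after false-connection pruning) are broken with a
spanning tree that keeps the thickest edges — thin edges are the likeliest
artifacts.  Hierarchy labels are then propagated outward from the stem:
stem edges are level 0, branches leaving the stem are level 1 (nodal
roots), their children level 2 (first-order laterals), and so on.  At a
branching point the child that continues straightest keeps its parent's
level; every other child starts a new branch one level deeper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .skeleton import Skeleton, StemPath, _edge
from .whorls import CandidatePath

__all__ = ["Branch", "HierarchyLabeling", "break_cycles", "label_hierarchy"]

logger = logging.getLogger(__name__)

Edge = Tuple[int, int]


@dataclass
class Branch:
    """A maximal chain of same-label edges, ordered from its attachment."""

    label: int
    vertex_ids: List[int]
    parent: Optional[int] = None  # index into HierarchyLabeling.branches
    children: List[int] = field(default_factory=list)

    def edges(self) -> List[Edge]:
        return [_edge(a, b) for a, b in zip(self.vertex_ids[:-1], self.vertex_ids[1:])]


@dataclass
class HierarchyLabeling:
    """Edge labels (0 stem, 1 nodal, 2+ lateral) plus the branch tree."""

    edge_label: Dict[Edge, int]
    branches: List[Branch]

    def max_label(self) -> int:
        return max(self.edge_label.values(), default=0)

    def edges_with_label_at_least(self, level: int) -> List[Edge]:
        return [e for e, lab in self.edge_label.items() if lab >= level]


def break_cycles(
    skeleton: Skeleton, stem: Optional[StemPath] = None
) -> Tuple[Skeleton, List[Edge]]:
    """Break all cycles with a maximum-thickness spanning tree.

    Per connected component, the spanning tree maximizing the total mean
    endpoint thickness of retained edges is kept; stem-path edges are
    pinned so they always survive.  Returns the acyclic skeleton and the
    removed edges.
    """
    g = nx.Graph()
    g.add_nodes_from(skeleton.vertices)
    stem_edges = stem.edges() if stem is not None else set()
    for a, b in skeleton.edges:
        w = 0.5 * (skeleton.thickness(a) + skeleton.thickness(b))
        if _edge(a, b) in stem_edges:
            w += 1e9  # pin stem edges into the tree
        g.add_edge(a, b, weight=w)
    tree = nx.maximum_spanning_tree(g, weight="weight")
    kept = {_edge(a, b) for a, b in tree.edges}
    removed = sorted(skeleton.edges - kept)
    out = Skeleton(skeleton.vertices.values(), kept, skeleton.voxel_pitch)
    if removed:
        logger.info("cycle breaking removed %d edges", len(removed))
    return out, removed


def _direction_change(
    skeleton: Skeleton, prev: int, cur: int, nxt: int
) -> float:
    u = skeleton.position(cur) - skeleton.position(prev)
    w = skeleton.position(nxt) - skeleton.position(cur)
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        return 0.0
    return float(np.arccos(np.clip(u @ w / (nu * nw), -1.0, 1.0)))


def label_hierarchy(
    tree: Skeleton,
    stem: StemPath,
    nodal_paths: Sequence[CandidatePath] = (),
) -> HierarchyLabeling:
    """Propagate hierarchy labels outward from the stem on an acyclic skeleton.

    Every branch leaving a stem vertex starts at level 1.  At an off-stem
    junction the outgoing edge with the smallest direction change relative
    to the incoming edge continues the current branch; the others become
    children one level deeper.
    """
    if tree.cycle_rank() != 0:
        raise ValueError("label_hierarchy requires an acyclic skeleton")
    for p in nodal_paths:
        missing = [e for e in p.edges() if e not in tree.edges]
        if missing:
            logger.warning(
                "nodal path at junction %d lost %d edges to cycle breaking; "
                "relabeling from its stem attachment",
                p.start_vertex,
                len(missing),
            )
    adj = tree.adjacency()
    stem_set = set(stem.vertex_ids)
    edge_label: Dict[Edge, int] = {e: 0 for e in stem.edges() if e in tree.edges}
    stem_branch = Branch(label=0, vertex_ids=list(stem.vertex_ids), parent=None)
    branches: List[Branch] = [stem_branch]

    # seeds: (branch start vertex on parent, first off-branch vertex, label, parent idx)
    stack: List[Tuple[int, int, int, int]] = []
    for v in stem.vertex_ids:
        for n in sorted(adj[v]):
            e = _edge(v, n)
            if e in edge_label or n in stem_set:
                continue
            stack.append((v, n, 1, 0))

    while stack:
        start, first, label, parent_idx = stack.pop()
        branch = Branch(label=label, vertex_ids=[start], parent=parent_idx)
        idx = len(branches)
        branches.append(branch)
        branches[parent_idx].children.append(idx)
        prev, cur = start, first
        while True:
            edge_label[_edge(prev, cur)] = label
            branch.vertex_ids.append(cur)
            nxt = [w for w in sorted(adj[cur]) if _edge(cur, w) not in edge_label]
            if not nxt:
                break
            cont = min(nxt, key=lambda w: (_direction_change(tree, prev, cur, w), w))
            for w in nxt:
                if w != cont:
                    stack.append((cur, w, label + 1, idx))
            prev, cur = cur, cont
    return HierarchyLabeling(edge_label=edge_label, branches=branches)
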