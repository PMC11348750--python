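"""Shared fixtures: hand-built mini skeletons, a reference synthetic crown,
and helpers for random test skeletons."""

from __future__ import annotations

import numpy as np
import pytest

import rootcrown as rc
from rootcrown.skeleton import Skeleton, SkeletonVertex, StemPath


def build_skeleton(vertices, edges, pitch=0.44):
    """vertices: list of (id, (x, y, z), thickness)."""
    sk = Skeleton(voxel_pitch=pitch)
    for vid, pos, th in vertices:
        sk.add_vertex(SkeletonVertex(vid, pos, th))
    for a, b in edges:
        sk.add_edge(a, b)
    return sk


def straight_stem(n=6, spacing=2.0, thickness=3.0, pitch=0.44):
    """Vertical stem along -Z: vertex i at depth i * spacing."""
    verts = [(i, (0.0, 0.0, -i * spacing), thickness) for i in range(n)]
    edges = [(i, i + 1) for i in range(n - 1)]
    sk = build_skeleton(verts, edges, pitch)
    return sk, StemPath.from_skeleton(sk, list(range(n)))


def random_skeleton(rng, n_extra=8, n_stem=4, box=20.0):
    """Small random skeleton: a straight stem plus random off-stem vertices
    wired with a random spanning tree and a few extra edges."""
    sk, stem = straight_stem(n=n_stem, spacing=4.0, thickness=2.0)
    ids = []
    for k in range(n_extra):
        vid = n_stem + k
        pos = rng.uniform(-box, box, 3)
        sk.add_vertex(SkeletonVertex(vid, pos, rng.uniform(0.5, 1.5)))
        ids.append(vid)
    all_ids = list(range(n_stem)) + ids
    for vid in ids:  # connect each new vertex somewhere: keeps it reachable
        other = int(rng.choice([i for i in all_ids if i < vid]))
        sk.add_edge(vid, other)
    for _ in range(rng.integers(0, 4)):  # extra edges may close cycles
        a, b = rng.choice(all_ids, 2, replace=False)
        if a != b and (min(a, b), max(a, b)) not in sk.edges:
            sk.add_edge(int(a), int(b))
    return sk, stem


@pytest.fixture(scope="session")
def ref_crown():
    """Reference synthetic crown (seed 0) with its ground truth."""
    skeleton, stem, truth = rc.generate_crown(rc.REFERENCE_SPEC)
    return skeleton, stem, truth


@pytest.fixture(scope="session")
def ref_result(ref_crown):
    skeleton, stem, _ = ref_crown
    return rc.run_pipeline(skeleton, stem)
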