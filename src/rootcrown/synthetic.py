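"""Synthetic root-crown skeletons with known ground truth.

The generator emulates the phenomena the detection pipeline must handle on
real excavated maize crowns:

* a thick, gently tapering stem (a noisy vertical polyline);
* whorls of nodal roots leaving the stem circumferentially at prescribed
  arc positions, bending smoothly toward the gravity vector;
* *clinging* nodal roots that hug the stem and are spuriously re-attached
  to it lower down by a short, sharply bent bridge — producing exactly the
  boundary-crossing spur and graph cycle that false connections cause;
* lateral roots attached to the nodal roots whose depth density follows a
  Gaussian ramp below a ground-truth soil line.

Every crown is deterministic for a fixed seed and ships with its ground
truth (whorl positions and counts, soil depth, bridge edges), so the whole
pipeline can be validated without CT data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .skeleton import (
    DEFAULT_VOXEL_PITCH_MM,
    Skeleton,
    SkeletonError,
    SkeletonVertex,
    StemPath,
    _edge,
)

__all__ = ["SyntheticSpec", "GroundTruth", "generate_crown", "REFERENCE_SPEC"]

Range = Union[float, Tuple[float, float]]
Edge = Tuple[int, int]


@dataclass(frozen=True)
class SyntheticSpec:
    """Construction parameters for one synthetic crown.

    Entries of ``internode_mm`` and ``nodal_per_whorl`` may be fixed values
    or ``(lo, hi)`` ranges drawn per seed, so a cohort of crowns can show
    natural variation.  All distances in mm, angles in degrees.
    """

    n_whorls: int = 4
    internode_mm: Sequence[Range] = ((30.0, 40.0),) * 3
    first_whorl_arc_mm: float = 25.0
    nodal_per_whorl: Sequence[Range] = ((6, 10),) * 4
    emergence_angle_deg: Tuple[float, float] = (35.0, 65.0)  # from vertical
    nodal_curvature: float = 0.008  # bend toward gravity, rad per mm
    direction_wobble: float = 0.05  # per-step direction jitter, rad (jagged growth)
    nodal_length_mm: Tuple[float, float] = (80.0, 140.0)
    stem_length_mm: float = 160.0
    stem_top_thickness_mm: float = 4.0
    stem_taper: float = 0.004  # fractional thickness loss per mm of arc
    soil_depth_mm: float = 70.0
    lateral_amplitude: float = 0.5  # attachment probability at the peak
    lateral_sigma_mm: float = 15.0  # Gaussian spread c
    lateral_peak_depth_mm: Optional[float] = None  # b; default soil + 2c
    sublateral_prob: float = 0.15
    fraction_clinging: float = 0.15  # per above-ground whorl
    noise_sigma_mm: float = 0.25  # vertex jitter, mm (~0.6 voxel, CT-like)
    step_mm: float = 2.0
    voxel_pitch_mm: float = DEFAULT_VOXEL_PITCH_MM
    seed: int = 0

    @property
    def peak_depth_mm(self) -> float:
        if self.lateral_peak_depth_mm is not None:
            return self.lateral_peak_depth_mm
        return self.soil_depth_mm + 2.0 * self.lateral_sigma_mm


#: Reference study conditions: 4 whorls, 30-40 mm internodes, 6-10 nodal
#: roots per whorl, 15% clinging roots at above-ground whorls, Gaussian
#: lateral density below a 70 mm soil line.
REFERENCE_SPEC = SyntheticSpec()


@dataclass
class GroundTruth:
    """Construction-time truth emitted alongside a synthetic skeleton."""

    whorl_arcs: List[float]  # mm along the stem, youngest first
    nodal_counts: List[int]  # per whorl, youngest first
    soil_depth_mm: float
    false_edges: List[Edge]  # the bridge edges of clinging roots
    edge_labels: dict = field(default_factory=dict)  # edge -> hierarchy label

    @property
    def internodes(self) -> List[float]:
        return [b - a for a, b in zip(self.whorl_arcs[:-1], self.whorl_arcs[1:])]

    def to_dict(self) -> dict:
        return {
            "whorl_arcs_mm": self.whorl_arcs,
            "nodal_counts": self.nodal_counts,
            "soil_depth_mm": self.soil_depth_mm,
            "false_edges": [list(e) for e in self.false_edges],
        }


def _resolve(value: Range, rng: np.random.Generator, integer: bool = False):
    if isinstance(value, (tuple, list)):
        lo, hi = value
        if integer:
            return int(rng.integers(int(lo), int(hi) + 1))
        return float(rng.uniform(lo, hi))
    return int(value) if integer else float(value)


def _rotate_toward(d: np.ndarray, target: np.ndarray, angle: float) -> np.ndarray:
    """Rotate unit vector d toward unit vector target by at most `angle` rad."""
    cosang = float(np.clip(d @ target, -1.0, 1.0))
    full = math.acos(cosang)
    if full < 1e-9 or angle <= 0:
        return d
    t = min(angle / full, 1.0)
    # slerp in the plane spanned by d and target
    perp = target - cosang * d
    norm = np.linalg.norm(perp)
    if norm < 1e-12:
        return d
    perp /= norm
    out = math.cos(t * full) * d + math.sin(t * full) * perp
    return out / np.linalg.norm(out)


class _Builder:
    def __init__(self, pitch: float):
        self.skeleton = Skeleton(voxel_pitch=pitch)
        self._next = 0

    def vertex(self, position, thickness) -> int:
        vid = self._next
        self._next += 1
        self.skeleton.add_vertex(SkeletonVertex(vid, position, thickness))
        return vid

    def edge(self, a: int, b: int) -> Edge:
        self.skeleton.add_edge(a, b)
        return _edge(a, b)


def generate_crown(spec: SyntheticSpec) -> Tuple[Skeleton, StemPath, GroundTruth]:
    """Build a synthetic crown skeleton, its stem path and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    internodes = [_resolve(v, rng) for v in spec.internode_mm]
    if len(internodes) != spec.n_whorls - 1:
        raise SkeletonError(
            f"need {spec.n_whorls - 1} internodes for {spec.n_whorls} whorls, "
            f"got {len(internodes)}"
        )
    counts = [_resolve(v, rng, integer=True) for v in spec.nodal_per_whorl]
    if len(counts) != spec.n_whorls:
        raise SkeletonError("nodal_per_whorl length must equal n_whorls")
    whorl_arcs = [spec.first_whorl_arc_mm]
    for gap in internodes:
        whorl_arcs.append(whorl_arcs[-1] + gap)
    if whorl_arcs[-1] > spec.stem_length_mm - 10.0:
        raise SkeletonError(
            f"whorls extend to {whorl_arcs[-1]:.1f} mm on a "
            f"{spec.stem_length_mm:.1f} mm stem"
        )

    b = _Builder(spec.voxel_pitch_mm)
    labels: dict = {}

    # -- stem: noisy vertical polyline, tapering thickness -----------------
    n_stem = int(round(spec.stem_length_mm / spec.step_mm)) + 1
    stem_ids: List[int] = []
    stem_z: List[float] = []
    for i in range(n_stem):
        arc = i * spec.step_mm
        xy = rng.normal(0.0, 0.3 * spec.noise_sigma_mm, size=2)
        th = spec.stem_top_thickness_mm * max(1.0 - spec.stem_taper * arc, 0.35)
        vid = b.vertex(np.array([xy[0], xy[1], -arc]), th)
        stem_ids.append(vid)
        stem_z.append(-arc)
        if i > 0:
            labels[b.edge(stem_ids[i - 1], vid)] = 0

    def stem_vertex_at(arc_mm: float) -> int:
        i = int(np.clip(round(arc_mm / spec.step_mm), 0, n_stem - 1))
        return stem_ids[i]

    def stem_radius_at(vid: int) -> float:
        return b.skeleton.thickness(vid)

    # -- nodal roots per whorl ---------------------------------------------
    false_edges: List[Edge] = []
    root_records = []  # (vertex ids, azimuth) for lateral attachment
    for w, (arc, k) in enumerate(zip(whorl_arcs, counts)):
        above_ground = arc <= spec.soil_depth_mm
        n_cling = int(round(spec.fraction_clinging * k)) if above_ground else 0
        cling_flags = [i < n_cling for i in range(k)]
        for i in range(k):
            azimuth = 2 * math.pi * i / k + rng.uniform(-0.2, 0.2)
            attach_arc = arc + rng.uniform(-2.0, 2.0)
            attach = stem_vertex_at(attach_arc)
            radial = np.array([math.cos(azimuth), math.sin(azimuth), 0.0])
            clinging = cling_flags[i]
            theta = (
                math.radians(rng.uniform(12.0, 20.0))
                if clinging
                else math.radians(rng.uniform(*spec.emergence_angle_deg))
            )
            d = math.sin(theta) * radial + math.cos(theta) * np.array([0, 0, -1.0])
            d /= np.linalg.norm(d)
            length = rng.uniform(*spec.nodal_length_mm)
            n_steps = max(int(length / spec.step_mm), 6)
            cling_steps = int(rng.uniform(15.0, 25.0) / spec.step_mm) if clinging else 0
            pos = b.skeleton.position(attach).copy()
            ids = [attach]
            for s in range(n_steps):
                pos = pos + d * spec.step_mm + rng.normal(
                    0.0, spec.noise_sigma_mm, 3
                )
                th = max(1.0 - 0.5 * s / n_steps, 0.45)
                vid = b.vertex(pos.copy(), th)
                labels[b.edge(ids[-1], vid)] = 1
                ids.append(vid)
                # jagged growth, as skeletonized CT roots show: small random
                # heading change each step on top of the gravitropic bend
                if spec.direction_wobble > 0:
                    d = d + rng.normal(0.0, spec.direction_wobble, 3)
                    d /= np.linalg.norm(d)
                if s >= cling_steps:
                    d = _rotate_toward(
                        d, np.array([0, 0, -1.0]), spec.nodal_curvature * spec.step_mm
                    )
            root_records.append((ids, azimuth))
            if clinging:
                false_edges += _add_bridge(
                    b, spec, rng, labels, stem_ids, stem_vertex_at,
                    attach_arc, ids, radial,
                    next_gap=internodes[w] if w < len(internodes) else 20.0,
                )

    # -- lateral roots with Gaussian depth density --------------------------
    # laterals only sprout clear of the stem region (dist > 1.6 r), and grow
    # away from it, so they never cross the stem boundary themselves.  The
    # attachment probability is normalized by the local density of eligible
    # root vertices per depth bin, so the realized attachment density (not
    # just the per-vertex rate) follows the prescribed Gaussian.
    peak, sigma = spec.peak_depth_mm, spec.lateral_sigma_mm
    stem_pos = np.array([b.skeleton.position(v) for v in stem_ids])
    stem_r = np.array([b.skeleton.thickness(v) for v in stem_ids])
    eligible = []  # (vid, depth, outward direction)
    for ids, _ in root_records:
        for vid in ids[1:]:
            pos = b.skeleton.position(vid)
            d2 = np.linalg.norm(stem_pos - pos, axis=1)
            nearest = int(np.argmin(d2))
            if d2[nearest] <= 1.6 * stem_r[nearest]:
                continue
            outward = pos - stem_pos[nearest]
            outward[2] = 0.0
            eligible.append((vid, -pos[2], outward))
    if eligible:
        depths = np.array([d for _, d, _ in eligible])
        bin_w = 2.0 * spec.step_mm
        bins = np.floor(depths / bin_w).astype(int)
        avail_counts = np.bincount(bins - bins.min())
        peak_bin = int(np.clip(peak // bin_w, bins.min(), bins.max())) - bins.min()
        ref = (
            max(avail_counts[peak_bin], 1)
            if peak_bin < len(avail_counts)
            else avail_counts.max()
        )
        for (vid, depth, outward), bin_i in zip(eligible, bins):
            avail = avail_counts[bin_i - bins.min()]
            p = (
                spec.lateral_amplitude
                * math.exp(-((depth - peak) ** 2) / (2 * sigma**2))
                * ref
                / max(avail, 1)
            )
            if rng.uniform() < min(p, 0.95):
                _add_lateral(b, spec, rng, labels, vid, outward)

    skeleton = b.skeleton
    stem = StemPath.from_skeleton(skeleton, stem_ids)
    truth = GroundTruth(
        whorl_arcs=list(whorl_arcs),
        nodal_counts=list(counts),
        soil_depth_mm=spec.soil_depth_mm,
        false_edges=false_edges,
        edge_labels=labels,
    )
    return skeleton, stem, truth


def _add_bridge(
    b: _Builder,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    labels: dict,
    stem_ids: List[int],
    stem_vertex_at,
    attach_arc: float,
    root_ids: List[int],
    radial: np.ndarray,
    next_gap: float,
) -> List[Edge]:
    """Spurious sharply-bent connection from the stem to a clinging root.

    The bridge leaves a stem vertex roughly half an internode below the
    whorl, bends sharply (exterior angle in the 100-170 degree range) at
    about one voxel beyond the stem surface, and joins the nearest
    sufficiently-outside vertex of the clinging root, closing a cycle.
    """
    sk = b.skeleton
    u = stem_vertex_at(attach_arc + rng.uniform(0.45, 0.55) * next_gap)
    pu = sk.position(u)
    r_u = sk.thickness(u)
    # pick the root vertex nearest to 3 mm above u that sits clearly outside
    zu = pu[2]
    candidates = [
        vid
        for vid in root_ids[1:]
        if np.linalg.norm(sk.position(vid)[:2] - pu[:2]) > 1.25 * r_u
    ]
    if not candidates:
        return []
    target = min(candidates, key=lambda v: abs(sk.position(v)[2] - (zu + 3.0)))
    p1 = pu + 0.55 * r_u * radial + np.array([0, 0, 2.5])
    p2 = pu + (r_u + spec.voxel_pitch_mm * 0.9) * radial
    v1 = b.vertex(p1, 0.7)
    v2 = b.vertex(p2, 0.7)
    e1 = b.edge(u, v1)
    e2 = b.edge(v1, v2)
    e3 = b.edge(v2, target)
    for e in (e1, e2, e3):
        labels[e] = -1  # marks a false connection
    return [e1, e2, e3]


def _add_lateral(
    b: _Builder,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    labels: dict,
    attach: int,
    outward: np.ndarray,
) -> None:
    """A short lateral root (label 2), occasionally with a sub-lateral (3)."""
    ids = _grow_rootlet(
        b, spec, rng, labels, attach, outward,
        length=rng.uniform(6.0, 14.0), label=2, thickness=0.42,
    )
    if len(ids) > 2 and rng.uniform() < spec.sublateral_prob:
        mid = ids[len(ids) // 2]
        _grow_rootlet(
            b, spec, rng, labels, mid, outward,
            length=rng.uniform(4.0, 8.0), label=3, thickness=0.35,
        )


def _grow_rootlet(b, spec, rng, labels, attach, outward, length, label, thickness):
    # mostly horizontal, symmetric in depth: keeps the realized length
    # density centered on the Gaussian placed on attachment points; azimuth
    # stays within a quarter turn of outward so the lateral cannot grow
    # back into the stem region
    theta = math.radians(rng.uniform(65.0, 115.0))
    base = math.atan2(outward[1], outward[0]) if np.linalg.norm(outward[:2]) > 0 else 0.0
    azimuth = base + rng.uniform(-0.5 * math.pi, 0.5 * math.pi)
    d = np.array(
        [
            math.sin(theta) * math.cos(azimuth),
            math.sin(theta) * math.sin(azimuth),
            -math.cos(theta),
        ]
    )
    d /= np.linalg.norm(d)
    n_steps = max(int(length / spec.step_mm), 2)
    pos = b.skeleton.position(attach).copy()
    ids = [attach]
    for _ in range(n_steps):
        pos = pos + d * spec.step_mm + rng.normal(0.0, spec.noise_sigma_mm, 3)
        vid = b.vertex(pos.copy(), thickness)
        labels[b.edge(ids[-1], vid)] = label
        ids.append(vid)
        d = _rotate_toward(d, np.array([0, 0, -1.0]), 0.005 * spec.step_mm)
    return ids
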