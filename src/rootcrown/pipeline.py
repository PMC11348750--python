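"""End-to-end pipeline: stem classification -> candidate paths -> scoring ->
dedup -> persistence clustering -> false-connection pruning -> cycle
breaking -> hierarchy labeling -> soil line -> trait suite.

``run_pipeline`` is the library entry point; the command-line ``detect``
subcommand is a thin wrapper around it plus ``write_artifacts``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as skio
from .hierarchy import HierarchyLabeling, break_cycles, label_hierarchy
from .skeleton import Skeleton, StemPath, depth_of
from .soil import (
    DEFAULT_BIN_WIDTH_MM,
    DEFAULT_SIGMA_FACTOR,
    DegenerateProfileError,
    DensityProfile,
    FitError,
    GaussianFit,
    fit_gaussian,
    lateral_density_profile,
    soil_line_depth,
)
from .stem import DEFAULT_STEM_MULTIPLIER, classify_stem
from .traits import (
    RldResult,
    above_below_aggregates,
    per_whorl_traits,
    root_length_density,
    soil_relative_indexing,
    whorl_locations_and_internodes,
)
from .whorls import (
    DEFAULT_BANDWIDTH_MM,
    DEFAULT_CLAMP_VOXELS,
    DEFAULT_RDP_EPSILON_VOXELS,
    CandidatePath,
    ScoreLadder,
    Whorl,
    cluster_whorls,
    dedup_by_boundary_edge,
    find_candidate_paths,
    prune_false_connections,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_artifacts"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline tunables, with the field-calibrated defaults."""

    stem_multiplier: float = DEFAULT_STEM_MULTIPLIER
    rdp_epsilon_voxels: float = DEFAULT_RDP_EPSILON_VOXELS
    clamp_voxels: float = DEFAULT_CLAMP_VOXELS
    voxel_pitch_mm: Optional[float] = None  # None: use the skeleton's pitch
    bandwidth_mm: float = DEFAULT_BANDWIDTH_MM
    bin_width_mm: float = DEFAULT_BIN_WIDTH_MM
    sigma_factor: float = DEFAULT_SIGMA_FACTOR
    rld_radius_cm: Optional[float] = None  # None: auto (95th percentile)
    density_mode: str = "length"
    flip_stem: bool = False
    seed: int = 0

    def rdp_epsilon_mm(self, pitch: float) -> float:
        return self.rdp_epsilon_voxels * pitch

    def clamp_mm(self, pitch: float) -> float:
        return self.clamp_voxels * pitch

    # flat key-value (de)serialization for config files
    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name} {'none' if v is None else v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition(" ")
            if key not in types:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            value = value.strip()
            if value.lower() == "none":
                kwargs[key] = None
            elif key == "density_mode":
                kwargs[key] = value
            elif key == "flip_stem":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key == "seed":
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    skeleton: Skeleton  # input skeleton (possibly flipped stem)
    stem: StemPath
    candidate_paths: List[CandidatePath]
    deduped_paths: List[CandidatePath]
    whorls: List[Whorl]
    ladder: ScoreLadder
    pruned: Skeleton
    removed_false: list
    tree: Skeleton
    removed_cycles: list
    labeling: HierarchyLabeling
    profile: Optional[DensityProfile]
    fit: Optional[GaussianFit]
    soil_depth_mm: Optional[float]
    whorl_locations: List[float]
    internode_distances: List[float]
    whorl_indices: Optional[List[int]]
    trait_rows: pd.DataFrame
    aggregates: pd.DataFrame
    rld: Optional[RldResult]

    def summary(self) -> dict:
        out = {
            "n_vertices": self.skeleton.n_vertices,
            "n_edges": self.skeleton.n_edges,
            "n_candidate_paths": len(self.candidate_paths),
            "n_deduped_paths": len(self.deduped_paths),
            "n_whorls": len(self.whorls),
            "whorl_locations_mm": self.whorl_locations,
            "internode_distances_mm": self.internode_distances,
            "whorl_indices": self.whorl_indices,
            "nodal_counts": [w.n_nodal_roots for w in self.whorls],
            "n_false_edges_removed": len(self.removed_false),
            "n_cycle_edges_removed": len(self.removed_cycles),
            "soil_depth_mm": self.soil_depth_mm,
        }
        if self.fit is not None:
            out["gaussian_fit"] = {
                "a": self.fit.a,
                "b_mm": self.fit.b,
                "c_mm": self.fit.c,
                "rss": self.fit.rss,
            }
        if self.rld is not None:
            out["rld_radius_cm"] = self.rld.radius_cm
            out["rld_cm_per_cm3"] = self.rld.values.tolist()
        return out


def run_pipeline(
    skeleton: Skeleton,
    stem: StemPath,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Run whorl detection, soil-line estimation and the trait suite."""
    if config.flip_stem:
        stem = stem.reversed(skeleton)
    pitch = (
        config.voxel_pitch_mm
        if config.voxel_pitch_mm is not None
        else skeleton.voxel_pitch
    )
    top = skeleton.position(stem.top)

    classification = classify_stem(skeleton, stem, config.stem_multiplier)
    candidates = find_candidate_paths(
        skeleton,
        stem,
        classification,
        rdp_epsilon_mm=config.rdp_epsilon_mm(pitch),
        clamp_voxels=config.clamp_voxels,
    )
    deduped = dedup_by_boundary_edge(candidates)
    if not deduped:
        raise RuntimeError("whorl detection: no candidate paths found")
    whorls, ladder = cluster_whorls(deduped, config.bandwidth_mm)
    nodal = [m for w in whorls for m in w.members]
    pruned, removed_false = prune_false_connections(skeleton, stem, nodal)
    tree, removed_cycles = break_cycles(pruned, stem)
    labeling = label_hierarchy(tree, stem, nodal)

    # whorl depth = depth of the stem point at the whorl's arc position
    arc_to_depth = np.interp(
        [w.location_arc for w in whorls],
        stem.arc_lengths,
        [depth_of(skeleton.position(v), top) for v in stem.vertex_ids],
    )
    for w, d in zip(whorls, arc_to_depth):
        w.location_depth = float(d)

    profile = fit = None
    soil_depth = None
    try:
        profile = lateral_density_profile(
            labeling, tree, top, config.bin_width_mm, mode=config.density_mode
        )
        fit = fit_gaussian(profile)
        soil_depth = soil_line_depth(fit, config.sigma_factor)
    except (DegenerateProfileError, FitError) as exc:
        logger.warning("soil line unavailable: %s", exc)

    locations, internodes = whorl_locations_and_internodes(whorls)
    indices = (
        soil_relative_indexing(whorls, soil_depth) if soil_depth is not None else None
    )
    trait_rows = per_whorl_traits(labeling, tree, whorls, stem)
    aggregates = (
        above_below_aggregates(trait_rows) if indices is not None else pd.DataFrame()
    )
    rld = (
        root_length_density(
            labeling, tree, stem, soil_depth, top, radius_cm=config.rld_radius_cm
        )
        if soil_depth is not None
        else None
    )
    return PipelineResult(
        skeleton=skeleton,
        stem=stem,
        candidate_paths=candidates,
        deduped_paths=deduped,
        whorls=whorls,
        ladder=ladder,
        pruned=pruned,
        removed_false=removed_false,
        tree=tree,
        removed_cycles=removed_cycles,
        labeling=labeling,
        profile=profile,
        fit=fit,
        soil_depth_mm=soil_depth,
        whorl_locations=locations,
        internode_distances=internodes,
        whorl_indices=indices,
        trait_rows=trait_rows,
        aggregates=aggregates,
        rld=rld,
    )


def write_artifacts(result: PipelineResult, out_dir) -> dict:
    """Write the CSV / JSON / annotated-skeleton artifacts of a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    whorl_rows = [
        {
            "kind": "whorl",
            "whorl": i,
            "index": w.index,
            "location_arc_mm": w.location_arc,
            "location_depth_mm": w.location_depth,
            "n_nodal_roots": w.n_nodal_roots,
            "min_member_arc_mm": w.arc_interval[0],
            "max_member_arc_mm": w.arc_interval[1],
            "score": np.nan,
        }
        for i, w in enumerate(result.whorls)
    ]
    member_of = {
        id(m): i for i, w in enumerate(result.whorls) for m in w.members
    }
    for p in result.deduped_paths:
        whorl_rows.append(
            {
                "kind": "candidate_path",
                "whorl": member_of.get(id(p), -1),
                "index": None,
                "location_arc_mm": p.start_arc,
                "location_depth_mm": np.nan,
                "n_nodal_roots": None,
                "min_member_arc_mm": np.nan,
                "max_member_arc_mm": np.nan,
                "score": p.score,
            }
        )
    pd.DataFrame(whorl_rows).to_csv(out_dir / "whorls.csv", index=False)

    result.trait_rows.to_csv(out_dir / "traits.csv", index=False)
    result.aggregates.to_csv(out_dir / "aggregates.csv", index=False)
    if result.profile is not None:
        pd.DataFrame(
            {
                "depth_mm": result.profile.centers,
                "lateral_length_mm": result.profile.values,
            }
        ).to_csv(out_dir / "profile.csv", index=False)
    if result.rld is not None:
        pd.DataFrame(
            {
                "depth_below_soil_cm": result.rld.bin_edges_cm[:-1],
                "rld_cm_per_cm3": result.rld.values,
            }
        ).to_csv(out_dir / "rld.csv", index=False)
    skio.write_skeleton(
        result.tree,
        result.stem,
        out_dir / "annotated_skeleton.txt",
        edge_labels=result.labeling.edge_label,
    )
    summary = result.summary()
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
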