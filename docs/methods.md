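# Methods

This note documents the models, parameters and numerical choices behind
`rootcrown`, and what its synthetic validation does and does not show.

## Input model and conventions

A crown is an undirected spatial graph: vertices carry a 3D position (mm)
and a thickness (mm, a radius-like measure produced by skeletonization),
edges connect them, and an ordered *stem path* runs from the stalk end
(top) to the stem tip.  The graph may contain cycles on input; they arise
where clinging nodal roots are spuriously merged with the stem.

Conventions: +Z is up; depth is measured top-down from the stem-path top
vertex (`depth = z_top − z`), so points below the top have positive depth.
Inputs stored bottom-to-top can be reversed with `flip_stem`.  All
geometry is in mm; parameters stated in voxels are converted through the
skeleton's voxel pitch (default 0.44 mm, i.e. a 109 µm scan downsampled
4×).  The pitch-denominated defaults are then ε = 3 voxels = 1.32 mm for
path simplification and 10 voxels = 4.4 mm for the score's distance clamp.

## Whorl detection

1. **Inside-stem test.**  A vertex is inside the stem if its distance to
   the nearest stem-path *vertex* v (not the interpolated polyline) is
   ≤ 1.2 · r_v, inclusive.  The 1.2 multiplier reflects the stem being
   markedly thicker than the roots; a different crop would need a
   different value.  A *boundary edge* has exactly one inside endpoint; a
   *junction* is a stem vertex of skeleton degree ≥ 3.

2. **Candidate paths.**  From every junction, Dijkstra (edge weight =
   Euclidean length) finds shortest paths to every inside vertex incident
   to a boundary edge; stem-path edges and edges with both endpoints
   outside are unusable.  Each path is extended by its boundary edge.
   Paths that collapse below three distinct points after simplification
   (e.g. a junction directly incident to a boundary edge) cannot carry a
   turning angle and are discarded with a logged warning.

3. **Scoring.**  Paths are simplified by RDP with a *forced first split*:
   the point farthest from the end-to-end segment is always inserted, so
   the output has ≥ 3 points and a measurable turning angle even for
   near-straight paths.  The turning angle at an interior point is the
   deviation from straight continuation (0 = straight, π = reversal);
   ties go to the point nearest the stem.  The score
   exp(−2α/π − (10 − clamp(d_vox, 0, 10))/10), with d_vox the
   turning-point distance beyond the stem surface in voxels, is bounded in
   [e⁻³, 1], strictly decreasing in α and non-decreasing in the distance.
   When several candidate paths share a boundary edge only the
   highest-scoring one is kept (ties: shorter path, then lexicographically
   smallest id sequence — determinism matters for reproducible runs).

4. **Persistence clustering.**  For each δ in the ascending list of
   candidate scores, the start arcs of paths scoring ≥ δ are clustered by
   a 1-D flat-kernel mean shift (bandwidth 10 mm by default — clusters in
   maize crowns are well under one internode wide; modes closer than half
   a bandwidth are merged; labels are ordered by mode position, making the
   procedure deterministic).  Two clusterings are equal when they have the
   same number of clusters and matched clusters share the same lowest and
   highest member paths (by start arc).  The clustering persisting over
   the most consecutive δ values is selected; ties prefer the higher-δ
   run, where spurious low-score paths have dropped out.  Final whorl
   membership takes *every* candidate path whose start arc lies in a
   winning cluster's [min, max] member interval, regardless of score —
   false connections are rare right at a true whorl, and this recovers
   genuine roots whose own scores are mediocre.

5. **Pruning.**  Stem-attached edge chains used by no nodal candidate
   path are traced through degree-2 vertices until the next junction or a
   leaf and removed (chain ends kept).  The trace additionally stops
   short of any nodal-path or stem edge, so detected roots are never
   damaged even when a spurious bridge merges into a root at a degree-2
   vertex.  Pruning typically removes the cycles that clinging roots
   created.

## Hierarchy

Residual cycles are broken by a per-component spanning tree that maximizes
retained mean endpoint thickness (thin edges are the likeliest artifacts);
stem edges are pinned into the tree.  Labels then propagate outward from
the stem: stem edges 0, branches leaving the stem 1, children one level
deeper.  At an off-stem junction the outgoing edge with the smallest
direction change continues its parent's branch.  This
continuation-by-straightest rule is a deliberate simplification of a full
thickness-driven hierarchy optimization; on smooth synthetic crowns it
reproduces construction labels for > 98 % of edges, with the rare swap
occurring where a daughter branch happens to leave straighter than its
parent continues.

## Soil line

Lateral-root (label ≥ 2) length is apportioned pro rata over uniform depth
bins (default 2 mm) spanned by each edge's vertical extent; the profile
sum therefore equals total lateral length exactly (a `count` mode binning
branch origins is available).  A Gaussian a·exp(−(x−b)²/(2c²)) is fitted
at bin centers by nonlinear least squares (initialized at the empirical
peak and the profile's weighted standard deviation; ftol 1e-10; profiles
with fewer than three nonzero bins are rejected as degenerate).  The soil
line is b − 2c — the depth where the profile begins to rise; the factor 2
is the calibrated default and is configurable (`sigma_factor`).  A
negative result is clamped to 0 with a warning.

## Traits

The youngest whorl is the one highest on the stalk; internode distances
are listed youngest-first, and E_k = Σ|c_i − m_i| / Σ m_i measures the
cumulative error of the first k computed internodes against reference
values.  Soil-relative whorl indices place 0 at the deepest whorl at or
above the soil line, positive above, negative below; if every whorl is
below, the shallowest gets −1 and the absence of a 0-th whorl is flagged.
Per-branch traits: length; tortuosity (arc length / end-to-end chord,
≥ 1); mean vertex thickness; child count; emergence, midpoint and tip
angles between the local tangent (5 mm window, linearly interpolated along
arc) and the downward vertical.  Above/below aggregates sum counts and
weight means by root count, which equals pooling the underlying branches.
Root length density uses a cylinder around the best-fit (SVD) stem axis
whose radius defaults to the 95th percentile of root-vertex radial
distances; per 1 cm depth bin below the soil line, RLD = in-cylinder
(segment midpoint inside) root length ÷ (π r² · 1 cm), so RLD × bin
volume reproduces the in-cylinder length exactly.

## Synthetic crowns

The generator emulates the phenomena the detector must survive, with
construction-time ground truth:

* stem: vertical polyline, 2 mm steps, thickness 4 mm tapering 0.4 %/mm;
* whorls: default 4, first at 25 mm, internodes drawn 30–40 mm, 6–10
  nodal roots per whorl attached with ± 2 mm arc jitter, emergence angles
  35–65° from vertical, smooth gravitropic bend (0.008 rad/mm);
* jaggedness: per-step direction wobble (σ 0.05 rad) plus 0.25 mm vertex
  jitter (≈ 0.6 voxel), matching the irregular geometry skeletonized CT
  data shows.  Without it, candidate-path scores are implausibly uniform
  and correlate only with stem taper, which starves the persistence
  selection of the score diversity real data provides;
* clinging roots: 15 % of roots at above-ground whorls descend steeply
  along the stem and are re-attached to it half an internode lower by a
  three-edge bridge bending 100–170° at ≈ 1 voxel beyond the stem
  surface — creating exactly the boundary-crossing spur and graph cycle
  of a false connection;
* laterals: attached to nodal-root vertices clear of the stem with
  probability proportional to a depth Gaussian whose b − 2c equals the
  ground-truth soil line (70 mm; c = 15 mm), normalized by the local
  availability of root vertices per depth bin so the *realized*
  attachment density follows the Gaussian; growth is near-horizontal and
  depth-symmetric so the length profile stays centered on it.  15 % of
  laterals carry a sub-lateral (hierarchy level 3).

What passing synthetic tests does **not** show: robustness to
segmentation errors that merge or sever roots, to stems that curve
strongly (the generator's stem is near-vertical), to whorls compressed
tighter than the 10 mm bandwidth near the stem base, or to lateral
density profiles that are markedly non-Gaussian.  Real-data validation
requires CT-derived skeletons with manual measurements.

## Problem sizes and determinism

Reference crowns have ≈ 2 500 vertices; a full pipeline run takes ≈ 0.3 s,
and the shipped studies use 50 crowns (recovery) and 100 fits (Gaussian
noise study) — sizes chosen to give stable rates while keeping the whole
validation under a minute.  Every stage is deterministic given the input
and configuration; the only randomness is the generator's seed, and
`scripts/acceptance.py --seed` shifts the whole seed block.
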