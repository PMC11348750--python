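"""Step through whorl detection on a synthetic crown.

Candidate paths (shortest skeleton paths from stem junctions to the stem
boundary) are scored by how sharply, and how close to the stem surface,
they bend: genuine nodal roots bend gently and far out, spurious bridges
from clinging roots bend sharply at the surface.  Whorls are the clusters
of path start positions that persist over the longest run of score
thresholds.
"""

import numpy as np

import rootcrown as rc
from rootcrown.stem import classify_stem
from rootcrown.whorls import (
    cluster_whorls,
    dedup_by_boundary_edge,
    find_candidate_paths,
)

skeleton, stem, truth = rc.generate_crown(rc.REFERENCE_SPEC)

cls = classify_stem(skeleton, stem)
print(f"stem junctions: {len(cls.junctions_on_stem)}, "
      f"boundary edges: {len(cls.boundary_edges)}")

paths = dedup_by_boundary_edge(find_candidate_paths(skeleton, stem, cls))
scores = np.array([p.score for p in paths])
print(f"candidate paths: {len(paths)}, scores {scores.min():.2f}-{scores.max():.2f}")
# low scores (~0.1) are the sharply-bent false connections; the rest are
# genuine nodal-root emergences

whorls, ladder = cluster_whorls(paths, bandwidth_mm=10.0)
print(f"selected clustering persists over thresholds "
      f"{ladder.selected_run[1] - ladder.selected_run[0]} of {len(ladder.deltas)}")
for i, w in enumerate(whorls):
    print(f"whorl {i}: arc {w.location_arc:6.1f} mm, {w.n_nodal_roots} nodal roots"
          f"  (truth: {truth.whorl_arcs[i]:6.1f} mm, {truth.nodal_counts[i]})")
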