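"""Generate a synthetic maize root crown and write it to disk.

The generator builds a tapering stem, whorls of nodal roots, clinging
roots with spurious bridges back to the stem (closing graph cycles), and
lateral roots whose depth density follows a Gaussian below the soil line.
The ground truth (whorl positions, counts, soil depth) ships alongside.
"""

import json

import rootcrown as rc

skeleton, stem, truth = rc.generate_crown(rc.REFERENCE_SPEC)
rc.write_skeleton(skeleton, stem, "crown.txt")

print(f"skeleton: {skeleton.n_vertices} vertices, {skeleton.n_edges} edges")
print(f"graph cycles (from clinging-root bridges): {skeleton.cycle_rank()}")
print(f"stem length: {stem.length:.1f} mm")
print("ground truth:", json.dumps(truth.to_dict(), indent=2))
# whorl_arcs_mm are the stem positions (youngest first) where nodal roots
# emerge; nodal_counts the roots per whorl; false_edges the spurious bridges
# the detector must prune.
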