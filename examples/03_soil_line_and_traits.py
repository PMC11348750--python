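"""Full pipeline: whorls, soil line, and the fine-grained trait suite.

The soil line of an excavated crown is estimated by fitting a Gaussian
f(x) = a*exp(-(x-b)^2 / (2 c^2)) to the depth profile of lateral-root
length and taking b - 2c, the depth where lateral density starts to rise.
Whorl indices are soil-relative: 0 at the whorl directly above or at the
soil line, negative below it.
"""

import rootcrown as rc

skeleton, stem, truth = rc.generate_crown(rc.REFERENCE_SPEC)
result = rc.run_pipeline(skeleton, stem)

fit = result.fit
print(f"gaussian fit: peak a={fit.a:.1f} mm/bin at depth b={fit.b:.1f} mm, "
      f"spread c={fit.c:.1f} mm")
print(f"soil line b-2c = {result.soil_depth_mm:.1f} mm "
      f"(ground truth {truth.soil_depth_mm:.1f} mm)")
print(f"whorl indices (soil-relative): {result.whorl_indices}")
print(f"internode distances, youngest first: "
      f"{[round(d, 1) for d in result.internode_distances]} mm")

print("\nper-whorl, per-level traits (level 1 = nodal, 2+ = lateral):")
print(result.trait_rows[
    ["whorl", "whorl_index", "level", "count", "total_length_mm",
     "avg_tortuosity", "avg_emergence_angle_deg"]
].round(2).to_string(index=False))

rld = result.rld
print(f"\nroot length density in a {rld.radius_cm:.2f} cm virtual soil core,")
print("per 1 cm depth below the soil line (cm root / cm^3 soil):")
print([round(float(v), 4) for v in rld.values[:8]])
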