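"""Build the body template that defines the map vector space.

Every bodily sensation map lives on a fixed silhouette grid; the
template records which pixels are inside the body and names coarse
anatomical regions used by the synthetic-cohort simulator.
"""

from bodymaps import build_default_template, mask_vector_index

template = build_default_template(width=60, height=120)
idx = mask_vector_index(template)

print(f"canvas: {template.width} x {template.height} pixels per panel")
print(f"in-body pixels (BSM vector length): {template.n_in_mask}")
for name, sub in template.regions.items():
    print(f"  region {name:8s} {int(sub.sum()):5d} px")
print(f"vector index round-trips {len(idx)} cells in row-major order")

# The in-body pixel count is the dimensionality of every downstream
# analysis: each subject map, t-map and classifier feature vector has
# exactly this many entries.
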