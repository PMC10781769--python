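"""Simulate a small Visium-like section and inspect its layout.

Builds a hexagonal lattice with a central tumor disk, a stromal annulus and
epithelial/lamina background, draws per-region cell-type proportions and
negative-binomial counts, and prints the region sizes and count summary.
"""

import numpy as np

from spotflow.synthio import (
    LayoutParams,
    make_layout,
    make_signatures,
    simulate_counts,
    simulate_proportions,
)

types = ["ct_epithelial", "ct_fibroblast", "ct_immune"]
region_dirichlet = {
    "tumor": (8, 1, 1),
    "stroma": (1, 8, 1),
    "epithelium": (4, 1, 1),
    "lamina_propria": (1, 4, 4),
    "immune_aggregate": (1, 1, 8),
}

layout = make_layout(
    30, 30,
    LayoutParams(tumor_radius=5.0, stroma_width=2.0, epithelium_width=3.0,
                 n_immune_aggregates=2),
    seed=0,
)
props = simulate_proportions(layout, types, region_dirichlet, seed=1)
signatures = make_signatures([f"G{i:03d}" for i in range(300)], types, seed=2)
ds = simulate_counts(props, signatures, layout, library_size=4000.0, seed=3)

print(f"{ds.n_spots} spots x {ds.n_genes} genes")
for cat, n in zip(*np.unique(layout.categories, return_counts=True)):
    print(f"  {cat:>18}: {n:4d} spots")
totals = np.asarray(ds.counts.sum(axis=0)).ravel()
print(f"median UMIs per spot: {np.median(totals):.0f} (target library 4000)")
# Spot totals fluctuate around the library size because counts are
# negative-binomial draws around the mixture means.
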