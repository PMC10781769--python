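"""Tumor-surrounding spots and peripheral/intermediary/central tumor zones.

Distances are Euclidean in canonical units (hex neighbors at distance 1).
Non-tumor spots within distance 2 of a tumor spot form the surrounding set;
tumor spots are zoned by their distance to the nearest non-tumor spot
(<2 peripheral, [2, 2.5) intermediary, >=2.5 central).
"""

import numpy as np

from spotflow.core_data import SYNTH_VOCABULARY, SpotDataset
import scipy.sparse as sp

from spotflow.spatial_stats import select_tumor_surrounding, stratify_tumor
from spotflow.synthio import LayoutParams, make_layout

layout = make_layout(30, 30, LayoutParams(tumor_radius=5.0), seed=0)
ds = SpotDataset(
    sample_id="disk",
    spot_ids=layout.spot_ids,
    array_coords=layout.array_coords,
    counts=sp.csr_matrix(np.ones((1, layout.n_spots))),
    gene_ids=np.array(["G"], dtype=object),
    annotations=layout.categories.copy(),
)

surrounding = select_tumor_surrounding(ds, SYNTH_VOCABULARY)
zoning = stratify_tumor(ds, SYNTH_VOCABULARY)
print(f"tumor spots: {len(zoning.spot_ids)}, surrounding spots: {len(surrounding)}")
for zone, n in zip(*np.unique(zoning.zones.astype(str), return_counts=True)):
    print(f"  {zone:>12}: {n:3d} spots")
# On a compact disk the boundary ring is peripheral and the core central;
# intermediary spots appear only where the nearest non-tumor spot sits at
# exactly distance 2 (e.g., around isolated non-tumor pockets).
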