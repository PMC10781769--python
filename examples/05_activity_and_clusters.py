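"""Pathway and TF activities, activity-based clustering, ROC markers.

Pathway activity is a weighted sum of z-scored expression of the most
perturbation-responsive genes.  TF activity is a rank-based regulon score
with a standard-normal null.  Spots are clustered on their TF activity
profiles and marker TFs are called by cluster-vs-rest AUC.
"""

import numpy as np

from spotflow.activity import (
    cluster_by_tf,
    pathway_activity,
    roc_markers,
    tf_activity,
    zscale_activities,
)
from spotflow.preprocess import normalize
from spotflow.synthio import (
    LayoutParams,
    make_layout,
    make_signatures,
    make_toy_prior,
    prior_gene_pool,
    simulate_counts,
    simulate_proportions,
)

prior = make_toy_prior(n_tfs=5, n_ligands=6, n_pathways=4, n_genes=400, seed=0)
types = ["ctA", "ctB", "ctC"]
layout = make_layout(26, 26, LayoutParams(tumor_radius=4.0), seed=1)
conc = {c: (8, 1, 1) if c == "tumor" else (1, 8, 1) if c == "stroma" else (1, 1, 8)
        for c in np.unique(layout.categories)}
props = simulate_proportions(layout, types, conc, seed=2)
signatures = make_signatures(prior_gene_pool(prior), types, seed=3)
ds = normalize(simulate_counts(props, signatures, layout, seed=4))

pw = pathway_activity(ds, prior.pathway_weights, scale=True)
act = tf_activity(ds, prior.regulons)
print(f"pathway activities: {pw.values.shape[1]} pathways x {pw.values.shape[0]} spots")
print(f"TF activities defined for {act.coverage.min()}-{act.coverage.max()} spots per TF")

clusters = cluster_by_tf(act, seed=5)
n_clusters = len(np.unique(clusters.labels))
markers = roc_markers(zscale_activities(act), clusters, return_all=True)
print(f"{n_clusters} TF-activity clusters; best marker AUC "
      f"{markers['auc'].max():.2f}")
# An AUC near 1 means that TF's activity alone almost perfectly separates
# its cluster from the rest of the tissue.
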