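"""Shared fixtures: small synthetic datasets and prior bundles."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from spotflow.core_data import AbundanceMatrix, SpotDataset
from spotflow.synthio import (
    LayoutParams,
    make_layout,
    make_signatures,
    make_toy_prior,
    simulate_counts,
    simulate_proportions,
)

REGION_DIRICHLET_3 = {
    "tumor": (8.0, 1.0, 1.0),
    "stroma": (1.0, 8.0, 1.0),
    "epithelium": (1.0, 1.0, 8.0),
    "lamina_propria": (1.0, 1.0, 8.0),
    "immune_aggregate": (1.0, 8.0, 1.0),
}


def build_dataset(
    counts: np.ndarray,
    *,
    genes: list[str] | None = None,
    annotations: list[str] | None = None,
    sample_id: str = "toy",
) -> SpotDataset:
    """Dataset from a dense gene x spot array on a linear hex row."""
    counts = np.asarray(counts)
    n_genes, n_spots = counts.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    return SpotDataset(
        sample_id=sample_id,
        spot_ids=np.array([f"bc{i:03d}" for i in range(n_spots)], dtype=object),
        array_coords=np.column_stack([np.zeros(n_spots, int), 2 * np.arange(n_spots)]),
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(genes, dtype=object),
        annotations=None if annotations is None else np.array(annotations, dtype=object),
    )


@pytest.fixture(scope="session")
def toy_prior():
    return make_toy_prior(n_tfs=4, n_ligands=6, n_pathways=3, n_genes=200, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """One ~200-spot sample with annotations, counts and ground truth."""
    from spotflow.synthio import prior_gene_pool

    prior = make_toy_prior(n_tfs=4, n_ligands=6, n_pathways=3, n_genes=200, seed=11)
    genes = prior_gene_pool(prior)
    types = ["ctA", "ctB", "ctC"]
    signatures = make_signatures(genes, types, seed=5)
    layout = make_layout(
        20, 20, LayoutParams(tumor_radius=4.0, stroma_width=2.0, epithelium_width=3.0), seed=5
    )
    props = simulate_proportions(layout, types, REGION_DIRICHLET_3, seed=6)
    ds = simulate_counts(
        props, signatures, layout, library_size=3000.0, dispersion=10.0, seed=7,
        sample_id="small",
    )
    return {"prior": prior, "signatures": signatures, "layout": layout, "props": props, "ds": ds}
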