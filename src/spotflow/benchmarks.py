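"""Reference synthetic benchmarks with known ground truth.

Each function builds its inputs with the :mod:`spotflow.synthio` generators,
runs the corresponding inference end to end, and reports recovery metrics
against the planted truth.  The problem sizes are the package's standard
study conditions (documented in docs/methods.md) and are shared by the test
suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthio
from .communication import (
    LigandImportance,
    aggregate_importance,
    ligand_tf_importance,
    lr_consensus,
)
from .core_data import AbundanceMatrix
from .preprocess import nnls_deconvolve, normalize
from .activity import tf_activity
from .synthio import (
    LayoutParams,
    make_layout,
    make_signatures,
    make_toy_prior,
    plant_ligand_tf_effects,
    prior_gene_pool,
    simulate_counts,
    simulate_proportions,
)

__all__ = [
    "communication_benchmark",
    "lr_benchmark",
    "deconvolution_benchmark",
    "tf_null_calibration",
]

CELL_TYPES = ("ct_epithelial", "ct_fibroblast", "ct_immune", "ct_endothelial", "ct_stem")

#: Dirichlet concentrations per tissue category: each region is dominated by
#: one major class with admixture from the rest.
REGION_DIRICHLET = {
    "tumor": (8.0, 1.0, 1.0, 1.0, 1.0),
    "stroma": (1.0, 8.0, 1.0, 1.0, 1.0),
    "epithelium": (1.0, 1.0, 1.0, 1.0, 8.0),
    "lamina_propria": (1.0, 1.0, 1.0, 8.0, 1.0),
    "immune_aggregate": (1.0, 1.0, 8.0, 1.0, 1.0),
}

PLANTED_EFFECTS = (("LIG00", "TF00", 1.0), ("LIG03", "TF01", 1.0), ("LIG07", "TF03", 1.0))


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def communication_benchmark(
    seed: int = 0,
    *,
    n_samples: int = 4,
    rows: int = 40,
    cols: int = 40,
    n_ligands: int = 10,
    n_tfs: int = 5,
    effect: float = 1.0,
    noise_sd: float = 1.0,
    library_size: float = 5000.0,
    dispersion: float = 10.0,
) -> dict:
    """Planted ligand->TF recovery on the default communication benchmark.

    Four 800-spot samples, 10 ligands, 5 TFs, 3 planted couplings at
    standardized effect 1.0 with unit activity noise.  Reports the aggregated
    importance matrix, the planted-pair importances, the fraction of null
    pairs exceeding the selection threshold (1.0), and the AUC of ranking
    planted vs null pairs by aggregated importance.
    """
    s_prior, s_sig, *s_samples = _seeds(seed, 2 + n_samples)
    prior = make_toy_prior(
        n_tfs=n_tfs, n_ligands=n_ligands, n_pathways=3, n_genes=600,
        seed=s_prior, regulon_size=(10, 14),
    )
    genes = prior_gene_pool(prior)
    signatures = make_signatures(genes, list(CELL_TYPES), seed=s_sig)
    effects = [(l, t, effect) for l, t, _ in PLANTED_EFFECTS]

    per_sample: list[LigandImportance] = []
    ligands = sorted(prior.ligands)
    for i in range(n_samples):
        sub = _seeds(s_samples[i], 4)
        layout = make_layout(
            rows, cols,
            LayoutParams(tumor_radius=6.0, stroma_width=3.0, epithelium_width=4.0,
                         n_immune_aggregates=2),
            seed=sub[0],
        )
        props = simulate_proportions(layout, CELL_TYPES, REGION_DIRICHLET, seed=sub[1])
        ds = simulate_counts(
            props, signatures, layout,
            library_size=library_size, dispersion=dispersion,
            seed=sub[2], sample_id=f"bench{i}",
        )
        ds = plant_ligand_tf_effects(ds, prior, effects, noise_sd=noise_sd, seed=sub[3])
        ds = normalize(ds)
        act = tf_activity(ds, prior.regulons)
        per_sample.append(ligand_tf_importance(ds, ligands, act, seed=sub[3]))

    agg = aggregate_importance(per_sample)
    planted = {(l, t) for l, t, _ in effects}
    vals, labels = [], []
    for lig in agg.table.index:
        for tf in agg.table.columns:
            v = agg.table.loc[lig, tf]
            if np.isfinite(v):
                vals.append(float(v))
                labels.append((str(lig), str(tf)) in planted)
    vals = np.asarray(vals)
    labels = np.asarray(labels)
    planted_vals = vals[labels]
    null_vals = vals[~labels]
    # rank-based AUC of planted vs null
    from scipy.stats import rankdata

    ranks = rankdata(vals)
    auc = (ranks[labels].sum() - labels.sum() * (labels.sum() + 1) / 2) / (
        labels.sum() * (~labels).sum()
    )
    return {
        "aggregate": agg,
        "per_sample": per_sample,
        "planted_pairs": sorted(planted),
        "planted_importances": planted_vals,
        "min_planted_importance": float(planted_vals.min()),
        "null_exceedance": float(np.mean(null_vals > 1.0)),
        "auc": float(auc),
    }


def lr_benchmark(
    seed: int = 0,
    *,
    n_decoys: int = 200,
    rows: int = 40,
    cols: int = 40,
    n_perm: int = 1000,
    library_size: float = 5000.0,
    dispersion: float = 10.0,
) -> dict:
    """Planted ligand-receptor pair among decoys, ranked by consensus.

    One sample with a tumor-marker ligand and a stroma-marker receptor
    planted among ``n_decoys`` nonspecific decoy pairs; reports the planted
    interaction's aggregate rank for the tumor -> TME cluster direction.
    """
    s_layout, s_props, s_counts, s_sig = _seeds(seed, 4)
    lig_p, rec_p = "LIGP", "RECP"
    decoy_pairs = [(f"DLG{i:03d}", f"DRC{i:03d}") for i in range(n_decoys)]
    filler = [f"BG{i:04d}" for i in range(600)]
    genes = [lig_p, rec_p] + [g for pair in decoy_pairs for g in pair] + filler

    # decoys carry only mild lognormal type-to-type variation (no marker
    # structure); the planted pair marks the tumor- and stroma-dominant classes
    signatures = make_signatures(genes, list(CELL_TYPES), seed=s_sig,
                                 n_markers_per_type=0)
    signatures.loc[lig_p] = signatures.loc[lig_p].mean()
    signatures.loc[rec_p] = signatures.loc[rec_p].mean()
    signatures.loc[lig_p, "ct_epithelial"] *= 8.0
    signatures.loc[rec_p, "ct_fibroblast"] *= 8.0

    layout = make_layout(
        rows, cols,
        LayoutParams(tumor_radius=6.0, stroma_width=3.0, epithelium_width=4.0),
        seed=s_layout,
    )
    props = simulate_proportions(layout, CELL_TYPES, REGION_DIRICHLET, seed=s_props)
    ds = simulate_counts(props, signatures, layout, library_size=library_size,
                         dispersion=dispersion, seed=s_counts, sample_id="lr_bench")
    ds = normalize(ds)
    clusters = np.where(
        ds.annotations == "tumor", "tumor",
        np.where(ds.annotations == "stroma", "tme", "other"),
    )
    lr_pairs = [(lig_p, rec_p)] + decoy_pairs
    table = lr_consensus([ds], [clusters], lr_pairs, None, n_perm=n_perm, seed=seed)
    hit = table[
        (table["ligand"] == lig_p)
        & (table["receptor"] == rec_p)
        & (table["source"] == "tumor")
        & (table["target"] == "tme")
    ]
    return {
        "table": table,
        "planted_rank": float(hit["aggregate_rank"].iloc[0]),
        "n_candidates": int(len(table)),
    }


def deconvolution_benchmark(
    seed: int = 0,
    *,
    n_types: int = 5,
    n_genes: int = 2000,
    n_spots: int = 500,
    library_size: float = 5000.0,
    dispersion: float = 10.0,
) -> dict:
    """NNLS proportion recovery: noiseless mixtures and the default NB run."""
    s_sig, s_props, s_counts = _seeds(seed, 3)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    types = [f"ct{i}" for i in range(n_types)]
    signatures = make_signatures(genes, types, seed=s_sig, n_markers_per_type=50)

    rng = np.random.default_rng(s_props)
    props_vals = rng.dirichlet(np.ones(n_types), size=n_spots)
    spot_ids = np.array([f"s{i:05d}" for i in range(n_spots)], dtype=object)
    props = AbundanceMatrix(
        spot_ids=spot_ids, cell_types=np.array(types, dtype=object),
        values=props_vals, mode="proportion",
    )

    import scipy.sparse as sp

    from .core_data import SpotDataset

    G = signatures.to_numpy()
    noiseless = SpotDataset(
        sample_id="noiseless",
        spot_ids=spot_ids,
        array_coords=np.column_stack([np.zeros(n_spots, int), 2 * np.arange(n_spots)]),
        counts=sp.csr_matrix(G @ props_vals.T),
        gene_ids=np.array(genes, dtype=object),
    )
    est0 = nnls_deconvolve(noiseless, signatures)
    noiseless_err = float(np.abs(est0.values - props_vals).max())

    mu = G @ props_vals.T
    mu = mu * (library_size / mu.sum(axis=0))
    counts = synthio._draw_counts(mu, np.full(n_genes, float(dispersion)), s_counts)
    noisy = SpotDataset(
        sample_id="nb",
        spot_ids=spot_ids,
        array_coords=np.column_stack([np.zeros(n_spots, int), 2 * np.arange(n_spots)]),
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(genes, dtype=object),
    )
    est = nnls_deconvolve(noisy, signatures)
    l1 = float(np.abs(est.values - props_vals).sum(axis=1).mean())
    return {
        "noiseless_max_abs_error": noiseless_err,
        "nb_mean_l1_error": l1,
        "n_spots": n_spots,
    }


def tf_null_calibration(
    seed: int = 0,
    *,
    n_spots: int = 10000,
    n_genes: int = 1000,
    n_tfs: int = 5,
) -> dict:
    """Null distribution of the rank-based TF score under random expression.

    Simulates ``n_spots`` independent spots with exchangeable positive
    expression and reports the per-TF sample mean and SD, which should sit in
    tight bands around 0 and 1 respectively.
    """
    s_prior, s_expr = _seeds(seed, 2)
    prior = make_toy_prior(n_tfs=n_tfs, n_ligands=2, n_pathways=1, n_genes=n_genes,
                           seed=s_prior, regulon_size=(10, 14))
    rng = np.random.default_rng(s_expr)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    expr = pd.DataFrame(
        rng.lognormal(0.0, 1.0, size=(n_genes, n_spots)),
        index=pd.Index(genes),
        columns=[f"s{i}" for i in range(n_spots)],
    )
    act = tf_activity(expr, prior.regulons)
    means = np.nanmean(act.values, axis=0)
    sds = np.nanstd(act.values, axis=0, ddof=1)
    return {
        "tf_names": [str(f) for f in act.features],
        "means": means,
        "sds": sds,
        "max_abs_mean": float(np.abs(means).max()),
        "sd_range": (float(sds.min()), float(sds.max())),
    }
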