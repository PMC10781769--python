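"""End-to-end orchestration: simulate -> QC -> deconvolve -> spatial stats ->
activities -> clustering -> communication -> DGE/ORA.

Everything is driven by one seed (spawned deterministically per stage) and a
flat config dictionary, so a fixed (config, seed) pair reproduces every
output file bit for bit.  The CLI ``pipeline`` subcommand is a thin wrapper
around :func:`run_pipeline`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import (
    cluster_by_tf,
    pathway_activity,
    roc_markers,
    tf_activity,
    zscale_activities,
)
from .communication import (
    aggregate_importance,
    ligand_tf_importance,
    lr_consensus,
    select_ligands,
    selected_pairs,
    shortest_path_network,
    tme_mean_expression,
)
from .core_data import ActivityMatrix, SpotDataset, save_prior, write_table
from .core_data import SYNTH_VOCABULARY
from .diffexp import ora, wilcoxon_markers
from .preprocess import QCThresholds, nnls_deconvolve, normalize, qc_filter
from .spatial_stats import enrichment_score, replicate_consistency, stratify_tumor
from .synthio import (
    LayoutParams,
    make_layout,
    make_signatures,
    make_toy_prior,
    plant_ligand_tf_effects,
    prior_gene_pool,
    simulate_counts,
    simulate_proportions,
    simulate_replicate,
    write_synthetic_sample,
)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "simulate_cohort"]

DEFAULT_CONFIG: dict = {
    "n_patients": 2,
    "n_replicates": 2,
    "rows": 55,
    "cols": 55,
    "tumor_radius": 7.0,
    "stroma_width": 3.0,
    "epithelium_width": 5.0,
    "n_immune_aggregates": 2,
    "n_ligands": 10,
    "n_tfs": 5,
    "n_pathways": 3,
    "n_genes": 600,
    "library_size": 5000.0,
    "dispersion": 10.0,
    "replicate_noise": 1.5,
    "planted_effects": [["LIG00", "TF00", 1.0], ["LIG03", "TF01", 1.0], ["LIG07", "TF03", 1.0]],
    "noise_sd": 1.0,
    "patient_effect_genes": 60,
    "patient_effect_fold": 2.0,
    "qc_umi_min": 500,
    "qc_umi_max": 45000,
    "qc_mito_fraction_max": 0.5,
    "enrichment_n_perm": 10000,
    "cluster_n_pcs": 20,
    "cluster_k": 20,
    "cluster_resolution": 0.5,
    "lr_n_perm": 1000,
    "ora_min_set_size": 3,
}

CELL_TYPES = ("ct_epithelial", "ct_fibroblast", "ct_immune", "ct_endothelial", "ct_stem")
REGION_DIRICHLET = {
    "tumor": (8.0, 1.0, 1.0, 1.0, 1.0),
    "stroma": (1.0, 8.0, 1.0, 1.0, 1.0),
    "epithelium": (1.0, 1.0, 1.0, 1.0, 8.0),
    "lamina_propria": (1.0, 1.0, 1.0, 8.0, 1.0),
    "immune_aggregate": (1.0, 1.0, 8.0, 1.0, 1.0),
}


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def simulate_cohort(config: dict, seed: int):
    """Simulate patients x technical replicates with planted ligand->TF effects."""
    cfg = {**DEFAULT_CONFIG, **config}
    s_prior, s_sig, *s_pat = _seeds(seed, 2 + cfg["n_patients"])
    prior = make_toy_prior(
        n_tfs=cfg["n_tfs"], n_ligands=cfg["n_ligands"], n_pathways=cfg["n_pathways"],
        n_genes=cfg["n_genes"], seed=s_prior, regulon_size=(10, 14),
    )
    signatures = make_signatures(prior_gene_pool(prior), list(CELL_TYPES), seed=s_sig)
    effects = [(l, t, float(b)) for l, t, b in cfg["planted_effects"]]

    datasets: list[SpotDataset] = []
    for p in range(cfg["n_patients"]):
        sub = _seeds(s_pat[p], 4 + 2 * cfg["n_replicates"])
        # inter-patient heterogeneity: a patient-specific subset of genes is
        # uniformly up-scaled in every cell type
        rng = np.random.default_rng(sub[-1])
        pat_sig = signatures.copy()
        n_eff = min(int(cfg["patient_effect_genes"]), len(pat_sig))
        eff_genes = rng.choice(len(pat_sig), size=n_eff, replace=False)
        pat_sig.iloc[eff_genes] *= float(cfg["patient_effect_fold"])
        layout = make_layout(
            cfg["rows"], cfg["cols"],
            LayoutParams(
                tumor_radius=cfg["tumor_radius"], stroma_width=cfg["stroma_width"],
                epithelium_width=cfg["epithelium_width"],
                n_immune_aggregates=cfg["n_immune_aggregates"],
            ),
            seed=sub[0],
        )
        props = simulate_proportions(layout, CELL_TYPES, REGION_DIRICHLET, seed=sub[1])
        base = simulate_counts(
            props, pat_sig, layout, library_size=cfg["library_size"],
            dispersion=cfg["dispersion"], seed=sub[2], sample_id=f"P{p + 1}_base",
        )
        first_id = None
        for r in range(cfg["n_replicates"]):
            noise = 1.0 if r == 0 else cfg["replicate_noise"]
            ds = simulate_replicate(
                base, noise=noise, seed=sub[3 + 2 * r], sample_id=f"P{p + 1}_Rep{r + 1}"
            )
            ds = plant_ligand_tf_effects(
                ds, prior, effects, noise_sd=cfg["noise_sd"], seed=sub[4 + 2 * r]
            )
            ds.replicate_of = first_id
            if first_id is None:
                first_id = ds.sample_id
            datasets.append(ds)
    return datasets, prior, signatures


def run_pipeline(outdir: str | Path, seed: int, config: dict | None = None) -> dict:
    """Run every stage on a simulated cohort and write all outputs to disk."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run.json").write_text(json.dumps({"seed": seed, "config": cfg}, sort_keys=True, indent=1))
    s_cohort, s_cluster, s_enrich, s_importance, s_lr, s_repl = _seeds(seed, 6)

    datasets, prior, signatures = simulate_cohort(cfg, s_cohort)
    save_prior(prior, outdir / "prior")
    for ds in datasets:
        write_synthetic_sample(ds, outdir / "samples" / ds.sample_id)

    vocab = SYNTH_VOCABULARY
    thr = QCThresholds(
        umi_min=cfg["qc_umi_min"], umi_max=cfg["qc_umi_max"],
        mito_fraction_max=cfg["qc_mito_fraction_max"],
    )
    kept, abundances = [], {}
    qc_dir = outdir / "qc"
    qc_dir.mkdir(exist_ok=True)
    for ds in datasets:
        ds_f, report = qc_filter(ds, thr)
        (qc_dir / f"{ds.sample_id}.json").write_text(json.dumps(report, sort_keys=True, indent=1))
        ds_f = normalize(ds_f)
        kept.append(ds_f)

    dec_dir = outdir / "deconvolution"
    dec_dir.mkdir(exist_ok=True)
    for ds in kept:
        ab = nnls_deconvolve(ds, signatures)
        abundances[ds.sample_id] = ab
        write_table(ab, dec_dir / f"{ds.sample_id}.tsv")

    enr_dir = outdir / "enrichment"
    enr_dir.mkdir(exist_ok=True)
    for i, ds in enumerate(kept):
        res = enrichment_score(
            abundances[ds.sample_id], ds.annotations, vocab,
            n_perm=cfg["enrichment_n_perm"], seed=s_enrich + i,
        )
        write_table(res, enr_dir / f"{ds.sample_id}.tsv")

    zone_dir = outdir / "zoning"
    zone_dir.mkdir(exist_ok=True)
    for ds in kept:
        zoning = stratify_tumor(ds, vocab)
        zoning.to_frame().to_csv(zone_dir / f"{ds.sample_id}.tsv", sep="\t")
        pd.DataFrame({"spot_id": zoning.surrounding.astype(str)}).to_csv(
            zone_dir / f"{ds.sample_id}_surrounding.tsv", sep="\t", index=False
        )

    # replicate consistency per patient (first two replicates)
    repl_dir = outdir / "replicates"
    repl_dir.mkdir(exist_ok=True)
    by_sample = {ds.sample_id: ds for ds in kept}
    for ds in kept:
        if ds.replicate_of and ds.replicate_of in by_sample:
            a = by_sample[ds.replicate_of]
            tab = replicate_consistency(
                abundances[a.sample_id], abundances[ds.sample_id], a, ds, seed=s_repl
            )
            tab.to_csv(repl_dir / f"{a.sample_id}_vs_{ds.sample_id}.tsv", sep="\t", index=False)

    act_dir = outdir / "activity"
    act_dir.mkdir(exist_ok=True)
    tf_acts = {}
    for ds in kept:
        pw = pathway_activity(ds, prior.pathway_weights, scale=True)
        write_table(pw, act_dir / f"{ds.sample_id}_pathways.tsv")
        act = tf_activity(ds, prior.regulons)
        tf_acts[ds.sample_id] = act
        write_table(act, act_dir / f"{ds.sample_id}_tfs.tsv")

    # merge TF activities over all spots, cluster, find markers
    merged_units = np.concatenate(
        [[f"{ds.sample_id}:{s}" for s in ds.spot_ids.astype(str)] for ds in kept]
    )
    merged_vals = np.vstack([tf_acts[ds.sample_id].values for ds in kept])
    merged_act = ActivityMatrix(
        unit_ids=merged_units,
        features=tf_acts[kept[0].sample_id].features.copy(),
        values=merged_vals,
        meta={"merged": [ds.sample_id for ds in kept]},
    )
    clusters = cluster_by_tf(
        merged_act, n_pcs=cfg["cluster_n_pcs"], k=cfg["cluster_k"],
        resolution=cfg["cluster_resolution"], seed=s_cluster,
    )
    clusters.to_frame().to_csv(outdir / "tf_clusters.tsv", sep="\t")
    markers = roc_markers(zscale_activities(merged_act), clusters, return_all=True)
    markers.to_csv(outdir / "tf_cluster_markers.tsv", sep="\t", index=False)

    # map clusters to compartments via annotations
    merged_annot = np.concatenate([ds.annotations for ds in kept])
    tumor_share, tme_share = {}, {}
    for lab in np.unique(clusters.labels):
        in_c = clusters.labels == lab
        tumor_share[lab] = float(np.mean(vocab.is_tumor(merged_annot[in_c])))
        tme_share[lab] = float(
            np.mean(np.isin(merged_annot[in_c], list(vocab.tme_categories)))
        )
    tumor_cluster = max(tumor_share, key=lambda k: (tumor_share[k], -k))
    tme_cluster = max(
        (k for k in tme_share if k != tumor_cluster),
        key=lambda k: (tme_share[k], -k),
    )
    (outdir / "cluster_map.json").write_text(
        json.dumps(
            {
                "tumor_cluster": int(tumor_cluster),
                "tme_cluster": int(tme_cluster),
                "tumor_share": {str(k): v for k, v in tumor_share.items()},
                "tme_share": {str(k): v for k, v in tme_share.items()},
            },
            sort_keys=True, indent=1,
        )
    )

    # per-sample interface masks (spots in the tumor or TME cluster)
    offsets = np.cumsum([0] + [ds.n_spots for ds in kept])
    masks = []
    labels_per_sample = []
    for i, ds in enumerate(kept):
        lab = clusters.labels[offsets[i]: offsets[i + 1]]
        labels_per_sample.append(lab.astype(str))
        masks.append(np.isin(lab, [tumor_cluster, tme_cluster]))

    ligands = select_ligands(kept, masks, prior)
    (outdir / "selected_ligands.json").write_text(json.dumps(ligands, indent=1))
    importance_ligands = ligands if len(ligands) >= 2 else sorted(prior.ligands)

    per_sample_imp = []
    for i, ds in enumerate(kept):
        imp = ligand_tf_importance(
            ds, importance_ligands, tf_acts[ds.sample_id],
            spot_mask=masks[i], seed=s_importance + i,
        )
        imp.table.to_csv(outdir / "activity" / f"{ds.sample_id}_importance.tsv", sep="\t")
        per_sample_imp.append(imp)
    agg = aggregate_importance(per_sample_imp)
    agg.table.to_csv(outdir / "ligand_tf_importance.tsv", sep="\t")
    pairs = selected_pairs(agg)

    lr_table = lr_consensus(
        kept, labels_per_sample, prior.lr_pairs, importance_ligands,
        n_perm=cfg["lr_n_perm"], seed=s_lr,
    )
    lr_table.to_csv(outdir / "lr_interactions.tsv", sep="\t", index=False)

    tme_masks = [lab == str(tme_cluster) for lab in labels_per_sample]
    node_expr = tme_mean_expression(kept, tme_masks)
    net = shortest_path_network(prior, lr_table, pairs, node_expression=node_expr)
    net.write_sif(outdir / "network.sif")
    net.write_graphml(outdir / "network.graphml")
    (outdir / "network_report.json").write_text(
        json.dumps(
            {
                "n_nodes": net.graph.number_of_nodes(),
                "n_edges": net.graph.number_of_edges(),
                "unreachable": [list(p) for p in net.unreachable],
                "unmapped": [list(p) for p in net.unmapped],
                "ligand_tf_pairs": [list(p) for p in pairs],
            },
            sort_keys=True, indent=1,
        )
    )

    # inter-patient DGE on tumor-annotated spots, then ORA on pathway gene sets
    tumor_blocks, patient_labels = [], []
    genes = kept[0].gene_ids.astype(str)
    for ds in kept:
        tmask = vocab.is_tumor(ds.annotations)
        tumor_blocks.append(np.asarray(ds.norm)[:, tmask])
        patient = ds.sample_id.split("_")[0]
        patient_labels.extend([patient] * int(tmask.sum()))
    tumor_expr = pd.DataFrame(
        np.hstack(tumor_blocks), index=pd.Index(genes),
        columns=[f"t{i}" for i in range(len(patient_labels))],
    )
    dge = wilcoxon_markers(tumor_expr, np.asarray(patient_labels))
    dge.to_csv(outdir / "dge_patients.tsv", sep="\t", index=False)

    gene_sets = {pw: [g for g, _, _ in entries] for pw, entries in prior.pathway_weights.items()}
    background = [g for g in genes if not g.startswith(("RPL", "RPS", "MT-"))]
    query = sorted(set(dge.loc[dge["p_adj"] < 0.05, "gene"]))
    if query:
        ora_table = ora(query, gene_sets, background, min_set_size=cfg["ora_min_set_size"])
    else:
        ora_table = ora(sorted(background)[:1], gene_sets, background,
                        min_set_size=cfg["ora_min_set_size"]).iloc[0:0]
    ora_table.to_csv(outdir / "ora_patients.tsv", sep="\t", index=False)

    return {
        "outdir": str(outdir),
        "samples": [ds.sample_id for ds in kept],
        "n_ligands_selected": len(ligands),
        "ligand_tf_pairs": pairs,
        "tumor_cluster": int(tumor_cluster),
        "tme_cluster": int(tme_cluster),
    }
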