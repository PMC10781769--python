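"""Tumor-stroma cell-communication inference.

Four linked stages: (1) selection of ligands overexpressed at the
tumor/TME interface and of TFs marking the TME activity cluster; (2) a
multi-view spatial importance model predicting each TF's activity from
ligand expression at the spot (intraview) and averaged over its <= 2
canonical-distance neighborhood (juxtaview), with per-TF z-scored
importances aggregated across samples; (3) consensus ranking of candidate
ligand-receptor interactions between clusters from three transparent
component scores (expression product, specificity, permutation p); and
(4) shortest-path reconstruction of receptor -> TF signaling cascades on the
signed protein-interaction graph, merged with the predicted LR edges.

Outputs are associations, not causal claims.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_data import ActivityMatrix, PriorKnowledge, SpotDataset
from .synthio import neighborhood_mean

__all__ = [
    "LigandImportance",
    "SignalingNetwork",
    "select_ligands",
    "select_tme_tfs",
    "ligand_tf_importance",
    "aggregate_importance",
    "lr_consensus",
    "shortest_path_network",
    "tme_mean_expression",
]

IMPORTANCE_THRESHOLD = 1.0
RANK_MAX = 0.01


def select_ligands(
    ds_list: Sequence[SpotDataset],
    interface_masks: Sequence[np.ndarray],
    prior: PriorKnowledge,
    *,
    lfc_min: float = 0.5,
    min_detect: float = 0.10,
    alpha: float = 0.05,
) -> list[str]:
    """Ligands overexpressed in tumor+TME spots and robustly detected.

    ``interface_masks`` flags the tumor+TME spots per sample.  Genes must be
    positive Wilcoxon markers (log2FC >= ``lfc_min``, BH-adjusted p < alpha)
    of the pooled interface vs all other spots, be annotated as ligands in the
    prior, and be detected (count > 0) in at least ``min_detect`` of the
    interface spots of every individual sample.
    """
    from .diffexp import wilcoxon_markers

    genes = ds_list[0].gene_ids
    norm_blocks, group_blocks = [], []
    for ds, mask in zip(ds_list, interface_masks):
        if ds.norm is None:
            raise ValueError(f"sample {ds.sample_id} has no normalized layer")
        if not np.array_equal(ds.gene_ids, genes):
            raise ValueError("samples must share the gene list")
        mask = np.asarray(mask, dtype=bool)
        norm_blocks.append(np.asarray(ds.norm))
        group_blocks.append(np.where(mask, "interface", "other"))
    expr = pd.DataFrame(
        np.hstack(norm_blocks),
        index=pd.Index(genes.astype(str)),
        columns=[f"s{i}" for i in range(sum(b.shape[1] for b in norm_blocks))],
    )
    groups = np.concatenate(group_blocks)
    table = wilcoxon_markers(
        expr, groups, lfc_min=lfc_min, positive_only=True, exclude_patterns=()
    )
    table = table[(table["group"] == "interface") & (table["p_adj"] < alpha)]
    candidates = set(table["gene"]) & set(prior.ligands)
    if not candidates:
        warnings.warn("no overexpressed genes intersect the ligand list")
        return []

    selected = []
    for lig in sorted(candidates):
        ok = True
        for ds, mask in zip(ds_list, interface_masks):
            gi = np.flatnonzero(ds.gene_ids.astype(str) == lig)
            mask = np.asarray(mask, dtype=bool)
            if not mask.any():
                ok = False
                break
            detected = np.asarray((ds.counts[gi[0]] > 0).todense()).ravel()[mask]
            if detected.mean() < min_detect:
                ok = False
                break
        if ok:
            selected.append(lig)
    return selected


def select_tme_tfs(
    markers: pd.DataFrame, tme_cluster, *, min_auc: float = 0.75
) -> list[str]:
    """TFs passing the marker thresholds for the TME activity cluster."""
    t = markers[(markers["cluster"] == tme_cluster) & (markers["auc"] >= min_auc)]
    if "marker" in t.columns:
        t = t[t["marker"]]
    return sorted(t["feature"].unique())


@dataclass
class LigandImportance:
    """Ligand x TF spatial importance for one sample (or an aggregate)."""

    table: pd.DataFrame  # ligands x TFs, z-scored importances per TF
    sample_id: str
    meta: dict = field(default_factory=dict)


def ligand_tf_importance(
    ds: SpotDataset,
    ligands: Sequence[str],
    tf_act: ActivityMatrix,
    *,
    neighbor_thr: float = 2.0,
    ridge_alpha: float = 1.0,
    spot_mask: np.ndarray | None = None,
    seed: int = 0,
) -> LigandImportance:
    """Multi-view ridge importance of ligand expression on TF activity.

    For each TF, its per-spot activity is regressed on two standardized
    predictor blocks per ligand: expression at the spot (intraview) and mean
    expression over spots within canonical distance <= ``neighbor_thr``
    (juxtaview, ball includes the spot).  The raw importance of a ligand is
    the sum of its two absolute standardized ridge coefficients; importances
    are z-scored across ligands per TF, so each TF column has mean 0 / SD 1
    by construction.
    """
    ligands = list(ligands)
    if len(ligands) < 2:
        raise ValueError("importance undefined for one predictor; need >= 2 ligands")
    if ds.norm is None:
        raise ValueError("dataset has no normalized layer")
    if not np.array_equal(ds.spot_ids.astype(str), tf_act.unit_ids.astype(str)):
        raise ValueError("TF activities must align with dataset spots")
    mask = (
        np.ones(ds.n_spots, dtype=bool)
        if spot_mask is None
        else np.asarray(spot_mask, dtype=bool)
    )
    coords = ds.canon_coords[mask]
    gene_pos = {g: i for i, g in enumerate(ds.gene_ids.astype(str))}
    missing = [l for l in ligands if l not in gene_pos]
    if missing:
        raise ValueError(f"ligands not in dataset: {missing}")

    norm = np.asarray(ds.norm)
    intra = norm[[gene_pos[l] for l in ligands]][:, mask].T  # spots x ligands
    juxta = neighborhood_mean(coords, intra, radius=neighbor_thr)

    def standardize(m: np.ndarray) -> np.ndarray:
        mu = m.mean(axis=0)
        sd = m.std(axis=0, ddof=0)
        out = np.zeros_like(m)
        ok = sd > 0
        out[:, ok] = (m[:, ok] - mu[ok]) / sd[ok]
        return out

    X_full = np.hstack([standardize(intra), standardize(juxta)])
    L = len(ligands)

    tf_names = [str(f) for f in tf_act.features]
    imp = np.full((L, len(tf_names)), np.nan)
    y_all = tf_act.values[mask]
    eye = np.eye(X_full.shape[1])
    for j in range(len(tf_names)):
        y = y_all[:, j]
        ok = ~np.isnan(y)
        if ok.sum() < X_full.shape[1] + 2:
            continue
        X = X_full[ok]
        yv = y[ok]
        sd = yv.std(ddof=0)
        if sd == 0:
            continue
        yv = (yv - yv.mean()) / sd
        beta = np.linalg.solve(X.T @ X + ridge_alpha * eye, X.T @ yv)
        raw = np.abs(beta[:L]) + np.abs(beta[L:])
        mu, s = raw.mean(), raw.std(ddof=0)
        imp[:, j] = (raw - mu) / s if s > 0 else 0.0
    table = pd.DataFrame(imp, index=pd.Index(ligands, name="ligand"), columns=tf_names)
    return LigandImportance(
        table=table,
        sample_id=ds.sample_id,
        meta={
            "regressor": "ridge_closed_form",
            "ridge_alpha": ridge_alpha,
            "neighbor_thr": neighbor_thr,
            "n_spots": int(mask.sum()),
            "seed": seed,
        },
    )


def aggregate_importance(per_sample: Sequence[LigandImportance]) -> LigandImportance:
    """Arithmetic mean of per-sample importances over samples where defined."""
    if not per_sample:
        raise ValueError("no per-sample importances to aggregate")
    stacked = pd.concat([li.table for li in per_sample], keys=range(len(per_sample)))
    agg = stacked.groupby(level=1, sort=False).mean()
    agg = agg.loc[per_sample[0].table.index]
    return LigandImportance(
        table=agg,
        sample_id="aggregate",
        meta={"n_samples": len(per_sample), "samples": [li.sample_id for li in per_sample]},
    )


def selected_pairs(
    agg: LigandImportance, *, threshold: float = IMPORTANCE_THRESHOLD
) -> list[tuple[str, str]]:
    """(ligand, TF) associations with aggregated importance > threshold."""
    t = agg.table
    out = []
    for lig in t.index:
        for tf in t.columns:
            v = t.loc[lig, tf]
            if np.isfinite(v) and v > threshold:
                out.append((str(lig), str(tf)))
    return out


def lr_consensus(
    ds_list: Sequence[SpotDataset],
    cluster_labels: Sequence[np.ndarray],
    lr_pairs: Sequence[tuple[str, str]],
    selected_ligands: Sequence[str] | None = None,
    *,
    n_perm: int = 1000,
    seed: int = 0,
    rank_max: float = RANK_MAX,
) -> pd.DataFrame:
    """Consensus ranking of ligand-receptor interactions between clusters.

    For every ordered cluster pair and candidate LR pair three component
    scores are computed on the merged normalized layer: the product of the
    ligand's source-cluster and the receptor's target-cluster mean expression
    (s1); the product of the two cluster-specificity fractions (s2); and a
    permutation p-value for s1 under cluster-label shuffles.  Each component
    is ranked across all candidates and the aggregate rank is the mean of the
    three normalized ranks in (0, 1]; interactions are selected when the
    aggregate rank is < ``rank_max`` and the ligand is in the selected set.
    """
    genes = ds_list[0].gene_ids.astype(str)
    blocks, labels = [], []
    for ds, lab in zip(ds_list, cluster_labels):
        if ds.norm is None:
            raise ValueError(f"sample {ds.sample_id} has no normalized layer")
        if not np.array_equal(ds.gene_ids.astype(str), genes):
            raise ValueError("samples must share the gene list")
        blocks.append(np.asarray(ds.norm))
        labels.append(np.asarray(lab))
    norm = np.hstack(blocks)
    labels = np.concatenate(labels)
    clusters = sorted(set(labels.tolist()), key=str)
    gene_pos = {g: i for i, g in enumerate(genes)}

    candidates = []
    for lig, rec in lr_pairs:
        if lig not in gene_pos or rec not in gene_pos:
            warnings.warn(f"LR pair ({lig}, {rec}) absent from data; skipped")
            continue
        candidates.append((lig, rec))
    if not candidates:
        raise ValueError("no candidate LR pairs present in the data")

    involved = sorted({g for pair in candidates for g in pair})
    inv_pos = {g: i for i, g in enumerate(involved)}
    E = norm[[gene_pos[g] for g in involved]]  # involved genes x spots

    cl_idx = [np.flatnonzero(labels == c) for c in clusters]
    obs_means = np.column_stack([E[:, idx].mean(axis=1) for idx in cl_idx])
    row_tot = obs_means.sum(axis=1)

    # permutation null for cluster means: shuffle spot labels jointly
    rng = np.random.default_rng(seed)
    n_spots = E.shape[1]
    sizes = [idx.size for idx in cl_idx]
    lig_rows = np.array([inv_pos[l] for l, _ in candidates])
    rec_rows = np.array([inv_pos[r] for _, r in candidates])
    obs_s1 = obs_means[lig_rows][:, :, None] * obs_means[rec_rows][:, None, :]
    ge_counts = np.zeros_like(obs_s1)
    for _ in range(n_perm):
        perm = rng.permutation(n_spots)
        start = 0
        pm = np.empty((len(involved), len(clusters)))
        for c, size in enumerate(sizes):
            pm[:, c] = E[:, perm[start : start + size]].mean(axis=1)
            start += size
        perm_s1 = pm[lig_rows][:, :, None] * pm[rec_rows][:, None, :]
        ge_counts += perm_s1 >= obs_s1 - 1e-15
    pvals = (1.0 + ge_counts) / (n_perm + 1.0)

    rows = []
    for k, (lig, rec) in enumerate(candidates):
        li, ri = inv_pos[lig], inv_pos[rec]
        for a, ca in enumerate(clusters):
            for b, cb in enumerate(clusters):
                spec_l = obs_means[li, a] / row_tot[li] if row_tot[li] > 0 else 0.0
                spec_r = obs_means[ri, b] / row_tot[ri] if row_tot[ri] > 0 else 0.0
                rows.append(
                    {
                        "source": ca,
                        "target": cb,
                        "ligand": lig,
                        "receptor": rec,
                        "s1_product": float(obs_s1[k, a, b]),
                        "s2_specificity": float(spec_l * spec_r),
                        "p_perm": float(pvals[k, a, b]),
                    }
                )
    table = pd.DataFrame(rows)
    n_cand = len(table)
    table["rank_s1"] = rankdata(-table["s1_product"]) / n_cand
    table["rank_s2"] = rankdata(-table["s2_specificity"]) / n_cand
    # permutation p is granular (resolution 1/(n_perm+1)); ties are broken by
    # the strength of the underlying product so the p-rank stays informative
    order = np.lexsort((-table["s1_product"].to_numpy(), table["p_perm"].to_numpy()))
    rank_p = np.empty(n_cand)
    rank_p[order] = np.arange(1, n_cand + 1)
    table["rank_p"] = rank_p / n_cand
    table["aggregate_rank"] = table[["rank_s1", "rank_s2", "rank_p"]].mean(axis=1)
    lig_ok = (
        table["ligand"].isin(set(selected_ligands))
        if selected_ligands is not None
        else pd.Series(True, index=table.index)
    )
    table["selected"] = (table["aggregate_rank"] < rank_max) & lig_ok
    return table.sort_values("aggregate_rank", kind="stable").reset_index(drop=True)


@dataclass
class SignalingNetwork:
    """Merged LR + shortest-path PPI network with expression annotation."""

    graph: nx.DiGraph
    unreachable: list[tuple[str, str]] = field(default_factory=list)
    unmapped: list[tuple[str, str]] = field(default_factory=list)

    def write_sif(self, path: str | Path) -> None:
        lines = []
        for u, v, data in sorted(self.graph.edges(data=True)):
            rel = data.get("kind", "PPI")
            sign = data.get("sign", 0)
            lines.append(f"{u}\t{rel}{'+' if sign > 0 else '-' if sign < 0 else ''}\t{v}")
        Path(path).write_text("\n".join(lines) + "\n")

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        for _, _, data in g.edges(data=True):
            if "paths" in data:
                data["paths"] = ";".join(f"{r}->{t}" for r, t in data["paths"])
        nx.write_graphml(g, path)


def tme_mean_expression(
    ds_list: Sequence[SpotDataset], tme_masks: Sequence[np.ndarray]
) -> dict[str, float]:
    """Mean normalized expression per gene over TME spots across samples."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for ds, mask in zip(ds_list, tme_masks):
        if ds.norm is None:
            raise ValueError(f"sample {ds.sample_id} has no normalized layer")
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            continue
        sub = np.asarray(ds.norm)[:, mask]
        for g, row_sum in zip(ds.gene_ids.astype(str), sub.sum(axis=1)):
            sums[g] = sums.get(g, 0.0) + float(row_sum)
            counts[g] = counts.get(g, 0) + int(mask.sum())
    return {g: sums[g] / counts[g] for g in sums if counts[g] > 0}


def shortest_path_network(
    prior: PriorKnowledge,
    lr_hits: pd.DataFrame,
    ligand_tf_pairs: Sequence[tuple[str, str]],
    *,
    node_expression: Mapping[str, float] | None = None,
    max_paths_per_pair: int = 50,
) -> SignalingNetwork:
    """Receptor -> TF shortest-path signaling network merged with LR edges.

    For every (ligand, TF) association, each of the ligand's selected
    receptors (rows of ``lr_hits`` with ``selected``) is connected to the TF
    by all unit-weight shortest directed paths in the signed PPI graph
    (breadth-first, capped at ``max_paths_per_pair`` paths; the cap is
    logged when hit).  Path edges are unioned and merged with the LR edges;
    nodes carry mean TME expression where measured.  Pairs whose endpoints
    are missing from the PPI graph are reported unmapped; pairs with no path
    are reported unreachable, never silently dropped.
    """
    if not prior.ppi_edges:
        raise ValueError("empty PPI graph")
    ppi = nx.DiGraph()
    for s, t, sign in prior.ppi_edges:
        ppi.add_edge(s, t, sign=sign)

    hits = lr_hits[lr_hits["selected"]] if "selected" in lr_hits.columns else lr_hits
    receptors_of: dict[str, set[str]] = {}
    for row in hits.itertuples(index=False):
        receptors_of.setdefault(str(row.ligand), set()).add(str(row.receptor))

    net = nx.DiGraph()
    unreachable: list[tuple[str, str]] = []
    unmapped: list[tuple[str, str]] = []
    tf_set = {tf for _, tf in ligand_tf_pairs}
    rec_set: set[str] = set()
    lig_set: set[str] = set()

    for lig, tf in ligand_tf_pairs:
        for rec in sorted(receptors_of.get(lig, ())):
            if rec not in ppi or tf not in ppi:
                unmapped.append((rec, tf))
                continue
            try:
                paths_iter = nx.all_shortest_paths(ppi, rec, tf)
                paths = []
                for p in paths_iter:
                    paths.append(p)
                    if len(paths) >= max_paths_per_pair:
                        warnings.warn(
                            f"path cap {max_paths_per_pair} hit for {rec}->{tf}"
                        )
                        break
            except nx.NetworkXNoPath:
                unreachable.append((rec, tf))
                continue
            lig_set.add(lig)
            rec_set.add(rec)
            net.add_edge(lig, rec, kind="LR", sign=1)
            for p in paths:
                for u, v in zip(p[:-1], p[1:]):
                    if net.has_edge(u, v) and net[u][v].get("kind") == "PPI":
                        net[u][v]["paths"].append((rec, tf))
                    else:
                        net.add_edge(
                            u, v, kind="PPI", sign=ppi[u][v]["sign"], paths=[(rec, tf)]
                        )

    for node in net.nodes:
        if node in lig_set:
            ntype = "ligand"
        elif node in rec_set:
            ntype = "receptor"
        elif node in tf_set:
            ntype = "tf"
        else:
            ntype = "intermediary"
        net.nodes[node]["type"] = ntype
        if node_expression is not None and node in node_expression:
            net.nodes[node]["mean_expression"] = float(node_expression[node])
    return SignalingNetwork(graph=net, unreachable=unreachable, unmapped=unmapped)
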