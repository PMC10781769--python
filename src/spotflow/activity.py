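"""Footprint-based pathway, TF and module activity scoring.

Pathway activity follows the footprint idea: a pathway's score at a spot is a
weighted sum of z-scored expression of its most perturbation-responsive
genes, not its member genes.  TF activity is a rank-based regulon statistic
with an analytic standard-normal null: per spot, expressed genes are ranked,
target ranks are mapped through the normal quantile function and combined as
``sum(mode_i * q_i) / sqrt(n)``.  Module scores are expression-bin-matched
control-subtracted means.  The module also provides seeded modularity
clustering of activity profiles, ROC (AUC) marker detection, and
abundance-activity correlation (Pearson cross-correlation or CCA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from ._utils import pca_knn_leiden
from .core_data import AbundanceMatrix, ActivityMatrix, PriorKnowledge, SpotDataset
from .preprocess import PseudoBulk

__all__ = [
    "pathway_activity",
    "tf_activity",
    "module_score",
    "cluster_by_tf",
    "roc_markers",
    "abundance_activity_correlation",
    "ClusterAssignment",
    "zscale_activities",
]

DEFAULT_GRADES = frozenset({"A", "B", "C"})


def _expression_frame(expr) -> pd.DataFrame:
    """Genes x units expression from a SpotDataset norm layer or PseudoBulk."""
    if isinstance(expr, SpotDataset):
        if expr.norm is None:
            raise ValueError("dataset has no normalized layer; run normalize() first")
        return pd.DataFrame(
            np.asarray(expr.norm),
            index=pd.Index(expr.gene_ids.astype(str)),
            columns=expr.spot_ids.astype(str),
        )
    if isinstance(expr, PseudoBulk):
        frame = expr.to_frame(layer="cpm", filtered=True)
        return np.log1p(frame)
    if isinstance(expr, pd.DataFrame):
        return expr
    raise TypeError(f"unsupported expression container {type(expr).__name__}")


def pathway_activity(
    expr,
    pathway_weights: Mapping[str, Sequence[tuple[str, float, int]]],
    *,
    top_n: int = 500,
    scale: bool = False,
) -> ActivityMatrix:
    """Weighted-footprint pathway activities per unit (spot or group).

    Per pathway, genes are restricted to the ``top_n`` most responsive (by
    responsiveness rank), expression is z-scored per gene across units, and
    the activity is the weighted sum over available genes.  With ``scale``
    each pathway column is additionally z-scored across units.
    """
    frame = _expression_frame(expr)
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 units to z-score expression")
    x = frame.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    gene_pos = {g: i for i, g in enumerate(frame.index)}

    names = sorted(pathway_weights)
    values = np.full((frame.shape[1], len(names)), np.nan)
    for j, pw in enumerate(names):
        entries = sorted(pathway_weights[pw], key=lambda t: t[2])[:top_n]
        rows, wts = [], []
        for g, w, _rank in entries:
            if g in gene_pos:
                rows.append(gene_pos[g])
                wts.append(w)
        if not rows:
            warnings.warn(f"pathway {pw!r} has no genes in the expression data")
            continue
        values[:, j] = np.asarray(wts) @ z[rows]
    if scale:
        mu_c = np.nanmean(values, axis=0)
        sd_c = np.nanstd(values, axis=0, ddof=0)
        ok = sd_c > 0
        values[:, ok] = (values[:, ok] - mu_c[ok]) / sd_c[ok]
    return ActivityMatrix(
        unit_ids=frame.columns.to_numpy(dtype=object),
        features=np.asarray(names, dtype=object),
        values=values,
        meta={"method": "footprint_weighted_sum", "top_n": top_n, "scaled": bool(scale)},
    )


def tf_activity(
    expr,
    regulons: Mapping[str, Sequence[tuple[str, int, str]]],
    *,
    grades: frozenset[str] = DEFAULT_GRADES,
    min_targets: int = 4,
) -> ActivityMatrix:
    """Rank-based regulon TF activity with a standard-normal null.

    Per spot, the N expressed (nonzero) genes are ranked; a target at rank r
    contributes ``q = ndtri(r / (N + 1))``; the TF's activity is
    ``sum(mode_i * q_i) / sqrt(n)`` over its n expressed targets (missing when
    n < ``min_targets``).  Only regulon edges with the requested confidence
    grades are used; TFs left without targets are dropped with a warning.
    """
    frame = _expression_frame(expr)
    gene_pos = {g: i for i, g in enumerate(frame.index)}

    tf_names, tf_idx, tf_modes = [], [], []
    for tf in sorted(regulons):
        kept = [
            (gene_pos[g], m)
            for g, m, grade in regulons[tf]
            if grade in grades and g in gene_pos
        ]
        if not kept:
            warnings.warn(f"TF {tf!r} has no graded targets in the data; dropped")
            continue
        tf_names.append(tf)
        tf_idx.append(np.array([i for i, _ in kept], dtype=int))
        tf_modes.append(np.array([m for _, m in kept], dtype=float))
    if not tf_names:
        raise ValueError("no regulons usable after grade filtering")

    x = frame.to_numpy(dtype=float)
    n_units = x.shape[1]
    values = np.full((n_units, len(tf_names)), np.nan)
    for s in range(n_units):
        col = x[:, s]
        expressed = np.flatnonzero(col > 0)
        n_expr = expressed.size
        if n_expr == 0:
            continue
        ranks = rankdata(col[expressed])
        qvec = np.full(x.shape[0], np.nan)
        qvec[expressed] = ndtri(ranks / (n_expr + 1))
        for j, (idx, modes) in enumerate(zip(tf_idx, tf_modes)):
            q = qvec[idx]
            ok = ~np.isnan(q)
            n = int(ok.sum())
            if n >= min_targets:
                values[s, j] = float(modes[ok] @ q[ok]) / np.sqrt(n)
    return ActivityMatrix(
        unit_ids=frame.columns.to_numpy(dtype=object),
        features=np.asarray(tf_names, dtype=object),
        values=values,
        meta={
            "method": "rank_normal_regulon",
            "grades": sorted(grades),
            "min_targets": min_targets,
        },
    )


def module_score(
    expr,
    gene_sets: Mapping[str, Sequence[str]],
    *,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ActivityMatrix:
    """Bin-matched control-subtracted module scores per spot.

    Genes are binned by mean expression into ``n_bins`` equal-size bins; for
    every set gene ``n_ctrl`` control genes are sampled (seeded, with
    replacement) from its bin; the score is mean set expression minus mean
    control expression.
    """
    frame = _expression_frame(expr)
    x = frame.to_numpy(dtype=float)
    n_genes = x.shape[0]
    order = np.argsort(frame.to_numpy(dtype=float).mean(axis=1), kind="stable")
    bin_of = np.empty(n_genes, dtype=int)
    bins = np.array_split(order, min(n_bins, n_genes))
    for b, members in enumerate(bins):
        bin_of[members] = b
    bin_members = [np.asarray(members) for members in bins]
    gene_pos = {g: i for i, g in enumerate(frame.index)}

    rng = np.random.default_rng(seed)
    names = sorted(gene_sets)
    values = np.full((x.shape[1], len(names)), np.nan)
    for j, name in enumerate(names):
        present = [gene_pos[g] for g in gene_sets[name] if g in gene_pos]
        if not present:
            warnings.warn(f"gene set {name!r} has no genes in the expression data")
            continue
        ctrl: list[np.ndarray] = []
        for gi in present:
            pool = bin_members[bin_of[gi]]
            ctrl.append(rng.choice(pool, size=n_ctrl, replace=True))
        ctrl_idx = np.concatenate(ctrl)
        values[:, j] = x[present].mean(axis=0) - x[ctrl_idx].mean(axis=0)
    return ActivityMatrix(
        unit_ids=frame.columns.to_numpy(dtype=object),
        features=np.asarray(names, dtype=object),
        values=values,
        meta={"method": "bin_matched_module_score", "n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed},
    )


def zscale_activities(act: ActivityMatrix) -> ActivityMatrix:
    """Per-feature z-scaling over defined values; missingness is preserved."""
    v = act.values.copy()
    mu = np.nanmean(v, axis=0)
    sd = np.nanstd(v, axis=0, ddof=0)
    ok = sd > 0
    v[:, ok] = (v[:, ok] - mu[ok]) / sd[ok]
    v[:, ~ok] = np.where(np.isnan(v[:, ~ok]), np.nan, 0.0)
    return ActivityMatrix(
        unit_ids=act.unit_ids.copy(),
        features=act.features.copy(),
        values=v,
        meta={**act.meta, "scaled": True},
    )


@dataclass
class ClusterAssignment:
    """Spot clustering on activity profiles plus its parameters."""

    unit_ids: np.ndarray
    labels: np.ndarray
    params: dict = field(default_factory=dict)
    markers: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": self.labels},
            index=pd.Index(self.unit_ids.astype(str), name="unit_id"),
        )


def cluster_by_tf(
    act: ActivityMatrix,
    *,
    n_pcs: int = 20,
    k: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster spots by their activity profiles (z-scale, PCA, k-NN, Leiden).

    Missing activities are zero-imputed after per-feature scaling — for the
    clustering only; statistics elsewhere stay missingness-aware.
    """
    if len(act.features) < 2:
        raise ValueError("need at least 2 activity features to cluster")
    scaled = zscale_activities(act).values
    scaled = np.nan_to_num(scaled, nan=0.0)
    labels = pca_knn_leiden(scaled, n_pcs=n_pcs, k=k, resolution=resolution, seed=seed)
    return ClusterAssignment(
        unit_ids=act.unit_ids.copy(),
        labels=labels,
        params={"n_pcs": n_pcs, "k": k, "resolution": resolution, "seed": seed},
    )


def roc_markers(
    act: ActivityMatrix,
    clusters: ClusterAssignment | np.ndarray,
    *,
    min_pct: float = 0.25,
    min_diff: float = 1.0,
    min_auc: float = 0.75,
    return_all: bool = False,
) -> pd.DataFrame:
    """Cluster-vs-rest ROC markers for activity features.

    Per feature x cluster: AUC from the Mann-Whitney construction (ties count
    half) over defined scores, the fraction of cluster spots with a defined
    score, and the difference of group means on the supplied values (pass
    z-scaled activities to interpret ``min_diff`` on the intended scale).
    Rows are kept iff all three thresholds are met unless ``return_all``.
    Clusters with fewer than 3 spots are skipped with a warning.
    """
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) else np.asarray(clusters)
    if len(labels) != len(act.unit_ids):
        raise ValueError("cluster labels must align with activity units")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    rows = []
    for lab in uniq:
        in_c = labels == lab
        if in_c.sum() < 3:
            warnings.warn(f"cluster {lab} has fewer than 3 spots; skipped")
            continue
        for j, feat in enumerate(act.features):
            v = act.values[:, j]
            defined = ~np.isnan(v)
            pct = float(np.mean(defined[in_c]))
            g1 = v[in_c & defined]
            g2 = v[~in_c & defined]
            if g1.size == 0 or g2.size == 0:
                continue
            ranks = rankdata(np.concatenate([g1, g2]))
            r1 = ranks[: g1.size].sum()
            auc = (r1 - g1.size * (g1.size + 1) / 2) / (g1.size * g2.size)
            diff = float(g1.mean() - g2.mean())
            rows.append(
                {
                    "feature": str(feat),
                    "cluster": lab,
                    "auc": float(auc),
                    "pct_defined": pct,
                    "mean_diff": diff,
                    "marker": bool(auc >= min_auc and pct >= min_pct and diff >= min_diff),
                }
            )
    table = pd.DataFrame(rows, columns=["feature", "cluster", "auc", "pct_defined", "mean_diff", "marker"])
    if not return_all:
        table = table[table["marker"]].reset_index(drop=True)
    return table


def abundance_activity_correlation(
    props: AbundanceMatrix,
    act: ActivityMatrix,
    mode: str = "pearson",
):
    """Correlate cell-type proportions with pathway/TF activities per spot.

    ``pearson`` returns the full cell-type x feature cross-correlation matrix
    over shared spots with pairwise deletion of missing activities.  ``cca``
    returns canonical correlations (non-increasing, in [0, 1]) and loadings
    from the whitened cross-covariance SVD over complete cases.
    """
    shared = [s for s in props.spot_ids.astype(str) if s in set(act.unit_ids.astype(str))]
    if not shared:
        raise ValueError("no shared spots between proportions and activities")
    pi = {s: i for i, s in enumerate(props.spot_ids.astype(str))}
    ai = {s: i for i, s in enumerate(act.unit_ids.astype(str))}
    X = props.values[[pi[s] for s in shared]]
    Y = act.values[[ai[s] for s in shared]]

    if mode == "pearson":
        out = np.full((X.shape[1], Y.shape[1]), np.nan)
        for j in range(Y.shape[1]):
            ok = ~np.isnan(Y[:, j])
            if ok.sum() < 3:
                continue
            y = Y[ok, j]
            if np.std(y) == 0:
                warnings.warn(f"feature {act.features[j]!r} has zero variance")
                continue
            for i in range(X.shape[1]):
                x = X[ok, i]
                if np.std(x) == 0:
                    continue
                out[i, j] = float(np.corrcoef(x, y)[0, 1])
        return pd.DataFrame(
            out,
            index=props.cell_types.astype(str),
            columns=act.features.astype(str),
        )

    if mode == "cca":
        ok = ~np.isnan(Y).any(axis=1)
        X, Y = X[ok], Y[ok]
        n = X.shape[0]
        if n <= X.shape[1] + Y.shape[1]:
            raise ValueError("CCA needs more spots than total features")
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        Sxx = Xc.T @ Xc / (n - 1)
        Syy = Yc.T @ Yc / (n - 1)
        Sxy = Xc.T @ Yc / (n - 1)
        wx = _inv_sqrt(Sxx)
        wy = _inv_sqrt(Syy)
        u, s, vt = np.linalg.svd(wx @ Sxy @ wy)
        corrs = np.clip(s, 0.0, 1.0)
        return {
            "correlations": corrs,
            "x_loadings": wx @ u,
            "y_loadings": wy @ vt.T,
        }
    raise ValueError(f"unknown mode {mode!r}")


def _inv_sqrt(mat: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """Symmetric pseudo-inverse square root (drops near-null directions)."""
    vals, vecs = np.linalg.eigh(mat)
    tol = rcond * vals.max() if vals.size else 0.0
    inv = np.where(vals > tol, 1.0 / np.sqrt(np.maximum(vals, tol if tol > 0 else 1)), 0.0)
    return (vecs * inv) @ vecs.T
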