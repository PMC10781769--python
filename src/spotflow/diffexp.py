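"""Rank-based differential expression and hypergeometric overrepresentation.

Marker detection uses the two-sided Wilcoxon rank-sum test per gene per
group (vs rest), with exact enumeration of rank splits when both groups have
at most 8 observations and a tie-corrected normal approximation otherwise.
Fold-changes are log2 ratios of expm1-of-normalized group means with a small
pseudo-count.  ORA is the one-sided hypergeometric upper tail against an
explicit background universe.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .core_data import SpotDataset

__all__ = ["wilcoxon_markers", "ora", "exact_rank_sum_p"]

EPS = 1e-9
DEFAULT_EXCLUDE = ("RPL", "RPS", "MT-")
EXACT_MAX = 8


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p by full rank-split enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled (tied) ranks and
    doubles the smaller tail, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = rankdata(np.concatenate([x, y]))
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    total = 0
    le = 0
    ge = 0
    for comb in combinations(range(len(ranks)), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def _exact_pvalues(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided rank-sum p per gene (rows of ``values``)."""
    n1 = int(in_group.sum())
    n = values.shape[1]
    combs = np.array(list(combinations(range(n), n1)), dtype=int)
    pvals = np.empty(values.shape[0])
    order = np.concatenate([np.flatnonzero(in_group), np.flatnonzero(~in_group)])
    for g in range(values.shape[0]):
        ranks = rankdata(values[g, order])
        w_obs = ranks[:n1].sum()
        w_all = ranks[combs].sum(axis=1)
        le = np.count_nonzero(w_all <= w_obs + 1e-9)
        ge = np.count_nonzero(w_all >= w_obs - 1e-9)
        pvals[g] = min(1.0, 2.0 * min(le, ge) / len(w_all))
    return pvals


def _expression_frame(expr) -> pd.DataFrame:
    if isinstance(expr, SpotDataset):
        if expr.norm is None:
            raise ValueError("dataset has no normalized layer; run normalize() first")
        return pd.DataFrame(
            np.asarray(expr.norm),
            index=pd.Index(expr.gene_ids.astype(str)),
            columns=expr.spot_ids.astype(str),
        )
    if isinstance(expr, pd.DataFrame):
        return expr
    raise TypeError(f"unsupported expression container {type(expr).__name__}")


def wilcoxon_markers(
    expr,
    groups: Sequence,
    *,
    lfc_min: float = 0.25,
    positive_only: bool = True,
    exclude_patterns: Sequence[str] = DEFAULT_EXCLUDE,
    min_group_size: int = 3,
    return_all: bool = False,
) -> pd.DataFrame:
    """Per-group-vs-rest Wilcoxon rank-sum markers on a normalized layer.

    Returns one row per (gene, group) with the log2 fold-change of
    expm1-transformed group means (pseudo-count 1e-9), detection fractions,
    the two-sided rank-sum p (exact enumeration when both sides have <= 8
    observations) and the BH-adjusted p across genes within the group.
    Ribosomal/mitochondrial genes (prefixes in ``exclude_patterns``) are
    removed before testing.  Unless ``return_all``, only rows passing the
    fold-change filter are retained.
    """
    frame = _expression_frame(expr)
    groups = np.asarray(groups)
    if len(groups) != frame.shape[1]:
        raise ValueError("groups must align with expression columns")
    if exclude_patterns:
        keep = ~frame.index.str.startswith(tuple(exclude_patterns))
        frame = frame.loc[keep]
    uniq = [g for g in pd.unique(groups)]
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    x = frame.to_numpy(dtype=float)
    expm = np.expm1(x)

    tables = []
    for grp in uniq:
        in_g = groups == grp
        n1, n2 = int(in_g.sum()), int((~in_g).sum())
        if n1 < min_group_size or n2 < min_group_size:
            import warnings

            warnings.warn(f"group {grp!r} or its complement below size {min_group_size}; skipped")
            continue
        mean_in = expm[:, in_g].mean(axis=1)
        mean_out = expm[:, ~in_g].mean(axis=1)
        lfc = np.log2((mean_in + EPS) / (mean_out + EPS))
        pct_in = (x[:, in_g] > 0).mean(axis=1)
        pct_out = (x[:, ~in_g] > 0).mean(axis=1)
        if n1 <= EXACT_MAX and n2 <= EXACT_MAX:
            pvals = _exact_pvalues(x, in_g)
        else:
            _, pvals = mannwhitneyu(
                x[:, in_g], x[:, ~in_g], axis=1, alternative="two-sided", method="asymptotic"
            )
        padj = multipletests(pvals, method="fdr_bh")[1]
        tables.append(
            pd.DataFrame(
                {
                    "gene": frame.index,
                    "group": grp,
                    "log2fc": lfc,
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                    "p_value": pvals,
                    "p_adj": padj,
                }
            )
        )
    if not tables:
        raise ValueError("no group large enough to test")
    table = pd.concat(tables, ignore_index=True)
    if not return_all:
        if positive_only:
            table = table[table["log2fc"] >= lfc_min]
        else:
            table = table[np.abs(table["log2fc"]) >= lfc_min]
    table.attrs["filters"] = {
        "lfc_min": lfc_min,
        "positive_only": positive_only,
        "exclude_patterns": list(exclude_patterns),
    }
    return table.reset_index(drop=True)


def ora(
    query: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    background: Sequence[str],
    *,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of gene sets.

    Sets are intersected with the background; only sets with at least
    ``min_set_size`` background-present genes are tested.  p is the upper
    tail P[X >= k] for overlap k between the query (size n) and the set
    (size K) in a background of size N; BH adjustment is across tested sets.
    """
    background = set(map(str, background))
    query = set(map(str, query))
    if not query:
        raise ValueError("empty query gene list")
    if not query <= background:
        raise ValueError(
            f"query genes missing from background: {sorted(query - background)[:5]}"
        )
    N = len(background)
    n = len(query)
    rows = []
    for name in sorted(gene_sets):
        members = set(map(str, gene_sets[name])) & background
        K = len(members)
        if K < min_set_size:
            continue
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "background_size": N,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_set", "overlap", "set_size", "query_size", "background_size", "p_value"],
    )
    if len(table):
        table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table
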