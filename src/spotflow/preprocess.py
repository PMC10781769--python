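"""Spot QC, normalization, pseudo-bulk aggregation and NNLS deconvolution.

Normalization is log1p of median-library-scaled counts (log-CPM-median), a
documented stand-in for variance-stabilizing transforms: the downstream
statistics here (rank tests, z-scored signatures) are insensitive to the
flavor.  Deconvolution is per-spot non-negative least squares against
cell-type reference signatures — an explicitly simplified alternative to
hierarchical Bayesian deconvolution, adequate for proportion-level analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import nnls

from .core_data import AbundanceMatrix, SpotDataset

__all__ = [
    "QCThresholds",
    "PseudoBulk",
    "qc_filter",
    "normalize",
    "pseudobulk",
    "nnls_deconvolve",
]


@dataclass
class QCThresholds:
    """Spot-level QC rules.

    Spots are removed when total UMIs fall strictly below ``umi_min`` or
    strictly above ``umi_max``, or when the mitochondrial count fraction is
    strictly greater than ``mito_fraction_max`` (a fraction of exactly the
    threshold is retained).  Mitochondrial genes are identified by symbol
    prefix.
    """

    umi_min: int = 500
    umi_max: int = 45000
    mito_fraction_max: float = 0.5
    mito_gene_pattern: str = "MT-"

    def __post_init__(self) -> None:
        if not self.umi_min < self.umi_max:
            raise ValueError("umi_min must be < umi_max")
        if not 0.0 <= self.mito_fraction_max <= 1.0:
            raise ValueError("mito_fraction_max must be in [0, 1]")


def qc_filter(
    ds: SpotDataset, thr: QCThresholds | None = None
) -> tuple[SpotDataset, dict]:
    """Remove low/high-UMI and mitochondria-dominated spots.

    Returns the filtered dataset and a report listing every removed spot with
    its reasons (``umi_low``, ``umi_high``, ``mito_high``).
    """
    thr = thr or QCThresholds()
    totals = np.asarray(ds.counts.sum(axis=0)).ravel()
    mito_mask = np.array(
        [str(g).startswith(thr.mito_gene_pattern) for g in ds.gene_ids], dtype=bool
    )
    mito_counts = (
        np.asarray(ds.counts[mito_mask].sum(axis=0)).ravel()
        if mito_mask.any()
        else np.zeros_like(totals)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    reasons: dict[str, list[str]] = {}

    def flag(mask: np.ndarray, reason: str) -> None:
        for i in np.flatnonzero(mask):
            reasons.setdefault(str(ds.spot_ids[i]), []).append(reason)

    flag(totals < thr.umi_min, "umi_low")
    flag(totals > thr.umi_max, "umi_high")
    flag(mito_frac > thr.mito_fraction_max, "mito_high")

    keep = ~np.isin(ds.spot_ids.astype(str), list(reasons))
    if not keep.any():
        raise ValueError("empty dataset after QC: every spot failed a threshold")
    report = {
        "n_input": int(ds.n_spots),
        "n_kept": int(keep.sum()),
        "removed": {b: sorted(r) for b, r in sorted(reasons.items())},
        "thresholds": {
            "umi_min": thr.umi_min,
            "umi_max": thr.umi_max,
            "mito_fraction_max": thr.mito_fraction_max,
            "mito_gene_pattern": thr.mito_gene_pattern,
        },
    }
    return ds.subset_spots(keep), report


def normalize(ds: SpotDataset, method: str = "logcpm_median") -> SpotDataset:
    """Attach a normalized layer: ``log1p(count * m / spot_total)``.

    ``m`` is the median spot total, so the layer is scale-invariant per spot
    while staying on a count-like magnitude.
    """
    if method != "logcpm_median":
        raise ValueError(f"unknown normalization method {method!r}")
    totals = np.asarray(ds.counts.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        bad = ds.spot_ids[totals <= 0][:5]
        raise ValueError(f"zero-total spots cannot be normalized: {list(bad)}")
    m = float(np.median(totals))
    dense = np.asarray(ds.counts.todense(), dtype=float)
    ds.norm = np.log1p(dense * (m / totals))
    return ds


@dataclass
class PseudoBulk:
    """Counts summed over spot groups, with a counts-per-million layer."""

    group_ids: np.ndarray
    gene_ids: np.ndarray
    counts: np.ndarray  # genes x groups, raw sums
    cpm: np.ndarray  # genes x groups, before gene filtering
    kept_genes: np.ndarray  # genes with >= min_count raw counts in every group

    def to_frame(self, layer: str = "cpm", filtered: bool = True) -> pd.DataFrame:
        mat = self.cpm if layer == "cpm" else self.counts
        frame = pd.DataFrame(
            mat,
            index=pd.Index(self.gene_ids.astype(str), name="gene"),
            columns=self.group_ids.astype(str),
        )
        return frame.loc[self.kept_genes.astype(str)] if filtered else frame


def pseudobulk(
    ds_list: Sequence[SpotDataset],
    grouping: Mapping[str, str],
    *,
    min_count: int = 50,
) -> PseudoBulk:
    """Sum counts per group across datasets and compute CPM.

    ``grouping`` maps spot barcode -> group id; genes are kept only when their
    raw summed count is >= ``min_count`` in every group.
    """
    genes = ds_list[0].gene_ids
    for ds in ds_list[1:]:
        if not np.array_equal(ds.gene_ids, genes):
            raise ValueError("datasets must share an identical gene list")
    groups = sorted(set(grouping.values()))
    if not groups:
        raise ValueError("grouping assigns no spots")
    sums = np.zeros((len(genes), len(groups)))
    gidx = {g: i for i, g in enumerate(groups)}
    seen = {g: 0 for g in groups}
    for ds in ds_list:
        cols: dict[int, list[int]] = {}
        for i, b in enumerate(ds.spot_ids.astype(str)):
            if b in grouping:
                cols.setdefault(gidx[grouping[b]], []).append(i)
        for gi, idx in cols.items():
            sums[:, gi] += np.asarray(ds.counts[:, idx].sum(axis=1)).ravel()
            seen[groups[gi]] += len(idx)
    empty = [g for g, n in seen.items() if n == 0]
    if empty:
        raise ValueError(f"empty pseudo-bulk group(s): {empty}")
    totals = sums.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("a group has zero total counts")
    cpm = sums * (1e6 / totals)
    kept = genes[np.all(sums >= min_count, axis=1)]
    return PseudoBulk(
        group_ids=np.asarray(groups, dtype=object),
        gene_ids=genes,
        counts=sums,
        cpm=cpm,
        kept_genes=np.asarray(kept, dtype=object),
    )


def nnls_deconvolve(
    ds: SpotDataset, signatures: pd.DataFrame, *, min_shared_genes: int = 20
) -> AbundanceMatrix:
    """Per-spot cell-type proportions by non-negative least squares.

    Each spot's CPM-scaled expression is regressed on the cell-type signature
    columns with beta >= 0; proportions are beta / sum(beta).  Spots with no
    non-negative support are flagged unresolved and given uniform proportions
    so downstream permutation statistics stay well-defined.
    """
    if signatures.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    sig = signatures.to_numpy(dtype=float)
    if np.any(sig < 0) or np.any(sig.sum(axis=0) == 0):
        raise ValueError("signatures must be non-negative with no all-zero column")
    shared = [g for g in signatures.index if g in set(ds.gene_ids)]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"insufficient signature overlap: {len(shared)} shared genes (< {min_shared_genes})"
        )
    gidx = ds.gene_index(shared)
    G = signatures.loc[shared].to_numpy(dtype=float)
    Y = np.asarray(ds.counts[gidx].todense(), dtype=float)
    totals = Y.sum(axis=0)
    Y = Y * np.where(totals > 0, 1e6 / np.maximum(totals, 1), 0.0)

    n_types = G.shape[1]
    values = np.empty((ds.n_spots, n_types))
    unresolved = np.zeros(ds.n_spots, dtype=bool)
    for s in range(ds.n_spots):
        beta, _ = nnls(G, Y[:, s])
        tot = beta.sum()
        if tot <= 0:
            unresolved[s] = True
            values[s] = 1.0 / n_types
        else:
            values[s] = beta / tot
    return AbundanceMatrix(
        spot_ids=ds.spot_ids.copy(),
        cell_types=signatures.columns.to_numpy(dtype=object),
        values=values,
        mode="proportion",
        unresolved=unresolved,
    )
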