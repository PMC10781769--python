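"""Region-aware spatial statistics on the hexagonal spot lattice.

Implements the permutation enrichment/depletion of deconvolved cell types in
pathologist-annotated compartments, selection of tumor-surrounding spots,
stratification of tumor spots into peripheral / intermediary / central zones
by distance to the nearest non-tumor spot, and replicate-consistency scoring
of deconvolution results.

All distances are Euclidean on canonical coordinates (hexagonal
nearest-neighbor distance = 1), the unit in which the thresholds 2 and 2.5
cleanly split the first three hex rings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._utils import knn_graph, leiden_partition, zscore_columns
from .core_data import (
    AbundanceMatrix,
    AnnotationVocabulary,
    EnrichmentResult,
    SpotDataset,
)

__all__ = [
    "SpotDistances",
    "TumorZoning",
    "pairwise_spot_distances",
    "enrichment_score",
    "select_tumor_surrounding",
    "stratify_tumor",
    "replicate_consistency",
]

#: non-tumor spots within this canonical distance of a tumor spot "surround" it
SURROUND_RADIUS = 2.0
#: zone boundaries on distance-to-nearest-non-tumor: <2 peripheral,
#: [2, 2.5) intermediary, >=2.5 central (2.5 itself cannot occur on the lattice)
PERIPHERAL_MAX = 2.0
CENTRAL_MIN = 2.5


class SpotDistances:
    """Euclidean distances between spots on canonical coordinates.

    Backed by a KD-tree: supports radius queries and nearest-cross-set
    distances without materializing the full pairwise matrix.
    """

    def __init__(self, coords: np.ndarray):
        self.coords = np.asarray(coords, dtype=float)
        self._tree = cKDTree(self.coords)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def within(self, i: int, radius: float) -> np.ndarray:
        """Indices of spots within ``radius`` of spot ``i`` (including i)."""
        return np.asarray(sorted(self._tree.query_ball_point(self.coords[i], radius + 1e-9)), dtype=int)

    def min_distance_to(self, targets: np.ndarray) -> np.ndarray:
        """Per spot, distance to the nearest spot in ``targets`` (index array)."""
        tree = cKDTree(self.coords[np.asarray(targets, dtype=int)])
        d, _ = tree.query(self.coords, k=1)
        return d

    def full_matrix(self) -> np.ndarray:
        from scipy.spatial.distance import cdist

        return cdist(self.coords, self.coords)


def pairwise_spot_distances(ds: SpotDataset) -> SpotDistances:
    return SpotDistances(ds.canon_coords)


def enrichment_score(
    props: AbundanceMatrix,
    annotations: np.ndarray,
    vocab: AnnotationVocabulary | None = None,
    *,
    n_perm: int = 10000,
    seed: int = 0,
    exclude_unresolved: bool = True,
) -> EnrichmentResult:
    """Permutation enrichment/depletion of cell types per tissue category.

    Whole proportion rows (spot profiles) are shuffled across spot positions
    ``n_perm`` times; for each permutation the difference between the observed
    and permuted mean proportion per category is recorded, and the score is
    the mean of these differences divided by their sample standard deviation
    (positive = enrichment, negative = depletion).  Pairs whose permutation SD
    is zero — including categories with no spots — are flagged degenerate and
    scored 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    annotations = np.asarray(annotations, dtype=object)
    if len(annotations) != len(props.spot_ids):
        raise ValueError("annotations must cover all spots in the abundance matrix")
    values = props.values
    keep = np.ones(len(values), dtype=bool)
    if exclude_unresolved and props.unresolved is not None:
        keep &= ~props.unresolved
    values = values[keep]
    annotations = annotations[keep]

    categories = (
        np.asarray(vocab.categories, dtype=object)
        if vocab is not None
        else np.unique(annotations.astype(str)).astype(object)
    )
    n_spots, n_types = values.shape
    n_cats = len(categories)
    cat_idx = [np.flatnonzero(annotations.astype(str) == str(c)) for c in categories]

    observed = np.full((n_types, n_cats), np.nan)
    for c, idx in enumerate(cat_idx):
        if idx.size:
            observed[:, c] = values[idx].mean(axis=0)

    rng = np.random.default_rng(seed)
    sum_d = np.zeros((n_types, n_cats))
    sum_d2 = np.zeros((n_types, n_cats))
    chunk = max(1, int(2e7 // max(n_spots * n_types, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # each row of `order` is one random permutation of spot rows
        order = np.argsort(rng.random((b, n_spots)), axis=1)
        for c, idx in enumerate(cat_idx):
            if idx.size:
                perm_means = values[order[:, idx]].mean(axis=1)  # (b, n_types)
                d = observed[:, c][None, :] - perm_means
                sum_d[:, c] += d.sum(axis=0)
                sum_d2[:, c] += (d * d).sum(axis=0)
        done += b

    mean_d = sum_d / n_perm
    if n_perm > 1:
        var_d = np.maximum(sum_d2 - n_perm * mean_d**2, 0.0) / (n_perm - 1)
    else:
        var_d = np.zeros_like(mean_d)
    sd_d = np.sqrt(var_d)

    degenerate = np.zeros((n_types, n_cats), dtype=bool)
    scores = np.zeros((n_types, n_cats))
    for c, idx in enumerate(cat_idx):
        if not idx.size:
            degenerate[:, c] = True
            continue
        zero_sd = sd_d[:, c] <= 1e-15
        degenerate[zero_sd, c] = True
        ok = ~zero_sd
        scores[ok, c] = mean_d[ok, c] / sd_d[ok, c]
    return EnrichmentResult(
        cell_types=props.cell_types.copy(),
        categories=categories,
        scores=scores,
        observed_means=observed,
        degenerate=degenerate,
        n_permutations=int(n_perm),
        seed=int(seed),
    )


def _tumor_mask(ds: SpotDataset, vocab: AnnotationVocabulary) -> np.ndarray:
    if ds.annotations is None:
        raise ValueError("dataset has no annotations")
    return vocab.is_tumor(ds.annotations)


def select_tumor_surrounding(
    ds: SpotDataset,
    vocab: AnnotationVocabulary,
    *,
    max_dist: float = SURROUND_RADIUS,
) -> np.ndarray:
    """Barcodes of non-tumor spots within ``max_dist`` of any tumor spot.

    Spots annotated as tumor are discarded even when within range.
    """
    tumor = _tumor_mask(ds, vocab)
    if not tumor.any():
        raise ValueError("no tumor spots in dataset")
    dist = pairwise_spot_distances(ds).min_distance_to(np.flatnonzero(tumor))
    sel = (~tumor) & (dist <= max_dist + 1e-9)
    return ds.spot_ids[sel].copy()


@dataclass
class TumorZoning:
    """Tumor spots stratified by distance to the nearest non-tumor spot."""

    spot_ids: np.ndarray  # tumor spots only
    zones: np.ndarray  # 'peripheral' | 'intermediary' | 'central'
    distances: np.ndarray  # per tumor spot, to nearest non-tumor spot
    surrounding: np.ndarray  # barcodes of tumor-surrounding (non-tumor) spots

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"zone": self.zones.astype(str), "distance": self.distances},
            index=pd.Index(self.spot_ids.astype(str), name="spot_id"),
        )


def stratify_tumor(ds: SpotDataset, vocab: AnnotationVocabulary) -> TumorZoning:
    """Partition tumor spots into peripheral / intermediary / central zones.

    Per tumor spot, ``d`` = distance to the nearest non-tumor spot:
    ``d < 2`` peripheral (in contact with the boundary), ``2 <= d < 2.5``
    intermediary, ``d >= 2.5`` central.  The intervals are disjoint and
    exhaustive; no hex-lattice distance equals 2.5.
    """
    tumor = _tumor_mask(ds, vocab)
    if not tumor.any():
        raise ValueError("no tumor spots in dataset")
    if tumor.all():
        raise ValueError("all spots are tumor annotated; no reference compartment")
    dists = pairwise_spot_distances(ds).min_distance_to(np.flatnonzero(~tumor))
    d = dists[tumor]
    zones = np.where(
        d < PERIPHERAL_MAX - 1e-9,
        "peripheral",
        np.where(d < CENTRAL_MIN - 1e-9, "intermediary", "central"),
    ).astype(object)
    return TumorZoning(
        spot_ids=ds.spot_ids[tumor].copy(),
        zones=zones,
        distances=d,
        surrounding=select_tumor_surrounding(ds, vocab),
    )


def replicate_consistency(
    props_a: AbundanceMatrix,
    props_b: AbundanceMatrix,
    ds_a: SpotDataset,
    ds_b: SpotDataset,
    *,
    resolutions: np.ndarray | None = None,
    n_pcs: int = 20,
    k: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson consistency of deconvolution between technical replicates.

    Spots of both replicates are jointly embedded (per-sample gene z-scaling
    of the normalized layer, shared PCA, k-NN graph) and clustered at each
    resolution in the grid (default 1.0..2.0 by 0.1).  Per cluster and cell
    type, the mean estimated abundance is computed separately per replicate
    and Pearson r over these (cluster x cell type) means is reported per
    resolution.  A resolution yielding a single cluster is flagged and r is
    computed over cell types only.
    """
    if resolutions is None:
        resolutions = np.round(np.arange(1.0, 2.0 + 1e-9, 0.1), 10)
    if not np.array_equal(props_a.cell_types, props_b.cell_types):
        raise ValueError("replicates must share the cell-type set")
    for ds in (ds_a, ds_b):
        if ds.norm is None:
            raise ValueError("normalize datasets before replicate_consistency")
    if not np.array_equal(ds_a.gene_ids, ds_b.gene_ids):
        raise ValueError("replicates must share the gene list")

    xa = zscore_columns(np.asarray(ds_a.norm).T)  # spots x genes
    xb = zscore_columns(np.asarray(ds_b.norm).T)
    x = np.vstack([xa, xb])
    sample = np.array([0] * xa.shape[0] + [1] * xb.shape[0])
    va = props_a.values
    vb = props_b.values

    graph = knn_graph(x, n_pcs=n_pcs, k=k)
    rows = []
    for resolution in resolutions:
        labels = leiden_partition(graph, resolution=float(resolution), seed=seed)
        n_clusters = len(np.unique(labels))
        means_a, means_b = [], []
        for lab in np.unique(labels):
            in_a = (labels == lab) & (sample == 0)
            in_b = (labels == lab) & (sample == 1)
            if in_a.any() and in_b.any():
                means_a.append(va[in_a[: len(va)]].mean(axis=0))
                means_b.append(vb[in_b[len(va):]].mean(axis=0))
        flagged = n_clusters <= 1 or len(means_a) <= 1
        a = np.concatenate(means_a) if means_a else np.array([])
        b = np.concatenate(means_b) if means_b else np.array([])
        if a.size >= 2 and np.std(a) > 0 and np.std(b) > 0:
            r = float(np.corrcoef(a, b)[0, 1])
        else:
            r = np.nan
        rows.append(
            {
                "resolution": float(resolution),
                "pearson_r": r,
                "n_clusters": int(n_clusters),
                "flagged": bool(flagged),
            }
        )
    return pd.DataFrame(rows)
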