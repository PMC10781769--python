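"""Synthetic Visium-like datasets with known ground truth.

Emulates the study conditions downstream stages are tested against: a
hexagonal spot lattice with annotated tissue regions (tumor disk, stromal
annulus, epithelium / lamina propria background, immune aggregates),
per-region Dirichlet cell-type proportions, negative-binomial counts mixed
from cell-type signatures, technical replicate pairs, and planted ligand->TF
spatial couplings that the communication module should recover.

All generators are pure functions of (parameters, seed); ground truth is
attached to the dataset and can be serialized next to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_data import (
    AbundanceMatrix,
    PriorKnowledge,
    SpotDataset,
    canonical_coords,
    save_prior,
    write_spot_dataset,
    write_table,
)

__all__ = [
    "LayoutParams",
    "TissueLayout",
    "GroundTruth",
    "make_layout",
    "simulate_proportions",
    "simulate_counts",
    "simulate_replicate",
    "plant_ligand_tf_effects",
    "make_toy_prior",
    "make_signatures",
    "neighborhood_mean",
    "write_ground_truth",
]

#: activity -> expression tilt strength used when planting ligand->TF effects
DEFAULT_TAU = 0.3


@dataclass
class LayoutParams:
    """Geometry of the synthetic tissue section (canonical distance units)."""

    tumor_radius: float = 5.0
    stroma_width: float = 2.0
    epithelium_width: float = 3.0
    n_immune_aggregates: int = 0
    aggregate_radius: float = 1.5


@dataclass
class TissueLayout:
    rows: int
    cols: int
    array_coords: np.ndarray  # (n_spots, 2) int, row+col even
    categories: np.ndarray  # per-spot tissue category
    params: LayoutParams
    seed: int

    @property
    def n_spots(self) -> int:
        return len(self.categories)

    @property
    def canon_coords(self) -> np.ndarray:
        return canonical_coords(self.array_coords)

    @property
    def spot_ids(self) -> np.ndarray:
        return np.array(
            [f"spot{r:03d}x{c:03d}" for r, c in self.array_coords], dtype=object
        )


@dataclass
class GroundTruth:
    """Everything needed to re-derive or audit a synthetic dataset."""

    proportions: AbundanceMatrix
    signature_means: pd.DataFrame  # genes x cell types
    library_size: np.ndarray  # per spot
    dispersion: np.ndarray  # per gene; np.inf means Poisson
    seed: int
    planted_effects: list = field(default_factory=list)  # (ligand, tf, beta)
    true_activity: pd.DataFrame | None = None  # spots x TFs latent activities


def make_layout(rows: int, cols: int, params: LayoutParams | None = None, *, seed: int = 0) -> TissueLayout:
    """Hexagonal lattice with a central tumor disk and surrounding compartments.

    Spots occupy array positions with even row+col parity.  A spot is tumor if
    its canonical distance to the lattice center is <= ``tumor_radius``
    (radius <= 0 plants no tumor), stroma within the annulus of width
    ``stroma_width`` beyond it, then epithelium, then lamina propria.  Immune
    aggregates are small balls seeded at random non-tumor spots.
    """
    if rows < 8 or cols < 8:
        raise ValueError("grid must be at least 8x8")
    params = params or LayoutParams()
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    keep = (rr + cc) % 2 == 0
    coords = np.column_stack([rr[keep], cc[keep]]).astype(int)
    xy = canonical_coords(coords)
    extent = min(xy[:, 0].max() - xy[:, 0].min(), xy[:, 1].max() - xy[:, 1].min())
    if params.tumor_radius > extent:
        raise ValueError(
            f"tumor_radius {params.tumor_radius} exceeds the lattice extent ({extent:.2f})"
        )
    center = xy.mean(axis=0)
    # snap to the nearest actual spot so distances are lattice-honest
    center = xy[np.argmin(np.linalg.norm(xy - center, axis=1))]
    d = np.linalg.norm(xy - center, axis=1)

    cats = np.full(len(coords), "lamina_propria", dtype=object)
    epi_edge = params.tumor_radius + params.stroma_width + params.epithelium_width
    cats[d <= epi_edge] = "epithelium"
    cats[d <= params.tumor_radius + params.stroma_width] = "stroma"
    if params.tumor_radius > 0:
        cats[d <= params.tumor_radius] = "tumor"

    rng = np.random.default_rng(seed)
    if params.n_immune_aggregates > 0:
        eligible = np.flatnonzero(~np.isin(cats, ["tumor"]))
        if eligible.size:
            seeds = rng.choice(eligible, size=min(params.n_immune_aggregates, eligible.size), replace=False)
            for s in seeds:
                ball = np.linalg.norm(xy - xy[s], axis=1) <= params.aggregate_radius
                cats[ball & (cats != "tumor")] = "immune_aggregate"
    return TissueLayout(rows=rows, cols=cols, array_coords=coords, categories=cats, params=params, seed=seed)


def simulate_proportions(
    layout: TissueLayout,
    cell_types: Sequence[str],
    region_dirichlet: Mapping[str, Sequence[float]],
    *,
    seed: int = 0,
) -> AbundanceMatrix:
    """Per-spot cell-type proportions drawn from the spot's region Dirichlet."""
    cell_types = np.asarray(list(cell_types), dtype=object)
    for cat in np.unique(layout.categories):
        if cat not in region_dirichlet:
            raise ValueError(f"no Dirichlet concentration vector for category {cat!r}")
        alpha = np.asarray(region_dirichlet[cat], dtype=float)
        if alpha.shape != (len(cell_types),) or np.any(alpha <= 0):
            raise ValueError(f"concentration vector for {cat!r} must be positive, length {len(cell_types)}")
    rng = np.random.default_rng(seed)
    values = np.empty((layout.n_spots, len(cell_types)))
    # draw region-by-region in a fixed category order for determinism
    for cat in np.unique(layout.categories):
        idx = np.flatnonzero(layout.categories == cat)
        values[idx] = rng.dirichlet(np.asarray(region_dirichlet[cat], dtype=float), size=idx.size)
    values /= values.sum(axis=1, keepdims=True)
    return AbundanceMatrix(spot_ids=layout.spot_ids, cell_types=cell_types, values=values, mode="proportion")


def make_signatures(
    genes: Sequence[str],
    cell_types: Sequence[str],
    *,
    seed: int = 0,
    base_rate: float = 1.0,
    n_markers_per_type: int = 40,
    marker_fold: float = 8.0,
) -> pd.DataFrame:
    """Gene x cell-type expected-expression signatures.

    Each cell type gets a disjoint block of marker genes expressed
    ``marker_fold`` times above the lognormal background, so mixtures are
    identifiable by non-negative least squares.
    """
    genes = list(genes)
    cell_types = list(cell_types)
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=np.log(base_rate), sigma=0.6, size=(len(genes), len(cell_types)))
    order = rng.permutation(len(genes))
    per = min(n_markers_per_type, len(genes) // max(len(cell_types), 1))
    for k in range(len(cell_types)):
        block = order[k * per : (k + 1) * per]
        base[block, k] *= marker_fold
    return pd.DataFrame(base, index=pd.Index(genes, name="gene"), columns=cell_types)


def _draw_counts(mu: np.ndarray, dispersion: np.ndarray, seed: int) -> np.ndarray:
    """NB(mean=mu, size=dispersion) counts; infinite dispersion means Poisson."""
    rng = np.random.default_rng(seed)
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float)[:, None], mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    finite = np.isfinite(disp)
    if np.any(~finite):
        out[~finite] = rng.poisson(mu[~finite])
    if np.any(finite):
        d = disp[finite]
        m = mu[finite]
        p = d / (d + np.maximum(m, 1e-300))
        out[finite] = rng.negative_binomial(d, p)
    out[mu == 0] = 0
    return out


def _base_means(
    props: AbundanceMatrix, signatures: pd.DataFrame, library_size: np.ndarray
) -> np.ndarray:
    """Expected gene x spot counts: mixture means rescaled to the library size."""
    sig = signatures.to_numpy(dtype=float)  # genes x types
    mix = sig @ props.values.T  # genes x spots
    totals = mix.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("a spot has zero expected expression; check signatures/proportions")
    return mix * (library_size / totals)


def simulate_counts(
    props: AbundanceMatrix,
    signatures: pd.DataFrame,
    layout: TissueLayout,
    *,
    library_size: float | np.ndarray = 5000.0,
    dispersion: float | np.ndarray = 10.0,
    seed: int = 0,
    sample_id: str = "synthetic",
) -> SpotDataset:
    """Negative-binomial counts for every spot, ground truth attached.

    Per spot ``s`` and gene ``g`` the count is NB with mean
    ``library_size_s * sum_k props[s,k] * sig[g,k] / (spot total)`` and the
    gene's dispersion (``inf`` = Poisson limit).
    """
    sig = signatures.to_numpy(dtype=float)
    if np.any(sig < 0):
        raise ValueError("signatures must be non-negative")
    if np.any(sig.sum(axis=0) == 0):
        raise ValueError("signature column is all zero")
    lib = np.broadcast_to(np.asarray(library_size, dtype=float), (props.values.shape[0],)).copy()
    if np.any(lib <= 0):
        raise ValueError("library_size must be positive")
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (len(signatures),)).copy()
    mu = _base_means(props, signatures, lib)
    counts = _draw_counts(mu, disp, seed)
    truth = GroundTruth(
        proportions=props,
        signature_means=signatures,
        library_size=lib,
        dispersion=disp,
        seed=seed,
    )
    return SpotDataset(
        sample_id=sample_id,
        spot_ids=props.spot_ids,
        array_coords=layout.array_coords,
        counts=sp.csr_matrix(counts),
        gene_ids=signatures.index.to_numpy(dtype=object),
        annotations=layout.categories.copy(),
        ground_truth=truth,
    )


def simulate_replicate(
    ds: SpotDataset, *, noise: float = 1.0, seed: int = 0, sample_id: str | None = None
) -> SpotDataset:
    """Technical replicate: same layout and truth, counts re-drawn.

    ``noise`` inflates overdispersion (dispersion is divided by it); with
    ``noise == 1`` and the original seed the counts are reproduced exactly.
    """
    truth: GroundTruth = ds.ground_truth
    if truth is None:
        raise ValueError("dataset has no attached ground truth")
    if noise <= 0:
        raise ValueError("noise factor must be positive")
    disp = truth.dispersion / noise
    mu = _base_means(truth.proportions, truth.signature_means, truth.library_size)
    counts = _draw_counts(mu, disp, seed)
    new_truth = GroundTruth(
        proportions=truth.proportions,
        signature_means=truth.signature_means,
        library_size=truth.library_size,
        dispersion=disp,
        seed=seed,
        planted_effects=list(truth.planted_effects),
        true_activity=truth.true_activity,
    )
    return SpotDataset(
        sample_id=sample_id or f"{ds.sample_id}_rep",
        spot_ids=ds.spot_ids.copy(),
        array_coords=ds.array_coords.copy(),
        counts=sp.csr_matrix(counts),
        gene_ids=ds.gene_ids.copy(),
        annotations=None if ds.annotations is None else ds.annotations.copy(),
        replicate_of=ds.sample_id,
        ground_truth=new_truth,
    )


def neighborhood_mean(
    coords: np.ndarray, values: np.ndarray, radius: float = 2.0
) -> np.ndarray:
    """Mean of ``values`` over all spots within canonical distance <= radius.

    The ball includes the spot itself; the same definition is used when
    planting ligand->TF effects and when building the juxtaview predictors,
    so generative and inferential neighborhoods match by construction.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    pairs = tree.query_ball_tree(tree, r=radius + 1e-9)
    vals = np.asarray(values, dtype=float)
    out = np.empty((len(pairs),) + vals.shape[1:], dtype=float)
    for i, nbrs in enumerate(pairs):
        out[i] = vals[nbrs].mean(axis=0)
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def plant_ligand_tf_effects(
    ds: SpotDataset,
    prior: PriorKnowledge,
    effects: Sequence[tuple[str, str, float]],
    *,
    noise_sd: float = 1.0,
    tau: float = DEFAULT_TAU,
    seed: int = 0,
) -> SpotDataset:
    """Plant spatial ligand->TF couplings into a synthetic dataset.

    For every TF ``t`` a latent activity
    ``a_t(s) = sum_l beta_{l,t} * z(neighborhood ligand expression at s) + eps``
    (eps ~ N(0, noise_sd^2)) is drawn; counts of the TF's regulon targets are
    then re-drawn with their means tilted by ``exp(mode * a_t(s) * tau)``.
    The true activity table is stored in the ground truth.
    """
    truth: GroundTruth = ds.ground_truth
    if truth is None:
        raise ValueError("dataset has no attached ground truth")
    tf_names = sorted({t for _, t, _ in effects})
    for lig, tf, _ in effects:
        if lig not in prior.ligands:
            raise ValueError(f"unknown ligand {lig!r}")
        if tf not in prior.regulons:
            raise ValueError(f"unknown TF {tf!r}")

    from .preprocess import normalize

    norm_ds = normalize(ds)
    coords = ds.canon_coords
    gene_pos = {g: i for i, g in enumerate(ds.gene_ids)}

    lig_names = sorted({l for l, _, _ in effects})
    lig_z = {}
    for lig in lig_names:
        if lig not in gene_pos:
            raise ValueError(f"ligand {lig!r} not in dataset genes")
        expr = norm_ds.norm[gene_pos[lig]]
        lig_z[lig] = _zscore(neighborhood_mean(coords, expr, radius=2.0))

    rng = np.random.default_rng(seed)
    activity = np.zeros((ds.n_spots, len(tf_names)))
    for j, tf in enumerate(tf_names):
        a = np.zeros(ds.n_spots)
        for lig, t, beta in effects:
            if t == tf:
                a += beta * lig_z[lig]
        if noise_sd > 0:
            a += rng.normal(0.0, noise_sd, size=ds.n_spots)
        activity[:, j] = a

    # tilt regulon-target means and redraw those genes' counts
    mu = _base_means(truth.proportions, truth.signature_means, truth.library_size)
    tilt = np.ones_like(mu)
    affected = set()
    for j, tf in enumerate(tf_names):
        for g, mode, _grade in prior.regulons[tf]:
            if g in gene_pos:
                gi = gene_pos[g]
                tilt[gi] *= np.exp(mode * activity[:, j] * tau)
                affected.add(gi)
    counts = np.asarray(ds.counts.todense())
    if affected:
        rows = np.array(sorted(affected), dtype=int)
        redraw_seed = int(rng.integers(0, 2**31 - 1))
        counts[rows] = _draw_counts(mu[rows] * tilt[rows], truth.dispersion[rows], redraw_seed)

    true_act = pd.DataFrame(
        activity, index=pd.Index(ds.spot_ids.astype(str), name="spot_id"), columns=tf_names
    )
    new_truth = GroundTruth(
        proportions=truth.proportions,
        signature_means=truth.signature_means,
        library_size=truth.library_size,
        dispersion=truth.dispersion,
        seed=truth.seed,
        planted_effects=list(effects),
        true_activity=true_act,
    )
    return SpotDataset(
        sample_id=ds.sample_id,
        spot_ids=ds.spot_ids.copy(),
        array_coords=ds.array_coords.copy(),
        counts=sp.csr_matrix(counts),
        gene_ids=ds.gene_ids.copy(),
        annotations=None if ds.annotations is None else ds.annotations.copy(),
        replicate_of=ds.replicate_of,
        ground_truth=new_truth,
    )


def make_toy_prior(
    n_tfs: int = 5,
    n_ligands: int = 10,
    n_pathways: int = 5,
    n_genes: int = 800,
    *,
    seed: int = 0,
    regulon_size: tuple[int, int] = (8, 15),
    pathway_size: int = 60,
) -> PriorKnowledge:
    """Small self-consistent prior-knowledge bundle.

    Regulons have >= 8 graded (A-C) signed targets drawn from a generic gene
    pool disjoint from ligands/receptors/TFs; every ligand links to 1-3
    receptors; the signed PPI graph contains a receptor->TF path of length
    <= 4 for every TF; pathway signatures carry weights and responsiveness
    ranks.
    """
    if min(n_tfs, n_ligands, n_pathways, n_genes) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    ligands = [f"LIG{i:02d}" for i in range(n_ligands)]
    n_receptors = max(2, n_ligands)
    receptors = [f"REC{i:02d}" for i in range(n_receptors)]
    tfs = [f"TF{i:02d}" for i in range(n_tfs)]
    intermediaries = [f"SIG{i:02d}" for i in range(max(4, 2 * n_tfs))]

    lr_pairs = []
    for lig in ligands:
        k = int(rng.integers(1, 4))
        for r in rng.choice(n_receptors, size=min(k, n_receptors), replace=False):
            lr_pairs.append((lig, receptors[r]))
    lr_pairs = sorted(set(lr_pairs))

    grades = np.array(["A", "B", "C"], dtype=object)
    regulons: dict[str, tuple] = {}
    lo, hi = regulon_size
    for tf in tfs:
        size = int(rng.integers(lo, hi + 1))
        targets = rng.choice(n_genes, size=size, replace=False)
        modes = rng.choice([1, -1], size=size)
        grd = rng.choice(grades, size=size)
        regulons[tf] = tuple((genes[t], int(m), str(g)) for t, m, g in zip(targets, modes, grd))

    # PPI: guaranteed receptor->TF paths (length 1-4) plus random extra edges
    edges: set[tuple[str, str, int]] = set()
    for tf in tfs:
        rec = receptors[int(rng.integers(0, n_receptors))]
        hops = int(rng.integers(0, 4))  # intermediaries on the path
        path = [rec] + [intermediaries[int(rng.integers(0, len(intermediaries)))] for _ in range(hops)] + [tf]
        for a, b in zip(path[:-1], path[1:]):
            if a != b:
                edges.add((a, b, int(rng.choice([1, -1]))))
    node_pool = receptors + intermediaries + tfs
    for _ in range(3 * len(node_pool)):
        a, b = rng.choice(len(node_pool), size=2, replace=False)
        edges.add((node_pool[a], node_pool[b], int(rng.choice([1, -1]))))
    # keep a single sign per directed edge (drop contradictory duplicates)
    dedup: dict[tuple[str, str], int] = {}
    for s, t, sign in sorted(edges):
        dedup.setdefault((s, t), sign)
    ppi_edges = tuple((s, t, sign) for (s, t), sign in sorted(dedup.items()))

    pathways: dict[str, tuple] = {}
    for p in range(n_pathways):
        size = min(pathway_size, n_genes)
        members = rng.choice(n_genes, size=size, replace=False)
        weights = rng.normal(0.0, 1.0, size=size)
        ranks = rng.permutation(size) + 1
        pathways[f"PW{p:02d}"] = tuple(
            (genes[g], float(w), int(r)) for g, w, r in zip(members, weights, ranks)
        )

    prior = PriorKnowledge(
        ligands=frozenset(ligands),
        lr_pairs=tuple(lr_pairs),
        ppi_edges=ppi_edges,
        regulons=regulons,
        pathway_weights=pathways,
    )
    prior.validate()
    return prior


def prior_gene_pool(prior: PriorKnowledge) -> list[str]:
    """Every gene symbol the prior mentions, sorted (for building signatures)."""
    pool: set[str] = set(prior.ligands)
    for l, r in prior.lr_pairs:
        pool.update((l, r))
    for s, t, _ in prior.ppi_edges:
        pool.update((s, t))
    for tf, targets in prior.regulons.items():
        pool.add(tf)
        pool.update(g for g, _, _ in targets)
    for genes in prior.pathway_weights.values():
        pool.update(g for g, _, _ in genes)
    return sorted(pool)


def write_ground_truth(ds: SpotDataset, dir_path: str | Path) -> None:
    """Serialize the dataset's ground truth next to it (TSV + JSON)."""
    truth: GroundTruth = ds.ground_truth
    if truth is None:
        raise ValueError("dataset has no attached ground truth")
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    write_table(truth.proportions, dir_path / "true_proportions.tsv")
    truth.signature_means.to_csv(dir_path / "signature_means.tsv", sep="\t")
    if truth.true_activity is not None:
        truth.true_activity.to_csv(dir_path / "true_activity.tsv", sep="\t")
    pd.DataFrame(truth.planted_effects, columns=["ligand", "tf", "beta"]).to_csv(
        dir_path / "planted_effects.tsv", sep="\t", index=False
    )
    params = {
        "seed": int(truth.seed),
        "library_size": truth.library_size.tolist(),
        "dispersion": truth.dispersion.tolist(),
    }
    (dir_path / "truth_params.json").write_text(json.dumps(params))


def write_synthetic_sample(ds: SpotDataset, dir_path: str | Path) -> None:
    """Space-Ranger-like directory plus the mandatory truth files."""
    dir_path = Path(dir_path)
    write_spot_dataset(ds, dir_path)
    write_ground_truth(ds, dir_path / "truth")
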