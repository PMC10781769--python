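"""Data model and I/O for spot-level spatial expression data.

The central container is :class:`SpotDataset`: one tissue section measured on a
Visium-style hexagonal lattice, holding a gene x spot count matrix, array and
canonical spot coordinates, and optional pathologist annotations.  Canonical
coordinates place hexagonal nearest neighbors at distance exactly 1
(``x = col / 2``, ``y = row * sqrt(3) / 2``), which is the unit all distance
thresholds in this package refer to.

All matrices are keyed by spot barcode, never by positional index, so that
subsetting and QC filtering are safe.
"""

from __future__ import annotations

import gzip
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpotDataset",
    "AnnotationVocabulary",
    "AbundanceMatrix",
    "ActivityMatrix",
    "EnrichmentResult",
    "PriorKnowledge",
    "SpotDataError",
    "ValidationError",
    "DEFAULT_VOCABULARY",
    "canonical_coords",
    "read_spot_dataset",
    "write_table",
    "read_table",
    "validate_dataset",
    "load_prior",
    "save_prior",
]

SQRT3_HALF = math.sqrt(3.0) / 2.0

#: Regulon confidence grades, most to least reliable.
CONFIDENCE_GRADES = ("A", "B", "C", "D", "E")


class SpotDataError(Exception):
    """Base error for malformed spot data."""


class ValidationError(SpotDataError):
    """Raised when a dataset or table violates a structural invariant."""


def canonical_coords(array_coords: np.ndarray) -> np.ndarray:
    """Map integer Visium array coordinates ``(row, col)`` to canonical x/y.

    On the Visium lattice spots occupy positions with constant row+col parity;
    ``x = col / 2`` and ``y = row * sqrt(3) / 2`` makes all six hexagonal
    neighbors lie at Euclidean distance exactly 1.
    """
    arr = np.asarray(array_coords, dtype=float)
    out = np.empty_like(arr)
    out[:, 0] = arr[:, 1] / 2.0
    out[:, 1] = arr[:, 0] * SQRT3_HALF
    return out


@dataclass
class AnnotationVocabulary:
    """Controlled vocabulary of pathologist tissue categories.

    ``tumor_categories`` are the categories treated as "tumor annotated" by the
    zoning and surrounding-spot operations; ``tme_categories`` are the
    stromal / microenvironment categories.
    """

    categories: tuple[str, ...]
    tumor_categories: frozenset[str]
    tme_categories: frozenset[str]

    def __post_init__(self) -> None:
        self.categories = tuple(self.categories)
        self.tumor_categories = frozenset(self.tumor_categories)
        self.tme_categories = frozenset(self.tme_categories)
        if not self.categories:
            raise ValidationError("vocabulary has no categories")
        cats = set(self.categories)
        if len(cats) != len(self.categories):
            raise ValidationError("duplicate categories in vocabulary")
        for name, subset in (("tumor", self.tumor_categories), ("tme", self.tme_categories)):
            if not subset:
                raise ValidationError(f"{name}_categories is empty")
            if not subset <= cats:
                raise ValidationError(
                    f"{name}_categories {sorted(subset - cats)} not in vocabulary"
                )

    def is_tumor(self, annotations: Sequence[str]) -> np.ndarray:
        return np.isin(np.asarray(annotations, dtype=object), list(self.tumor_categories))


#: Default vocabulary with the tissue categories named in the study figures.
DEFAULT_VOCABULARY = AnnotationVocabulary(
    categories=(
        "tumor",
        "tumor&stroma_IC med to high",
        "stroma_fibroblastic_IC med to high",
        "non-neoplastic epithelium",
        "lamina propria",
        "IC aggregate",
        "mixed",
    ),
    tumor_categories=frozenset({"tumor", "tumor&stroma_IC med to high"}),
    tme_categories=frozenset(
        {"stroma_fibroblastic_IC med to high", "lamina propria", "IC aggregate"}
    ),
)

#: Compact vocabulary used by the synthetic generator.
SYNTH_VOCABULARY = AnnotationVocabulary(
    categories=("tumor", "stroma", "epithelium", "lamina_propria", "immune_aggregate"),
    tumor_categories=frozenset({"tumor"}),
    tme_categories=frozenset({"stroma", "lamina_propria", "immune_aggregate"}),
)


@dataclass
class SpotDataset:
    """One tissue section: counts, coordinates and annotations per spot.

    ``counts`` is gene x spot (CSR, non-negative integers); ``norm`` is an
    optional normalized gene x spot layer.  ``annotations`` is an optional
    per-spot tissue category aligned with ``spot_ids``.  ``ground_truth`` holds
    simulation truth when the dataset is synthetic.
    """

    sample_id: str
    spot_ids: np.ndarray
    array_coords: np.ndarray
    counts: sp.csr_matrix
    gene_ids: np.ndarray
    norm: np.ndarray | None = None
    annotations: np.ndarray | None = None
    replicate_of: str | None = None
    ground_truth: object | None = None

    def __post_init__(self) -> None:
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.array_coords = np.asarray(self.array_coords, dtype=int)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        if self.annotations is not None:
            self.annotations = np.asarray(self.annotations, dtype=object)
            if len(self.annotations) != self.n_spots:
                raise ValidationError("annotations length does not match spot count")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def canon_coords(self) -> np.ndarray:
        """Per-spot (x, y) with hexagonal nearest-neighbor distance 1."""
        return canonical_coords(self.array_coords)

    def spot_index(self, barcodes: Iterable[str]) -> np.ndarray:
        lookup = {b: i for i, b in enumerate(self.spot_ids)}
        try:
            return np.array([lookup[b] for b in barcodes], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown barcode {exc.args[0]!r}") from None

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_spots(self, mask_or_index: np.ndarray) -> "SpotDataset":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpotDataset(
            sample_id=self.sample_id,
            spot_ids=self.spot_ids[idx],
            array_coords=self.array_coords[idx],
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            norm=None if self.norm is None else self.norm[:, idx],
            annotations=None if self.annotations is None else self.annotations[idx],
            replicate_of=self.replicate_of,
            ground_truth=self.ground_truth,
        )

    def to_anndata(self):
        """Spots x genes AnnData view (requires anndata installed)."""
        import anndata

        ad = anndata.AnnData(
            X=self.counts.T.tocsr(),
            obs=pd.DataFrame(
                {
                    "array_row": self.array_coords[:, 0],
                    "array_col": self.array_coords[:, 1],
                },
                index=pd.Index(self.spot_ids.astype(str), name="barcode"),
            ),
            var=pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene")),
        )
        ad.obsm["spatial"] = self.canon_coords
        if self.annotations is not None:
            ad.obs["category"] = pd.Categorical(self.annotations.astype(str))
        return ad


@dataclass
class AbundanceMatrix:
    """Per-spot cell-type abundances (deconvolution output or ground truth)."""

    spot_ids: np.ndarray
    cell_types: np.ndarray
    values: np.ndarray
    mode: str = "proportion"
    unresolved: np.ndarray | None = None  # spots where deconvolution had no support

    def __post_init__(self) -> None:
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.spot_ids), len(self.cell_types)):
            raise ValidationError("abundance values shape mismatch")
        if self.mode not in ("proportion", "absolute"):
            raise ValidationError(f"unknown abundance mode {self.mode!r}")

    def validate(self) -> None:
        if self.values.size and np.min(self.values) < 0:
            raise ValidationError("negative abundance values")
        if self.mode == "proportion" and self.values.size:
            sums = self.values.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
            if bad.size:
                raise ValidationError(
                    f"proportion rows not summing to 1: spots {list(self.spot_ids[bad[:5]])}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.spot_ids.astype(str), name="spot_id"),
            columns=self.cell_types.astype(str),
        )


@dataclass
class ActivityMatrix:
    """Per-unit (spot or pseudo-bulk group) pathway/TF/module scores.

    Undefined scores are stored as NaN, never as 0; ``coverage`` reports the
    number of units with a defined score per feature.
    """

    unit_ids: np.ndarray
    features: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids, dtype=object)
        self.features = np.asarray(self.features, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.unit_ids), len(self.features)):
            raise ValidationError("activity values shape mismatch")

    @property
    def coverage(self) -> np.ndarray:
        return np.sum(~np.isnan(self.values), axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.unit_ids.astype(str), name="unit_id"),
            columns=self.features.astype(str),
        )


@dataclass
class EnrichmentResult:
    """Signed permutation enrichment scores per (cell type, tissue category)."""

    cell_types: np.ndarray
    categories: np.ndarray
    scores: np.ndarray
    observed_means: np.ndarray
    degenerate: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        self.categories = np.asarray(self.categories, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.cell_types.astype(str), name="cell_type"),
            columns=self.categories.astype(str),
        )


@dataclass
class PriorKnowledge:
    """Prior-knowledge bundle: ligands, LR pairs, signed PPIs, regulons, pathways.

    regulons: TF -> list of (target gene, mode in {+1,-1}, grade in A..E).
    pathway_weights: pathway -> list of (gene, weight, responsiveness rank).
    """

    ligands: frozenset[str]
    lr_pairs: tuple[tuple[str, str], ...]
    ppi_edges: tuple[tuple[str, str, int], ...]
    regulons: Mapping[str, tuple[tuple[str, int, str], ...]]
    pathway_weights: Mapping[str, tuple[tuple[str, float, int], ...]]

    def __post_init__(self) -> None:
        self.ligands = frozenset(self.ligands)
        self.lr_pairs = tuple((str(l), str(r)) for l, r in self.lr_pairs)
        self.ppi_edges = tuple((str(s), str(t), int(g)) for s, t, g in self.ppi_edges)
        self.regulons = {
            tf: tuple((str(g), int(m), str(c)) for g, m, c in targets)
            for tf, targets in self.regulons.items()
        }
        self.pathway_weights = {
            pw: tuple((str(g), float(w), int(r)) for g, w, r in genes)
            for pw, genes in self.pathway_weights.items()
        }

    def validate(self) -> None:
        for lig, rec in self.lr_pairs:
            if lig == rec:
                raise ValidationError(f"self-loop ligand-receptor pair {lig!r}")
        for s, t, sign in self.ppi_edges:
            if sign not in (1, -1):
                raise ValidationError(f"PPI edge ({s},{t}) has sign {sign}")
        for tf, targets in self.regulons.items():
            genes = [g for g, _, _ in targets]
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate targets in regulon {tf}")
            for g, mode, grade in targets:
                if mode not in (1, -1):
                    raise ValidationError(f"regulon {tf} target {g} has mode {mode}")
                if grade not in CONFIDENCE_GRADES:
                    raise ValidationError(f"regulon {tf} target {g} has grade {grade!r}")
        for pw, genes in self.pathway_weights.items():
            names = [g for g, _, _ in genes]
            if len(set(names)) != len(names):
                raise ValidationError(f"duplicate genes in pathway {pw}")

    @property
    def receptors(self) -> frozenset[str]:
        return frozenset(r for _, r in self.lr_pairs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _find(dir_path: Path, *names: str) -> Path:
    for name in names:
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(
        f"missing required file in {dir_path}: looked for {', '.join(names)}"
    )


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_spot_dataset(
    dir_path: str | Path,
    sample_id: str | None = None,
) -> SpotDataset:
    """Load a Space-Ranger-like directory into a :class:`SpotDataset`.

    Expects ``matrix.mtx(.gz)`` (genes x spots, MatrixMarket), ``features.tsv(.gz)``,
    ``barcodes.tsv(.gz)``, a positions CSV with columns
    ``barcode,in_tissue,array_row,array_col`` and an optional ``annotations.csv``
    with columns ``barcode,category``.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FileNotFoundError(f"no such directory: {dir_path}")
    mtx_path = _find(dir_path, "matrix.mtx", "matrix.mtx.gz")
    feat_path = _find(dir_path, "features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz")
    bc_path = _find(dir_path, "barcodes.tsv", "barcodes.tsv.gz")
    pos_path = _find(
        dir_path, "positions.csv", "tissue_positions.csv", "tissue_positions_list.csv"
    )

    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    genes = np.array([line.split("\t")[0] for line in _read_lines(feat_path)], dtype=object)
    barcodes = np.array(_read_lines(bc_path), dtype=object)
    if counts.shape != (len(genes), len(barcodes)):
        raise ValidationError(
            f"matrix shape {counts.shape} does not match {len(genes)} features "
            f"x {len(barcodes)} barcodes"
        )

    # Deduplicate gene symbols: first occurrence wins.
    _, first_idx = np.unique(genes, return_index=True)
    if len(first_idx) != len(genes):
        keep = np.sort(first_idx)
        dropped = len(genes) - len(keep)
        warnings.warn(f"{dropped} duplicate gene symbol rows dropped (first occurrence kept)")
        genes = genes[keep]
        counts = counts[keep]

    pos = pd.read_csv(pos_path, dtype={"barcode": str})
    required = {"barcode", "in_tissue", "array_row", "array_col"}
    if not required <= set(pos.columns):
        raise ValidationError(
            f"positions file {pos_path.name} missing columns {sorted(required - set(pos.columns))}"
        )
    pos = pos[pos["in_tissue"].astype(int) == 1]
    missing = sorted(set(pos["barcode"]) - set(barcodes))
    if missing:
        raise ValidationError(
            f"barcodes in positions but absent from matrix: {missing[:10]}"
        )
    pos = pos.set_index("barcode").loc[list(barcodes)]
    array_coords = pos[["array_row", "array_col"]].to_numpy(dtype=int)

    annotations = None
    ann_path = dir_path / "annotations.csv"
    if ann_path.exists():
        ann = pd.read_csv(ann_path, dtype=str)
        if not {"barcode", "category"} <= set(ann.columns):
            raise ValidationError("annotations.csv must have columns barcode,category")
        ann = ann.set_index("barcode")["category"]
        unknown = sorted(set(ann.index) - set(barcodes))
        if unknown:
            raise ValidationError(
                f"annotated barcodes absent from matrix: {unknown[:10]}"
            )
        annotations = ann.reindex(list(barcodes)).to_numpy(dtype=object)

    return SpotDataset(
        sample_id=sample_id or dir_path.name,
        spot_ids=barcodes,
        array_coords=array_coords,
        counts=counts,
        gene_ids=genes,
        annotations=annotations,
    )


def write_spot_dataset(ds: SpotDataset, dir_path: str | Path) -> None:
    """Write a dataset back out as a Space-Ranger-like plain-text directory."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), sp.coo_matrix(ds.counts))
    (dir_path / "features.tsv").write_text("\n".join(ds.gene_ids.astype(str)) + "\n")
    (dir_path / "barcodes.tsv").write_text("\n".join(ds.spot_ids.astype(str)) + "\n")
    pd.DataFrame(
        {
            "barcode": ds.spot_ids.astype(str),
            "in_tissue": 1,
            "array_row": ds.array_coords[:, 0],
            "array_col": ds.array_coords[:, 1],
        }
    ).to_csv(dir_path / "positions.csv", index=False)
    if ds.annotations is not None:
        pd.DataFrame(
            {"barcode": ds.spot_ids.astype(str), "category": ds.annotations.astype(str)}
        ).to_csv(dir_path / "annotations.csv", index=False)


def write_table(obj, path: str | Path) -> Path:
    """Write an AbundanceMatrix / ActivityMatrix / EnrichmentResult as TSV.

    Metadata that cannot live in the table (mode, seed, degenerate flags,
    method parameters) is written to a ``<path>.meta.json`` sidecar so that
    :func:`read_table` round-trips the object exactly.
    """
    path = Path(path)
    meta: dict = {}
    if isinstance(obj, AbundanceMatrix):
        obj.validate()
        frame = obj.to_frame()
        meta = {"kind": "abundance", "mode": obj.mode}
        if obj.unresolved is not None:
            meta["unresolved"] = [str(s) for s in obj.spot_ids[obj.unresolved]]
    elif isinstance(obj, ActivityMatrix):
        frame = obj.to_frame()
        meta = {"kind": "activity", "meta": _jsonable(obj.meta)}
    elif isinstance(obj, EnrichmentResult):
        frame = obj.to_frame()
        meta = {
            "kind": "enrichment",
            "n_permutations": obj.n_permutations,
            "seed": obj.seed,
            "degenerate": obj.degenerate.tolist(),
            "observed_means": np.asarray(obj.observed_means, dtype=float).tolist(),
        }
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
    frame.to_csv(path, sep="\t")
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_table(path: str | Path):
    """Inverse of :func:`write_table`; dispatches on the JSON sidecar."""
    path = Path(path)
    sidecar = path.with_name(path.name + ".meta.json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    kind = meta["kind"]
    if kind == "abundance":
        unresolved = None
        if "unresolved" in meta:
            unresolved = np.isin(frame.index.to_numpy(dtype=object), meta["unresolved"])
        return AbundanceMatrix(
            spot_ids=frame.index.to_numpy(dtype=object),
            cell_types=frame.columns.to_numpy(dtype=object),
            values=frame.to_numpy(dtype=float),
            mode=meta["mode"],
            unresolved=unresolved,
        )
    if kind == "activity":
        return ActivityMatrix(
            unit_ids=frame.index.to_numpy(dtype=object),
            features=frame.columns.to_numpy(dtype=object),
            values=frame.to_numpy(dtype=float),
            meta=meta.get("meta", {}),
        )
    if kind == "enrichment":
        return EnrichmentResult(
            cell_types=frame.index.to_numpy(dtype=object),
            categories=frame.columns.to_numpy(dtype=object),
            scores=frame.to_numpy(dtype=float),
            observed_means=np.array(meta["observed_means"], dtype=float),
            degenerate=np.array(meta["degenerate"], dtype=bool),
            n_permutations=int(meta["n_permutations"]),
            seed=int(meta["seed"]),
        )
    raise ValueError(f"unknown table kind {kind!r}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_dataset(ds: SpotDataset, vocab: AnnotationVocabulary) -> list[dict]:
    """Report-based validation; returns an empty list iff the dataset is valid.

    Each violation is a dict with a ``kind`` key (``duplicate_spot_id``,
    ``unknown_category``, ``negative_count``, ``coordinate_parity``) plus
    identifying detail.
    """
    report: list[dict] = []
    ids, counts_per = np.unique(ds.spot_ids, return_counts=True)
    for b in ids[counts_per > 1]:
        report.append({"kind": "duplicate_spot_id", "spot_id": str(b)})
    if ds.counts.nnz and ds.counts.data.min() < 0:
        neg_cols = np.unique(sp.coo_matrix(ds.counts).col[sp.coo_matrix(ds.counts).data < 0])
        for c in neg_cols[:20]:
            report.append({"kind": "negative_count", "spot_id": str(ds.spot_ids[c])})
    if ds.annotations is not None:
        known = set(vocab.categories)
        for i, cat in enumerate(ds.annotations):
            if cat is not None and not (isinstance(cat, float) and np.isnan(cat)):
                if str(cat) not in known:
                    report.append(
                        {
                            "kind": "unknown_category",
                            "spot_id": str(ds.spot_ids[i]),
                            "category": str(cat),
                        }
                    )
    if ds.n_spots:
        parity = (ds.array_coords[:, 0] + ds.array_coords[:, 1]) % 2
        if len(np.unique(parity)) > 1:
            report.append({"kind": "coordinate_parity", "detail": "mixed row+col parity"})
    return report


# ---------------------------------------------------------------------------
# Prior-knowledge bundle persistence (plain TSVs)
# ---------------------------------------------------------------------------


def save_prior(prior: PriorKnowledge, dir_path: str | Path) -> None:
    prior.validate()
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"ligand": sorted(prior.ligands)}).to_csv(
        dir_path / "ligands.tsv", sep="\t", index=False
    )
    pd.DataFrame(prior.lr_pairs, columns=["ligand", "receptor"]).to_csv(
        dir_path / "lr_pairs.tsv", sep="\t", index=False
    )
    pd.DataFrame(prior.ppi_edges, columns=["source", "target", "sign"]).to_csv(
        dir_path / "ppi_edges.tsv", sep="\t", index=False
    )
    reg_rows = [
        (tf, g, m, c) for tf, targets in sorted(prior.regulons.items()) for g, m, c in targets
    ]
    pd.DataFrame(reg_rows, columns=["tf", "target", "mode", "grade"]).to_csv(
        dir_path / "regulons.tsv", sep="\t", index=False
    )
    pw_rows = [
        (pw, g, w, r)
        for pw, genes in sorted(prior.pathway_weights.items())
        for g, w, r in genes
    ]
    pd.DataFrame(pw_rows, columns=["pathway", "gene", "weight", "rank"]).to_csv(
        dir_path / "pathway_weights.tsv", sep="\t", index=False
    )


def load_prior(dir_path: str | Path) -> PriorKnowledge:
    dir_path = Path(dir_path)
    lig = pd.read_csv(_find(dir_path, "ligands.tsv"), sep="\t")
    lr = pd.read_csv(_find(dir_path, "lr_pairs.tsv"), sep="\t")
    ppi = pd.read_csv(_find(dir_path, "ppi_edges.tsv"), sep="\t")
    reg = pd.read_csv(_find(dir_path, "regulons.tsv"), sep="\t")
    pw = pd.read_csv(_find(dir_path, "pathway_weights.tsv"), sep="\t")
    regulons: dict[str, list] = {}
    for row in reg.itertuples(index=False):
        regulons.setdefault(row.tf, []).append((row.target, int(row.mode), row.grade))
    pathways: dict[str, list] = {}
    for row in pw.itertuples(index=False):
        pathways.setdefault(row.pathway, []).append((row.gene, float(row.weight), int(row.rank)))
    prior = PriorKnowledge(
        ligands=frozenset(lig["ligand"].astype(str)),
        lr_pairs=tuple(zip(lr["ligand"].astype(str), lr["receptor"].astype(str))),
        ppi_edges=tuple(
            zip(ppi["source"].astype(str), ppi["target"].astype(str), ppi["sign"].astype(int))
        ),
        regulons={tf: tuple(t) for tf, t in regulons.items()},
        pathway_weights={p: tuple(g) for p, g in pathways.items()},
    )
    prior.validate()
    return prior
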