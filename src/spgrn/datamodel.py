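"""Core in-memory containers shared by every pipeline stage.

The pipeline operates on a sparse gene x unit count matrix (a *unit* is a
cell in the single-cell reference or a spot on the spatial array), a spot
geometry with its derived neighbor graph, and a handful of small relational
tables (gene positions, ligand-receptor database, TF/target priors,
per-spot cell-type weights). Everything is plain numpy / scipy.sparse /
pandas; gene symbols are the join key throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

log = logging.getLogger("spgrn")

__all__ = [
    "ExpressionMatrix",
    "SpotGeometry",
    "GenePositions",
    "LRDatabase",
    "PriorTables",
    "CellTypeWeights",
]


@dataclass
class ExpressionMatrix:
    """Sparse non-negative integer counts, genes x units.

    ``normalized`` (optional) is a dense log-scale matrix of identical
    shape, filled in by :func:`spgrn.preprocess.normalize_log1p`.
    """

    genes: np.ndarray
    units: np.ndarray
    counts: sp.csr_matrix
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.units = np.asarray(self.units, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.genes), len(self.units)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.genes)} genes, {len(self.units)} units)"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        if len(set(self.units)) != len(self.units):
            raise ValueError("unit identifiers must be unique")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.counts.shape:
                raise ValueError("normalized must match counts shape")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def gene_index(self, symbols) -> np.ndarray:
        """Positions of ``symbols`` in the gene axis; raises on misses."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [s for s in symbols if s not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([lookup[s] for s in symbols], dtype=int)

    def unit_index(self, ids) -> np.ndarray:
        lookup = {u: i for i, u in enumerate(self.units)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"units absent from matrix: {missing}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def subset_units(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            genes=self.genes.copy(),
            units=self.units[idx],
            counts=self.counts[:, idx],
            normalized=None if self.normalized is None else self.normalized[:, idx],
        )

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            genes=self.genes[idx],
            units=self.units.copy(),
            counts=self.counts[idx, :],
            normalized=None if self.normalized is None else self.normalized[idx, :],
        )

    def totals(self) -> np.ndarray:
        """Total counts per unit (library sizes)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def require_normalized(self) -> np.ndarray:
        if self.normalized is None:
            raise ValueError("matrix has no normalized layer; run normalize_log1p")
        return self.normalized


@dataclass
class SpotGeometry:
    """Spot coordinates (spot-pitch units) plus the derived neighbor graph.

    ``neighbors`` is a symmetric boolean adjacency (CSR, no self loops)
    over all spots, built by connecting pairs whose Euclidean distance is
    at most ``pitch_factor`` times the minimal positive pairwise distance
    among in-tissue spots: one hexagonal ring at the default 1.3.
    """

    spot_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    in_tissue: np.ndarray
    neighbors: sp.csr_matrix

    def __post_init__(self) -> None:
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
        n = len(self.spot_ids)
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot barcodes")
        if self.neighbors.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if (self.neighbors != self.neighbors.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if self.neighbors.diagonal().any():
            raise ValueError("adjacency must have no self-loops")

    @classmethod
    def from_coords(
        cls,
        spot_ids,
        x,
        y,
        in_tissue=None,
        pitch_factor: float = 1.3,
    ) -> "SpotGeometry":
        spot_ids = np.asarray(spot_ids, dtype=object)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(spot_ids)
        if in_tissue is None:
            in_tissue = np.ones(n, dtype=bool)
        in_tissue = np.asarray(in_tissue, dtype=bool)
        if not in_tissue.any():
            raise ValueError("need at least one in-tissue spot")
        pts = np.column_stack([x, y])
        tissue_pts = pts[in_tissue]
        if len(tissue_pts) == 1:
            adj = sp.csr_matrix((n, n), dtype=bool)
            return cls(spot_ids, x, y, in_tissue, adj)
        tree = cKDTree(tissue_pts)
        # minimal positive pairwise distance among in-tissue spots
        d, _ = tree.query(tissue_pts, k=2)
        positive = d[:, 1][d[:, 1] > 0]
        if len(positive) == 0:
            raise ValueError("all in-tissue spots are coincident")
        pitch = positive.min()
        pairs = tree.query_pairs(pitch_factor * pitch, output_type="ndarray")
        tissue_idx = np.flatnonzero(in_tissue)
        rows = tissue_idx[pairs[:, 0]] if len(pairs) else np.array([], dtype=int)
        cols = tissue_idx[pairs[:, 1]] if len(pairs) else np.array([], dtype=int)
        adj = sp.coo_matrix(
            (np.ones(2 * len(rows), dtype=bool),
             (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
            shape=(n, n),
        ).tocsr()
        return cls(spot_ids, x, y, in_tissue, adj)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def degree(self) -> np.ndarray:
        return np.asarray(self.neighbors.sum(axis=1)).ravel().astype(int)


@dataclass
class GenePositions:
    """Gene symbol -> (chromosome, 1-based start); at most one row per gene."""

    table: pd.DataFrame  # columns: gene, chrom, start

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "start"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"gene position table needs columns {sorted(required)}")
        if self.table["gene"].duplicated().any():
            dups = self.table.loc[self.table["gene"].duplicated(), "gene"].tolist()
            log.warning("duplicate gene positions resolved by first occurrence: %s", dups[:5])
            self.table = self.table.drop_duplicates("gene", keep="first")
        if (self.table["start"] < 1).any():
            raise ValueError("start coordinates must be >= 1")
        self.table = self.table.reset_index(drop=True)

    def ordered_genes(self, universe) -> list[str]:
        """Genes of ``universe`` with known positions, (chrom, start) order."""
        have = self.table[self.table["gene"].isin(set(universe))]
        ordered = have.sort_values(["chrom", "start"], kind="mergesort")
        return ordered["gene"].tolist()

    def chrom_of(self) -> dict[str, str]:
        return dict(zip(self.table["gene"], self.table["chrom"]))


@dataclass
class LRDatabase:
    """Ligand-receptor pairs; any table in this shape is accepted."""

    pairs: pd.DataFrame  # columns: ligand, receptor[, pathway]

    def __post_init__(self) -> None:
        if not {"ligand", "receptor"}.issubset(self.pairs.columns):
            raise ValueError("LR database needs 'ligand' and 'receptor' columns")
        self.pairs = self.pairs.drop_duplicates(["ligand", "receptor"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_tuples(self) -> list[tuple[str, str]]:
        return list(zip(self.pairs["ligand"], self.pairs["receptor"]))


@dataclass
class PriorTables:
    """TF->target prior (motif-prior surrogate) and optional receptor->TF prior."""

    tf_target: pd.DataFrame  # columns: tf, target
    receptor_tf: pd.DataFrame | None = None  # columns: receptor, tf

    def __post_init__(self) -> None:
        if not {"tf", "target"}.issubset(self.tf_target.columns):
            raise ValueError("tf_target prior needs 'tf' and 'target' columns")
        self.tf_target = self.tf_target.drop_duplicates(["tf", "target"]).reset_index(drop=True)
        if self.receptor_tf is not None:
            if not {"receptor", "tf"}.issubset(self.receptor_tf.columns):
                raise ValueError("receptor_tf prior needs 'receptor' and 'tf' columns")
            self.receptor_tf = self.receptor_tf.drop_duplicates(
                ["receptor", "tf"]
            ).reset_index(drop=True)

    def tf_target_set(self) -> set[tuple[str, str]]:
        return set(zip(self.tf_target["tf"], self.tf_target["target"]))

    def receptor_tf_set(self) -> set[tuple[str, str]] | None:
        if self.receptor_tf is None:
            return None
        return set(zip(self.receptor_tf["receptor"], self.receptor_tf["tf"]))


@dataclass
class CellTypeWeights:
    """Per-spot non-negative cell-type weights summing to 1, plus argmax label."""

    spot_ids: np.ndarray
    cell_types: list[str] = field(default_factory=list)
    weights: np.ndarray = None  # spots x types
    labels: np.ndarray = None
    margins: np.ndarray = None

    def __post_init__(self) -> None:
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.spot_ids), len(self.cell_types)):
            raise ValueError("weights shape must be (n_spots, n_types)")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        sums = self.weights.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("weights per spot must sum to 1")
        if self.labels is None:
            best = np.argmax(self.weights, axis=1)
            self.labels = np.array([self.cell_types[i] for i in best], dtype=object)
        if self.margins is None:
            srt = np.sort(self.weights, axis=1)
            self.margins = srt[:, -1] - (srt[:, -2] if self.weights.shape[1] > 1 else 0.0)

    def weight_of(self, cell_type: str) -> np.ndarray:
        return self.weights[:, self.cell_types.index(cell_type)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.weights, columns=self.cell_types)
        df.insert(0, "spot", self.spot_ids)
        df["label"] = self.labels
        df["margin"] = self.margins
        return df
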