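"""Readers and writers for every external format the pipeline touches.

Formats: CellRanger-style MatrixMarket triplets (matrix.mtx + genes.tsv +
barcodes.tsv), tissue-positions CSV, headered TSVs for the LR database and
TF/target priors, and the layered-network edge TSV / GraphML export.
Readers fail loudly on malformed input and never silently drop rows.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datamodel import (
    ExpressionMatrix,
    GenePositions,
    LRDatabase,
    PriorTables,
    SpotGeometry,
)

log = logging.getLogger("spgrn")

POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "px_row", "px_col"]


class FormatError(ValueError):
    """Malformed input file."""


def read_matrix_market(directory, mtx="matrix.mtx", genes="genes.tsv", barcodes="barcodes.tsv") -> ExpressionMatrix:
    """Read a CellRanger triplet directory into an :class:`ExpressionMatrix`.

    ``genes.tsv``/``barcodes.tsv`` are one identifier per line (first
    column used if tab-separated). The matrix is genes x units.
    """
    d = Path(directory)
    mtx_path, genes_path, bc_path = d / mtx, d / genes, d / barcodes
    for p in (mtx_path, genes_path, bc_path):
        if not p.exists():
            raise FormatError(f"missing file: {p}")
    gene_list = _read_first_column(genes_path)
    bc_list = _read_first_column(bc_path)
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(gene_list), len(bc_list)):
        raise FormatError(
            f"{mtx_path}: declared shape {mat.shape} does not match "
            f"{len(gene_list)} genes x {len(bc_list)} barcodes"
        )
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{mtx_path}: non-integer count entries")
    counts = sp.csr_matrix((np.round(mat.data).astype(np.int64), (mat.row, mat.col)), shape=mat.shape)
    return ExpressionMatrix(genes=np.array(gene_list, dtype=object),
                            units=np.array(bc_list, dtype=object),
                            counts=counts)


def write_matrix_market(m: ExpressionMatrix, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(m.counts), field="integer")
    (d / "genes.tsv").write_text("".join(f"{g}\n" for g in m.genes))
    (d / "barcodes.tsv").write_text("".join(f"{u}\n" for u in m.units))


def _read_first_column(path: Path) -> list[str]:
    out = []
    for line in path.read_text().splitlines():
        if line.strip():
            out.append(line.split("\t")[0].strip())
    return out


def read_spot_positions(path, pitch_factor: float = 1.3) -> SpotGeometry:
    """Read a tissue-positions CSV and build the neighbor graph.

    Columns (with or without header): barcode, in_tissue, array_row,
    array_col, px_row, px_col. The pixel columns carry the geometry (on
    Visium arrays the array row/col indices are not Euclidean); they are
    rescaled so one spot pitch is one unit. Spots within
    ``pitch_factor`` pitches become neighbors: at the default 1.3 this
    captures one hex ring (ring two sits at 1.73 pitches) and the four
    rook neighbors of a square grid (diagonals sit at 1.41).
    """
    path = Path(path)
    first = path.read_text().splitlines()
    if not first:
        raise FormatError(f"{path}: empty file")
    has_header = "barcode" in first[0].lower()
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 6:
        raise FormatError(f"{path}: expected 6 columns {POSITION_COLUMNS}")
    df = df.iloc[:, :6]
    df.columns = POSITION_COLUMNS
    if df["barcode"].duplicated().any():
        dups = df.loc[df["barcode"].duplicated(), "barcode"].tolist()
        raise FormatError(f"{path}: duplicate barcodes {dups[:5]}")
    in_tissue = df["in_tissue"].astype(int).astype(bool).to_numpy()
    if not in_tissue.any():
        raise FormatError(f"{path}: no in-tissue spots")
    x = df["px_col"].astype(float).to_numpy()
    y = df["px_row"].astype(float).to_numpy()
    geom = SpotGeometry.from_coords(
        df["barcode"].to_numpy(dtype=object), x, y, in_tissue, pitch_factor=pitch_factor
    )
    # rescale coordinates to spot-pitch units
    tissue = geom.in_tissue
    if tissue.sum() > 1:
        pts = np.column_stack([geom.x[tissue], geom.y[tissue]])
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(pts, k=2)
        positive = d[:, 1][d[:, 1] > 0]
        if len(positive):
            pitch = positive.min()
            geom.x = geom.x / pitch
            geom.y = geom.y / pitch
    return geom


def write_spot_positions(geom: SpotGeometry, path, pitch_px: float = 100.0) -> None:
    """Write tissue-positions CSV; coordinates scaled to ``pitch_px`` px/pitch."""
    df = pd.DataFrame(
        {
            "barcode": geom.spot_ids,
            "in_tissue": geom.in_tissue.astype(int),
            "array_row": np.round(geom.y).astype(int),
            "array_col": np.round(geom.x).astype(int),
            "px_row": geom.y * pitch_px,
            "px_col": geom.x * pitch_px,
        }
    )
    df.to_csv(path, index=False)


def _read_tsv_require(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for c in df.columns:
        df[c] = df[c].str.strip()
    return df


def read_table_priors(lr_path, tf_target_path, receptor_tf_path=None) -> tuple[LRDatabase, PriorTables]:
    """Read the LR database and TF/target (+ optional receptor/TF) priors.

    All are headered TSVs; rows are deduplicated and symbols
    whitespace-trimmed with case preserved. A missing receptor->TF table
    makes downstream receptor linking fall back to correlation only.
    """
    lr = LRDatabase(_read_tsv_require(lr_path, ["ligand", "receptor"]))
    tf_target = _read_tsv_require(tf_target_path, ["tf", "target"])
    receptor_tf = None
    if receptor_tf_path is not None and os.path.exists(str(receptor_tf_path)):
        receptor_tf = _read_tsv_require(receptor_tf_path, ["receptor", "tf"])
    return lr, PriorTables(tf_target=tf_target, receptor_tf=receptor_tf)


def read_gene_positions(path) -> GenePositions:
    df = _read_tsv_require(path, ["gene", "chrom", "start"])
    df["start"] = df["start"].astype(int)
    return GenePositions(df)


def write_gene_positions(pos: GenePositions, path) -> None:
    pos.table.to_csv(path, sep="\t", index=False)


EDGE_COLUMNS = [
    "source", "target", "edge_type", "sender", "receiver",
    "score", "p_adj", "in_N1", "in_N2", "in_N3", "in_N4",
]


def write_network(net, out_prefix) -> list[str]:
    """Write a layered network: one edge TSV plus one GraphML per layer.

    The TSV has one row per unique typed edge (LR, RT, TT) with its layer
    flags; re-reading it reconstructs identical edge sets.
    """
    out_prefix = str(out_prefix)
    parent = Path(out_prefix).parent
    if parent and not parent.exists():
        parent.mkdir(parents=True, exist_ok=True)
    edges = net.edge_table()
    tsv_path = f"{out_prefix}_edges.tsv"
    edges.to_csv(tsv_path, sep="\t", index=False)
    written = [tsv_path]
    for layer in (1, 2, 3, 4):
        sub = edges[edges[f"in_N{layer}"]]
        g = nx.DiGraph()
        for _, row in sub.iterrows():
            g.add_edge(
                row["source"], row["target"],
                edge_type=row["edge_type"], sender=str(row["sender"]),
                receiver=str(row["receiver"]), score=float(row["score"]),
            )
        p = f"{out_prefix}_N{layer}.graphml"
        nx.write_graphml(g, p)
        written.append(p)
    return written


def read_network_edges(tsv_path) -> pd.DataFrame:
    df = pd.read_csv(tsv_path, sep="\t")
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{tsv_path}: missing column(s) {missing}")
    for c in ("in_N1", "in_N2", "in_N3", "in_N4"):
        df[c] = df[c].astype(bool)
    return df
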