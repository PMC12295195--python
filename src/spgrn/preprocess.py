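"""QC filtering, normalization, module-score projection and DEG testing.

QC thresholds follow the common droplet-data defaults: cells are dropped
at >20% mitochondrial content, <200 or >60,000 UMIs, or <200 detected
genes; spots need >=200 detected genes, and genes must be seen in >=3
surviving spots with >=10 total counts. Normalization is library-size
scaling to 10,000 followed by ln(1+x). Cell-type abundance is projected
onto spots by binned-control module scores, clipped at zero and
renormalized into proportions. Differential expression is a two-sided
Wilcoxon rank-sum (normal approximation with tie correction) with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .datamodel import CellTypeWeights, ExpressionMatrix

log = logging.getLogger("spgrn")

__all__ = [
    "QCThresholds",
    "filter_cells",
    "filter_spots",
    "normalize_log1p",
    "module_score",
    "celltype_weights",
    "wilcoxon_deg",
]


@dataclass(frozen=True)
class QCThresholds:
    mito_max_frac: float = 0.20
    umi_min: int = 200
    umi_max: int = 60000
    genes_min_per_cell: int = 200
    genes_min_per_spot: int = 200
    min_spots_per_gene: int = 3
    min_counts_per_gene: int = 10

    def __post_init__(self) -> None:
        if self.umi_min >= self.umi_max:
            raise ValueError("umi_min must be < umi_max")
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class EmptyResultError(RuntimeError):
    """QC removed every unit."""


def filter_cells(
    m: ExpressionMatrix,
    mito_gene_prefix: str = "MT-",
    thresholds: QCThresholds = QCThresholds(),
) -> ExpressionMatrix:
    """Drop cells failing the mito-fraction / UMI / detected-gene rules.

    The gene axis is left unchanged; idempotent.
    """
    totals = m.totals()
    detected = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    mito_mask = np.array([g.startswith(mito_gene_prefix) for g in m.genes])
    mito_counts = np.asarray(m.counts[mito_mask].sum(axis=0)).ravel() if mito_mask.any() else np.zeros(m.n_units)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    keep = (
        (mito_frac <= thresholds.mito_max_frac)
        & (totals >= thresholds.umi_min)
        & (totals <= thresholds.umi_max)
        & (detected >= thresholds.genes_min_per_cell)
    )
    if not keep.any():
        raise EmptyResultError("all cells removed by QC")
    return m.subset_units(keep)


def filter_spots(m: ExpressionMatrix, thresholds: QCThresholds = QCThresholds()) -> ExpressionMatrix:
    """Spot filter then gene filter: spots need >= ``genes_min_per_spot``
    detected genes; genes must be expressed in >= ``min_spots_per_gene``
    surviving spots and total >= ``min_counts_per_gene`` counts there."""
    detected = np.asarray((m.counts > 0).sum(axis=0)).ravel()
    keep_spots = detected >= thresholds.genes_min_per_spot
    if not keep_spots.any():
        raise EmptyResultError("all spots removed by QC")
    m2 = m.subset_units(keep_spots)
    n_spots_expr = np.asarray((m2.counts > 0).sum(axis=1)).ravel()
    gene_totals = np.asarray(m2.counts.sum(axis=1)).ravel()
    keep_genes = (n_spots_expr >= thresholds.min_spots_per_gene) & (
        gene_totals >= thresholds.min_counts_per_gene
    )
    if not keep_genes.any():
        raise EmptyResultError("all genes removed by QC")
    return m2.subset_genes(keep_genes)


def normalize_log1p(m: ExpressionMatrix, scale: float = 10000.0) -> ExpressionMatrix:
    """ln(1 + scale * counts / library_size), stored as the dense
    ``normalized`` layer on a copy of the matrix."""
    totals = m.totals()
    if (totals <= 0).any():
        raise ValueError("zero-count units present; run QC first")
    dense = np.asarray(m.counts.todense(), dtype=float)
    normalized = np.log1p(scale * dense / totals[None, :])
    return ExpressionMatrix(genes=m.genes, units=m.units, counts=m.counts, normalized=normalized)


def _expression_bins(mean_expr: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin id per gene, by mean expression rank. Ties are
    broken by gene order so bins are deterministic."""
    order = np.argsort(mean_expr, kind="mergesort")
    bins = np.empty(len(mean_expr), dtype=int)
    # split ranks into n_bins near-equal chunks
    edges = np.linspace(0, len(mean_expr), n_bins + 1).astype(int)
    for b in range(n_bins):
        bins[order[edges[b]:edges[b + 1]]] = b
    return bins


def module_score(
    m: ExpressionMatrix,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control signature score per unit.

    Genes are ranked by mean normalized expression and cut into
    ``n_bins`` equal-frequency bins; each set gene draws ``n_ctrl``
    control genes with replacement from its own bin. The score is the
    mean expression of the set minus the mean over all drawn controls.
    """
    expr = m.require_normalized()
    gene_set = list(gene_set)
    if m.n_genes < n_bins:
        raise ValueError(f"need >= {n_bins} genes for {n_bins} control bins")
    set_idx = m.gene_index(gene_set)  # raises listing missing genes
    mean_expr = expr.mean(axis=1)
    bins = _expression_bins(mean_expr, n_bins)
    bin_members = {b: np.flatnonzero(bins == b) for b in range(n_bins)}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    ctrl_rows = []
    for gi in set_idx:
        members = bin_members[bins[gi]]
        ctrl_rows.append(rng.choice(members, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_rows)
    return expr[set_idx].mean(axis=0) - expr[ctrl_idx].mean(axis=0)


def celltype_weights(
    m: ExpressionMatrix,
    marker_sets: dict[str, list],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> CellTypeWeights:
    """Project cell types onto spots: one module score per type, negatives
    clipped to zero, renormalized to proportions (uniform if all zero)."""
    if len(marker_sets) < 2:
        raise ValueError("need >= 2 cell types to estimate proportions")
    types = list(marker_sets)
    all_markers = [g for s in marker_sets.values() for g in s]
    if len(set(all_markers)) != len(all_markers):
        log.warning("marker sets overlap across cell types")
    scores = np.column_stack(
        [
            module_score(m, marker_sets[t], n_bins=n_bins, n_ctrl=n_ctrl,
                         seed=_type_seed(seed, t))
            for t in types
        ]
    )
    clipped = np.clip(scores, 0.0, None)
    sums = clipped.sum(axis=1)
    weights = np.where(
        sums[:, None] > 0, clipped / np.maximum(sums, 1e-300)[:, None],
        1.0 / len(types),
    )
    return CellTypeWeights(spot_ids=m.units, cell_types=types, weights=weights)


def _type_seed(seed: int, name: str) -> int:
    import zlib

    return (int(seed) * 1000003 + zlib.crc32(name.encode())) % (2**31 - 1)


def _ranksum_pvalues(expr: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum per gene, normal approximation with tie
    correction and no continuity correction (identical groups give p = 1)."""
    na, nb = len(a_idx), len(b_idx)
    n = na + nb
    sub = expr[:, np.concatenate([a_idx, b_idx])]
    ranks = np.apply_along_axis(rankdata, 1, sub)
    w = ranks[:, :na].sum(axis=1)
    mu = na * (n + 1) / 2.0
    # tie correction per gene
    tie_term = np.zeros(expr.shape[0])
    for g in range(sub.shape[0]):
        _, counts = np.unique(sub[g], return_counts=True)
        t = counts[counts > 1]
        tie_term[g] = (t**3 - t).sum()
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (w - mu) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    return 2.0 * norm.sf(np.abs(z))


def wilcoxon_deg(
    m: ExpressionMatrix,
    group_a,
    group_b,
    lfc_min: float = 0.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two disjoint unit groups.

    log2fc compares back-transformed means: log2((mean expm1 A + 1) /
    (mean expm1 B + 1)). Significance: BH-adjusted p < ``alpha`` and
    |log2fc| >= ``lfc_min``.
    """
    expr = m.require_normalized()
    a_idx = m.unit_index(list(group_a))
    b_idx = m.unit_index(list(group_b))
    if len(a_idx) < 3 or len(b_idx) < 3:
        raise ValueError("both groups need >= 3 units")
    if set(a_idx) & set(b_idx):
        raise ValueError("groups overlap")
    p = _ranksum_pvalues(expr, a_idx, b_idx)
    mean_a = np.expm1(expr[:, a_idx]).mean(axis=1)
    mean_b = np.expm1(expr[:, b_idx]).mean(axis=1)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene": m.genes,
            "group": "A",
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "significant": (p_adj < alpha) & (np.abs(log2fc) >= lfc_min),
        }
    )
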