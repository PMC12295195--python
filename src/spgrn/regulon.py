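"""TF -> target regulon inference inside the receiver population.

Candidate edges are scored by Spearman rank correlation between the TF
and every other expressed gene; a motif-derived TF->target prior then
prunes indirect edges, and TFs retaining at least ``min_targets`` prior-
supported targets become validated regulons. Regulon activity per unit
is the fraction of targets among that unit's top-expressed genes, and
receptors are linked to TFs by correlating receptor expression with
regulon activity (optionally gated by a receptor->TF prior).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import ExpressionMatrix, PriorTables

log = logging.getLogger("spgrn")

__all__ = [
    "Regulon",
    "tf_target_importance",
    "prune_with_prior",
    "regulon_activity",
    "link_receptor_tf",
]


@dataclass
class Regulon:
    tf: str
    targets: dict[str, float] = field(default_factory=dict)  # target -> |rho|
    validated: bool = False

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ValueError("regulon targets must exclude the TF itself")


def _spearman_matrix(tf_expr: np.ndarray, gene_expr: np.ndarray) -> np.ndarray:
    """Spearman rho of one TF vector against each row of gene_expr."""
    rt = rankdata(tf_expr)
    rg = np.apply_along_axis(rankdata, 1, gene_expr)
    rt = rt - rt.mean()
    rg = rg - rg.mean(axis=1, keepdims=True)
    denom = np.sqrt((rt**2).sum() * (rg**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rg @ rt) / np.maximum(denom, 1e-300), 0.0)
    return rho


def tf_target_importance(
    m: ExpressionMatrix,
    tf_list,
    min_abs_rho: float = 0.3,
    top_k: int = 50,
) -> pd.DataFrame:
    """Rank-correlation candidate edges: per TF, Spearman rho against every
    other expressed gene; keep |rho| >= ``min_abs_rho``, at most ``top_k``
    per TF by |rho|. Constant-expression TFs are skipped."""
    expr = m.require_normalized()
    if m.n_units < 30:
        raise ValueError("population too small for regulon inference (need >= 30 units)")
    tf_list = [t for t in tf_list]
    m.gene_index(tf_list)  # raises if a TF is outside the gene universe
    gene_pos = {g: i for i, g in enumerate(m.genes)}
    rows = []
    for tf in tf_list:
        tf_expr = expr[gene_pos[tf]]
        if np.ptp(tf_expr) == 0:
            log.info("skipping constant-expression TF %s", tf)
            continue
        rho = _spearman_matrix(tf_expr, expr)
        keep = np.flatnonzero(np.abs(rho) >= min_abs_rho)
        keep = keep[keep != gene_pos[tf]]  # never test the TF against itself
        if len(keep) > top_k:
            keep = keep[np.argsort(-np.abs(rho[keep]), kind="mergesort")[:top_k]]
        for gi in keep:
            rows.append({"tf": tf, "target": m.genes[gi], "rho": float(rho[gi])})
    return pd.DataFrame(rows, columns=["tf", "target", "rho"])


def prune_with_prior(
    edges: pd.DataFrame,
    priors: PriorTables,
    min_targets: int = 3,
) -> dict[str, Regulon]:
    """Keep only prior-supported edges; TFs retaining >= ``min_targets``
    targets become validated regulons. Output edges are always a subset
    of the input edges."""
    prior_set = priors.tf_target_set()
    if not prior_set:
        raise ValueError("tf_target prior is empty")
    regulons: dict[str, Regulon] = {}
    for _, row in edges.iterrows():
        if (row["tf"], row["target"]) in prior_set:
            reg = regulons.setdefault(row["tf"], Regulon(tf=row["tf"]))
            reg.targets[row["target"]] = abs(float(row["rho"]))
    for reg in regulons.values():
        reg.validated = len(reg.targets) >= min_targets
    return regulons


def regulon_activity(
    m: ExpressionMatrix,
    regulon: Regulon,
    top_frac: float = 0.05,
) -> np.ndarray:
    """Fraction of regulon targets among each unit's top-expressed genes.

    The top set holds the ceil(top_frac * G) highest normalized values;
    ties at the rank cutoff break by gene-symbol order. Rank-based, so
    invariant to monotone transformations of a unit's expression.
    """
    if not regulon.validated:
        raise ValueError("regulon must be validated before activity scoring")
    expr = m.require_normalized()
    k = int(np.ceil(top_frac * m.n_genes))
    target_idx = set(m.gene_index(list(regulon.targets)))
    # sort by (-expr, symbol): lexsort keys applied last take precedence
    symbol_order = np.argsort(m.genes.astype(str), kind="mergesort")
    symbol_rank = np.empty(m.n_genes, dtype=int)
    symbol_rank[symbol_order] = np.arange(m.n_genes)
    activity = np.empty(m.n_units)
    for u in range(m.n_units):
        order = np.lexsort((symbol_rank, -expr[:, u]))
        top = set(order[:k].tolist())
        activity[u] = len(target_idx & top) / len(target_idx)
    return activity


def link_receptor_tf(
    m: ExpressionMatrix,
    receptors,
    regulons: dict[str, Regulon],
    priors: PriorTables | None = None,
    min_rho: float = 0.2,
    top_frac: float = 0.05,
) -> pd.DataFrame:
    """Receptor -> TF edges inside the receiver population.

    An edge (R, TF) is kept iff the receptor->TF prior is absent or
    contains the pair, AND Spearman rho between receptor expression and
    the TF's regulon activity is >= ``min_rho``.
    """
    validated = {tf: r for tf, r in regulons.items() if r.validated}
    if not validated:
        raise ValueError("need at least one validated regulon")
    expr = m.require_normalized()
    prior_set = priors.receptor_tf_set() if priors is not None else None
    gene_pos = {g: i for i, g in enumerate(m.genes)}
    activities = {
        tf: regulon_activity(m, reg, top_frac=top_frac) for tf, reg in validated.items()
    }
    rows = []
    for receptor in receptors:
        if receptor not in gene_pos:
            log.info("receptor %s absent from matrix; skipped", receptor)
            continue
        x_r = expr[gene_pos[receptor]]
        for tf, act in activities.items():
            if prior_set is not None and (receptor, tf) not in prior_set:
                continue
            rho = _spearman_matrix(x_r, act[None, :])[0]
            if rho >= min_rho:
                rows.append({"receptor": receptor, "tf": tf, "rho": float(rho)})
    return pd.DataFrame(rows, columns=["receptor", "tf", "rho"])
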