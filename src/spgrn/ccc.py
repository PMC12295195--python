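"""Spatial ligand-receptor communication scoring.

Two deliberately independent schemes score each ligand-receptor pair:

* ``lr_neighborhood_score`` — sender-aware: ligand expression weighted by
  the sender type's per-spot abundance is paired with receptor expression
  weighted by the receiver type's abundance over neighboring spots; the
  null permutes the cell-type weight table across spots.
* ``spatial_lr_test`` — type-agnostic neighborhood co-expression; the
  null permutes the assignment of expression columns to coordinates.

Both use the add-one permutation p-value (never exactly zero, conservative
tie handling) with Benjamini-Hochberg adjustment across pairs, and retain
pairs with adjusted p below a cutoff, capped at the top ``n_pairs`` by
score. The consensus of the two retained sets feeds the layered network,
and an aggregate sender x receiver matrix summarizes communication load.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from .datamodel import CellTypeWeights, ExpressionMatrix, LRDatabase, SpotGeometry

log = logging.getLogger("spgrn")

__all__ = [
    "LRResult",
    "lr_neighborhood_score",
    "spatial_lr_test",
    "consensus_lr",
    "aggregate_communication",
]


@dataclass
class LRResult:
    """Per-pair scores/p-values for one method, with the retention rule
    p_adj < cutoff and rank <= n_pairs already applied in ``retained``."""

    table: pd.DataFrame  # ligand, receptor, sender, receiver, score, p, p_adj, retained
    method: str

    def retained_pairs(self) -> set[tuple[str, str]]:
        sub = self.table[self.table["retained"]]
        return set(zip(sub["ligand"], sub["receptor"]))


def _pair_rng(master_seed: int, ligand: str, receptor: str) -> np.random.Generator:
    """Per-pair stream from the master seed by hashing the pair name, so
    results do not depend on database row order."""
    digest = hashlib.sha256(f"{ligand}|{receptor}".encode()).digest()
    pair_key = int.from_bytes(digest[:4], "big") % (2**31 - 1)
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), pair_key]))


def _neighbor_plus_self(geometry: SpotGeometry) -> sp.csr_matrix:
    n = geometry.n_spots
    return (geometry.neighbors.astype(float) + sp.eye(n, format="csr")).tocsr()


def _usable_pairs(m: ExpressionMatrix, lr: LRDatabase) -> list[tuple[str, str]]:
    universe = set(m.genes)
    usable = []
    for ligand, receptor in lr.pair_tuples():
        if ligand in universe and receptor in universe:
            usable.append((ligand, receptor))
        else:
            log.info("dropping LR pair with absent gene(s): %s -> %s", ligand, receptor)
    return usable


def _finalize(table: pd.DataFrame, pval_adj_cutoff: float, n_pairs: int, method: str) -> LRResult:
    if len(table):
        _, p_adj, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
        table = table.assign(p_adj=p_adj)
        passing = table[table["p_adj"] < pval_adj_cutoff]
        top = set(
            passing.sort_values("score", ascending=False, kind="mergesort")
            .head(n_pairs)
            .index
        )
        table = table.assign(retained=table.index.isin(top))
    else:
        table = table.assign(p_adj=pd.Series(dtype=float), retained=pd.Series(dtype=bool))
    return LRResult(table=table.reset_index(drop=True), method=method)


def lr_neighborhood_score(
    m: ExpressionMatrix,
    geometry: SpotGeometry,
    weights: CellTypeWeights,
    lr: LRDatabase,
    sender: str,
    receiver: str,
    n_perm: int = 999,
    pval_adj_cutoff: float = 0.05,
    n_pairs: int = 200,
    seed: int = 0,
) -> LRResult:
    """Sender-aware neighborhood LR score with weight-permutation null.

    S = sum over ordered neighbor pairs (s, t), s = t included, of
    w_sender(s) w_receiver(t) x_L(s) x_R(t), normalized by
    sum w_sender(s) w_receiver(t); the null jointly permutes the rows of
    the weight table across spots, expression fixed.
    """
    if sender not in weights.cell_types or receiver not in weights.cell_types:
        raise ValueError("sender/receiver must be among the weight cell types")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    expr = m.require_normalized()
    w_s = weights.weight_of(sender).astype(float)
    w_r = weights.weight_of(receiver).astype(float)
    if not w_s.any():
        raise ValueError(f"sender weight identically zero for {sender!r}")
    a1 = _neighbor_plus_self(geometry)
    n = geometry.n_spots

    rows = []
    for ligand, receptor in _usable_pairs(m, lr):
        x_l = expr[np.flatnonzero(m.genes == ligand)[0]]
        x_r = expr[np.flatnonzero(m.genes == receptor)[0]]
        rng = _pair_rng(seed, ligand, receptor)

        def score(ws: np.ndarray, wr: np.ndarray) -> float:
            num = (ws * x_l) @ (a1 @ (wr * x_r))
            den = ws @ (a1 @ wr)
            return num / den if den > 0 else 0.0

        s_obs = score(w_s, w_r)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if score(w_s[perm], w_r[perm]) >= s_obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        rows.append(
            {"ligand": ligand, "receptor": receptor, "sender": sender,
             "receiver": receiver, "score": s_obs, "p": p}
        )
    table = pd.DataFrame(rows, columns=["ligand", "receptor", "sender", "receiver", "score", "p"])
    return _finalize(table, pval_adj_cutoff, n_pairs, method="neighborhood")


def _coherence_weights(geometry: SpotGeometry) -> sp.csr_matrix:
    """Distance-decayed spatial weights: 2 for first-ring neighbors, 1 for
    second-ring, 0 on the diagonal."""
    a = geometry.neighbors.astype(float)
    eye = sp.eye(geometry.n_spots, format="csr")
    ring2 = ((((a + eye) @ (a + eye)) > 0).astype(float) - eye).tocsr()
    return (a + ring2).tocsr()


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def spatial_lr_test(
    m: ExpressionMatrix,
    geometry: SpotGeometry,
    lr: LRDatabase,
    n_perm: int = 999,
    n_pairs: int = 200,
    pval_adj_cutoff: float = 0.05,
    seed: int = 0,
) -> LRResult:
    """Type-agnostic spatial coherence test per ligand-receptor pair.

    Each gene's library-normalized expression (linear scale) is
    standardized across spots, and the per-spot median of these
    standardized fields over all genes — the compositional factor that
    library-size normalization imprints on every gene wherever a few
    dominant transcripts change — is subtracted, so only gene-specific
    spatial structure remains. The pair statistic is the sum over the
    two genes of the spatial autocorrelation quadratic form z' W z, with
    weights 2 on first-ring and 1 on second-ring neighbor pairs. A pair
    scores high when both genes form coherent expression territories
    instead of unstructured noise — the signature of localized
    ligand-receptor signaling. The null permutes the assignment of
    expression columns to spot coordinates, which leaves each gene's
    value multiset (and the within-spot L/R pairing) intact and destroys
    only the spatial arrangement, so the permutation p-value is exact.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    expr = m.require_normalized()
    w = _coherence_weights(geometry)
    n = geometry.n_spots
    linear = np.expm1(expr)
    sd = linear.std(axis=1, keepdims=True)
    z_all = (linear - linear.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    common = np.median(z_all, axis=0)

    rows = []
    for ligand, receptor in _usable_pairs(m, lr):
        z_l = _standardize(np.expm1(expr[np.flatnonzero(m.genes == ligand)[0]]))
        z_r = _standardize(np.expm1(expr[np.flatnonzero(m.genes == receptor)[0]]))
        z_l = z_l - common if z_l.any() else z_l
        z_r = z_r - common if z_r.any() else z_r
        rng = _pair_rng(seed, ligand, receptor)

        def stat(zl: np.ndarray, zr: np.ndarray) -> float:
            return float(zl @ (w @ zl) + zr @ (w @ zr))

        t_obs = stat(z_l, z_r)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if stat(z_l[perm], z_r[perm]) >= t_obs:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        rows.append(
            {"ligand": ligand, "receptor": receptor, "sender": None,
             "receiver": None, "score": t_obs, "p": p}
        )
    table = pd.DataFrame(rows, columns=["ligand", "receptor", "sender", "receiver", "score", "p"])
    return _finalize(table, pval_adj_cutoff, n_pairs, method="spatial_test")


def consensus_lr(a: LRResult, b: LRResult) -> pd.DataFrame:
    """Pairs retained by both methods, carrying the max p_adj and both
    scores; an empty intersection is valid (downstream layers go empty)."""
    keys = a.retained_pairs() & b.retained_pairs()
    if not keys:
        log.warning("LR consensus is empty: %s vs %s", a.method, b.method)

    def best_rows(table: pd.DataFrame) -> dict[tuple[str, str], pd.Series]:
        # a pair can carry one row per sender; keep the best-supported one
        out: dict[tuple[str, str], pd.Series] = {}
        ordered = table.sort_values(["p_adj", "score"], ascending=[True, False], kind="mergesort")
        for _, row in ordered.iterrows():
            out.setdefault((row["ligand"], row["receptor"]), row)
        return out

    ta = best_rows(a.table[a.table["retained"]])
    tb = best_rows(b.table[b.table["retained"]])
    rows = []
    for ligand, receptor in sorted(keys):
        ra, rb = ta[(ligand, receptor)], tb[(ligand, receptor)]
        rows.append(
            {
                "ligand": ligand,
                "receptor": receptor,
                "sender": ra["sender"],
                "receiver": ra["receiver"],
                f"score_{a.method}": ra["score"],
                f"score_{b.method}": rb["score"],
                "p_adj": max(ra["p_adj"], rb["p_adj"]),
            }
        )
    cols = ["ligand", "receptor", "sender", "receiver",
            f"score_{a.method}", f"score_{b.method}", "p_adj"]
    return pd.DataFrame(rows, columns=cols)


def aggregate_communication(*results: LRResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sender x receiver matrices of retained-pair counts and summed scores."""
    frames = [r.table[r.table["retained"]] for r in results]
    if not frames:
        raise ValueError("need at least one LRResult")
    all_rows = pd.concat(frames, ignore_index=True)
    all_rows = all_rows.dropna(subset=["sender", "receiver"])
    senders = sorted(all_rows["sender"].unique()) if len(all_rows) else []
    receivers = sorted(all_rows["receiver"].unique()) if len(all_rows) else []
    counts = pd.DataFrame(0, index=senders, columns=receivers, dtype=int)
    scores = pd.DataFrame(0.0, index=senders, columns=receivers)
    for _, row in all_rows.iterrows():
        counts.loc[row["sender"], row["receiver"]] += 1
        scores.loc[row["sender"], row["receiver"]] += row["score"]
    return counts, scores
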