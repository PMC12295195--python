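"""Layered ligand-receptor-TF-target network assembly and pruning.

Network 1.0 enumerates every ligand->receptor->TF->target chain supported
by the sender-aware LR result, the receptor->TF links and the candidate
TF->target edges. Three sequential filters then produce the nested
layers: 2.0 keeps chains whose LR pair survives the two-method consensus,
3.0 keeps chains whose TF is a validated regulon containing the target,
and 4.0 keeps chains whose ligand is differentially expressed in the
sender population and whose target is differentially expressed in the
receiver population. Chains (not bare edges) are the unit of filtering,
so pruning a TF removes its whole downstream sub-path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regulon import Regulon

log = logging.getLogger("spgrn")

__all__ = ["LayeredNetwork", "build_n1", "filter_n2", "filter_n3", "filter_n4", "signal_count"]

CHAIN_COLUMNS = [
    "ligand", "receptor", "tf", "target", "sender", "receiver",
    "lr_score", "lr_p_adj", "rt_rho", "tt_rho",
    "in_N1", "in_N2", "in_N3", "in_N4",
]


@dataclass
class LayeredNetwork:
    """Chains with nested layer flags in_N1 >= in_N2 >= in_N3 >= in_N4."""

    chains: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CHAIN_COLUMNS if c not in self.chains.columns]
        if missing:
            raise ValueError(f"chain table missing columns {missing}")
        self.chains = self.chains.astype(
            {"in_N1": bool, "in_N2": bool, "in_N3": bool, "in_N4": bool,
             "lr_score": float, "lr_p_adj": float, "rt_rho": float, "tt_rho": float}
        )
        self.assert_nested()

    def assert_nested(self) -> None:
        c = self.chains
        for outer, inner in (("in_N1", "in_N2"), ("in_N2", "in_N3"), ("in_N3", "in_N4")):
            if (c[inner] & ~c[outer]).any():
                raise AssertionError(f"{inner} is not nested inside {outer}")

    def layer(self, k: int) -> pd.DataFrame:
        return self.chains[self.chains[f"in_N{k}"]]

    def edge_table(self) -> pd.DataFrame:
        """Unique typed edges (LR, RT, TT) with per-layer membership flags
        (an edge is in a layer iff some chain of that layer contains it)."""
        rows = []
        for _, ch in self.chains.iterrows():
            for src, dst, etype, score in (
                (ch["ligand"], ch["receptor"], "LR", ch["lr_score"]),
                (ch["receptor"], ch["tf"], "RT", ch["rt_rho"]),
                (ch["tf"], ch["target"], "TT", ch["tt_rho"]),
            ):
                rows.append(
                    {
                        "source": src, "target": dst, "edge_type": etype,
                        "sender": ch["sender"], "receiver": ch["receiver"],
                        "score": score, "p_adj": ch["lr_p_adj"],
                        "in_N1": ch["in_N1"], "in_N2": ch["in_N2"],
                        "in_N3": ch["in_N3"], "in_N4": ch["in_N4"],
                    }
                )
        if not rows:
            return pd.DataFrame(
                columns=["source", "target", "edge_type", "sender", "receiver",
                         "score", "p_adj", "in_N1", "in_N2", "in_N3", "in_N4"]
            )
        df = pd.DataFrame(rows)
        agg = {
            "score": "max", "p_adj": "min",
            "in_N1": "any", "in_N2": "any", "in_N3": "any", "in_N4": "any",
        }
        out = (
            df.groupby(["source", "target", "edge_type", "sender", "receiver"], as_index=False)
            .agg(agg)
            .sort_values(["edge_type", "source", "target"], kind="mergesort")
            .reset_index(drop=True)
        )
        return out


def build_n1(
    lr_result,
    receptor_tf_edges: pd.DataFrame,
    tf_target_edges: pd.DataFrame,
) -> LayeredNetwork:
    """Enumerate every L->R->TF->target path over the three edge sets.

    ``lr_result`` is the sender-aware :class:`~spgrn.ccc.LRResult`; only
    its retained pairs start chains.
    """
    lr_tab = lr_result.table[lr_result.table["retained"]]
    rt_by_receptor: dict[str, list] = {}
    for _, row in receptor_tf_edges.iterrows():
        rt_by_receptor.setdefault(row["receptor"], []).append(row)
    tt_by_tf: dict[str, list] = {}
    for _, row in tf_target_edges.iterrows():
        tt_by_tf.setdefault(row["tf"], []).append(row)

    rows = []
    for _, lr_row in lr_tab.iterrows():
        for rt in rt_by_receptor.get(lr_row["receptor"], []):
            for tt in tt_by_tf.get(rt["tf"], []):
                rows.append(
                    {
                        "ligand": lr_row["ligand"], "receptor": lr_row["receptor"],
                        "tf": rt["tf"], "target": tt["target"],
                        "sender": lr_row["sender"], "receiver": lr_row["receiver"],
                        "lr_score": lr_row["score"], "lr_p_adj": lr_row["p_adj"],
                        "rt_rho": rt["rho"], "tt_rho": tt["rho"],
                        "in_N1": True, "in_N2": False, "in_N3": False, "in_N4": False,
                    }
                )
    if not rows:
        log.warning("Network 1.0 is empty: no L->R->TF->target chain found")
    chains = pd.DataFrame(rows, columns=CHAIN_COLUMNS)
    return LayeredNetwork(chains=chains)


def filter_n2(net: LayeredNetwork, consensus: pd.DataFrame | set) -> LayeredNetwork:
    """Layer 2: keep chains whose (ligand, receptor) is in the consensus."""
    if isinstance(consensus, pd.DataFrame):
        keys = set(zip(consensus["ligand"], consensus["receptor"]))
    else:
        keys = set(consensus)
    c = net.chains.copy()
    member = [
        (lig, rec) in keys for lig, rec in zip(c["ligand"], c["receptor"])
    ]
    c["in_N2"] = c["in_N1"] & np.asarray(member, dtype=bool)
    c["in_N3"] &= c["in_N2"]
    c["in_N4"] &= c["in_N3"]
    return LayeredNetwork(chains=c)


def filter_n3(net: LayeredNetwork, regulons: dict[str, Regulon]) -> LayeredNetwork:
    """Layer 3: keep chains whose TF is a validated regulon and whose
    target is in that regulon's pruned target set."""
    c = net.chains.copy()
    ok = []
    for tf, tg in zip(c["tf"], c["target"]):
        reg = regulons.get(tf)
        ok.append(reg is not None and reg.validated and tg in reg.targets)
    c["in_N3"] = c["in_N2"] & np.asarray(ok, dtype=bool)
    c["in_N4"] &= c["in_N3"]
    return LayeredNetwork(chains=c)


def filter_n4(
    net: LayeredNetwork,
    deg_sender: pd.DataFrame,
    deg_receiver: pd.DataFrame,
    rule: str = "both",
) -> LayeredNetwork:
    """Layer 4: DEG screening.

    ``rule``: "both" (default, strictest) requires the ligand significant
    in the sender DEG table and the target significant in the receiver
    table; "receiver" requires only the target; "any" keeps chains where
    any chain gene is significant in either table.
    """
    sig_sender = set(deg_sender.loc[deg_sender["significant"], "gene"])
    sig_receiver = set(deg_receiver.loc[deg_receiver["significant"], "gene"])
    c = net.chains.copy()
    if rule == "both":
        ok = [
            (lig in sig_sender) and (tg in sig_receiver)
            for lig, tg in zip(c["ligand"], c["target"])
        ]
    elif rule == "receiver":
        ok = [tg in sig_receiver for tg in c["target"]]
    elif rule == "any":
        union = sig_sender | sig_receiver
        ok = [
            bool({lig, rec, tf, tg} & union)
            for lig, rec, tf, tg in zip(c["ligand"], c["receptor"], c["tf"], c["target"])
        ]
    else:
        raise ValueError(f"unknown N4 rule {rule!r}")
    c["in_N4"] = c["in_N3"] & np.asarray(ok, dtype=bool)
    return LayeredNetwork(chains=c)


def signal_count(net: LayeredNetwork) -> pd.DataFrame:
    """Per-layer counts: distinct signaling molecules (gene symbols over
    the layer's chains), distinct typed edges, and chains. Monotone
    non-increasing across layers by nestedness."""
    rows = []
    edges = net.edge_table()
    for k in (1, 2, 3, 4):
        sub = net.layer(k)
        molecules = set()
        for col in ("ligand", "receptor", "tf", "target"):
            molecules.update(sub[col].tolist())
        n_edges = int(edges[f"in_N{k}"].sum()) if len(edges) else 0
        rows.append(
            {"layer": f"N{k}", "molecules": len(molecules),
             "edges": n_edges, "chains": len(sub)}
        )
    return pd.DataFrame(rows)
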