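"""End-to-end orchestration: simulate/load -> QC -> projection -> boundary
-> communication -> consensus -> regulons -> DEG -> layered network.

A single master seed fans out to per-stage seeds by stable hashing of
stage names, so adding a stage never perturbs earlier stages' randomness;
a manifest of per-file content hashes makes reruns checkable bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ccc, cnv, io, network, preprocess, regulon, simulate
from .datamodel import CellTypeWeights, ExpressionMatrix

log = logging.getLogger("spgrn")

__all__ = ["RunConfig", "RunResult", "run_all", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed from the master seed and the stage name."""
    return (int(master_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run.

    With ``simulate=True`` all inputs come from the synthetic-tissue
    generator; otherwise the path fields must point at the on-disk
    formats handled by :mod:`spgrn.io`.
    """

    seed: int = 0
    simulate: bool = True
    sim: simulate.SimConfig | None = None
    cells_per_type: int = 300

    # external-input paths (used when simulate=False)
    tissue_counts_dir: str | None = None
    positions_path: str | None = None
    scref_counts_dir: str | None = None
    scref_labels_path: str | None = None
    lr_db_path: str | None = None
    tf_target_path: str | None = None
    receptor_tf_path: str | None = None
    gene_positions_path: str | None = None

    qc: preprocess.QCThresholds = field(default_factory=preprocess.QCThresholds)
    n_perm: int = 999
    pval_adj_cutoff: float = 0.05
    n_pairs: int = 200
    sender_types: tuple[str, ...] = ("fibroblast", "plasma")
    receiver_type: str = "malignant"
    markers_per_type: int = 15
    cnv_window: int = 101
    cnv_clamp: float = 3.0
    q_seed: float = 0.95
    min_separation: float = 4.2
    min_abs_rho: float = 0.3
    rt_min_rho: float = 0.2
    min_targets: int = 3
    n4_rule: str = "both"

    def __post_init__(self) -> None:
        if self.simulate and self.sim is None:
            self.sim = simulate.SimConfig(seed=stage_seed(self.seed, "simulate"))
        if not self.simulate:
            required = [
                "tissue_counts_dir", "positions_path", "scref_counts_dir",
                "scref_labels_path", "lr_db_path", "tf_target_path",
                "gene_positions_path",
            ]
            missing = [f for f in required if getattr(self, f) is None]
            if missing:
                raise ValueError(f"missing input path(s): {missing}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunResult:
    """In-memory artifacts of a run (also written to the run directory)."""

    config: RunConfig
    regions: cnv.RegionLabels
    weights: CellTypeWeights
    lr_neighborhood: ccc.LRResult
    lr_spatial: ccc.LRResult
    consensus: pd.DataFrame
    regulons: dict
    net: network.LayeredNetwork
    counts: pd.DataFrame  # signal_count table
    truth: simulate.GroundTruth | None = None
    manifest: dict | None = None


def _load_inputs(config: RunConfig):
    if config.simulate:
        sim = config.sim
        tissue, geom, _, truth = simulate.simulate_tissue(sim)
        scref, labels = simulate.simulate_scref(sim, cells_per_type=config.cells_per_type)
        positions = simulate.simulate_gene_positions(sim)
        lrdb, priors, tf_list = simulate.simulate_priors(sim)
        return tissue, geom, scref, labels, positions, lrdb, priors, tf_list, truth
    tissue = io.read_matrix_market(config.tissue_counts_dir)
    geom = io.read_spot_positions(config.positions_path)
    scref = io.read_matrix_market(config.scref_counts_dir)
    lab = pd.read_csv(config.scref_labels_path, sep="\t")
    labels = lab.set_index(lab.columns[0]).iloc[:, 0].reindex(scref.units).to_numpy(dtype=object)
    positions = io.read_gene_positions(config.gene_positions_path)
    lrdb, priors = io.read_table_priors(
        config.lr_db_path, config.tf_target_path, config.receptor_tf_path
    )
    tf_list = sorted(set(priors.tf_target["tf"]))
    return tissue, geom, scref, labels, positions, lrdb, priors, tf_list, None


def _marker_sets(scref_norm: ExpressionMatrix, labels: np.ndarray, n_markers: int) -> dict[str, list[str]]:
    """Top up-regulated genes per cell type from the single-cell reference."""
    sets = {}
    for t in pd.unique(labels):
        in_t = scref_norm.units[labels == t]
        rest = scref_norm.units[labels != t]
        deg = preprocess.wilcoxon_deg(scref_norm, in_t, rest)
        up = deg[deg["significant"] & (deg["log2fc"] > 0)]
        top = up.sort_values("log2fc", ascending=False, kind="mergesort").head(n_markers)
        sets[str(t)] = top["gene"].tolist()
    return sets


def _multi_sender_n4(net, deg_by_sender: dict[str, pd.DataFrame], deg_receiver: pd.DataFrame, rule: str):
    """Apply the N4 DEG screen with each chain judged against its own
    sender's DEG table."""
    flags = np.zeros(len(net.chains), dtype=bool)
    for sender, deg_s in deg_by_sender.items():
        filtered = network.filter_n4(net, deg_s, deg_receiver, rule=rule)
        mask = (net.chains["sender"] == sender).to_numpy()
        flags[mask] = filtered.chains["in_N4"].to_numpy()[mask]
    c = net.chains.copy()
    c["in_N4"] = c["in_N3"] & flags
    return network.LayeredNetwork(chains=c)


def run_all(config: RunConfig, out_dir=None) -> RunResult:
    """Execute the full pipeline; write artifacts + manifest if ``out_dir``."""
    tissue, geom, scref, labels, positions, lrdb, priors, tf_list, truth = _load_inputs(config)

    # ---- QC + normalization -------------------------------------------
    scref_f = preprocess.filter_cells(scref, thresholds=config.qc)
    scref_n = preprocess.normalize_log1p(preprocess.filter_spots(scref_f, config.qc))
    tissue_f = preprocess.filter_spots(tissue, config.qc)
    tissue_n = preprocess.normalize_log1p(tissue_f)
    kept = set(tissue_n.units)
    keep_mask = np.array([u in kept for u in geom.spot_ids])
    if not keep_mask.all():
        geom = _subset_geometry(geom, keep_mask)
        if truth is not None:
            truth = simulate.GroundTruth(
                region=truth.region[keep_mask],
                dominant_type=truth.dominant_type[keep_mask],
                chains=truth.chains,
                decoys=truth.decoys,
            )
    # align unit order with geometry
    tissue_n = tissue_n.subset_units(tissue_n.unit_index(list(geom.spot_ids)))

    labels = np.asarray(labels, dtype=object)[scref.unit_index(list(scref_n.units))]

    # ---- cell-type projection -----------------------------------------
    marker_sets = _marker_sets(scref_n, labels, config.markers_per_type)
    tissue_genes = set(tissue_n.genes)
    marker_sets = {
        t: [g for g in genes if g in tissue_genes] for t, genes in marker_sets.items()
    }
    weights = preprocess.celltype_weights(
        tissue_n, marker_sets, seed=stage_seed(config.seed, "project")
    )

    # ---- CNV boundary --------------------------------------------------
    ref_units = cnv.infer_reference(tissue_n, positions, w=config.cnv_window, c=config.cnv_clamp)
    profile = cnv.cnv_profile(
        tissue_n, positions, ref_units, w=config.cnv_window, c=config.cnv_clamp
    )
    scores = cnv.cnv_score(profile)
    regions = cnv.define_boundary(
        scores, geom, q_seed=config.q_seed, min_separation=config.min_separation
    )

    # ---- spatial communication ----------------------------------------
    lr_parts = []
    for sender in config.sender_types:
        lr_parts.append(
            ccc.lr_neighborhood_score(
                tissue_n, geom, weights, lrdb, sender=sender,
                receiver=config.receiver_type, n_perm=config.n_perm,
                pval_adj_cutoff=config.pval_adj_cutoff, n_pairs=config.n_pairs,
                seed=stage_seed(config.seed, f"ccc-neighborhood-{sender}"),
            )
        )
    lr_neigh = ccc.LRResult(
        table=pd.concat([p.table for p in lr_parts], ignore_index=True),
        method="neighborhood",
    )
    lr_spatial = ccc.spatial_lr_test(
        tissue_n, geom, lrdb, n_perm=config.n_perm, n_pairs=config.n_pairs,
        pval_adj_cutoff=config.pval_adj_cutoff,
        seed=stage_seed(config.seed, "ccc-spatial"),
    )
    consensus = ccc.consensus_lr(lr_neigh, lr_spatial)

    # ---- regulons in the receiver (malignant) population ---------------
    mal_units = regions.spot_ids[regions.mask("Mal")]
    regulons: dict = {}
    rt_edges = pd.DataFrame(columns=["receptor", "tf", "rho"])
    tt_edges = pd.DataFrame(columns=["tf", "target", "rho"])
    if len(mal_units) >= 30:
        mal_norm = tissue_n.subset_units(tissue_n.unit_index(list(mal_units)))
        tfs_present = [t for t in tf_list if t in set(mal_norm.genes)]
        tt_edges = regulon.tf_target_importance(
            mal_norm, tfs_present, min_abs_rho=config.min_abs_rho
        )
        regulons = regulon.prune_with_prior(tt_edges, priors, min_targets=config.min_targets)
        receptors = sorted({r for _, r in lr_neigh.retained_pairs()})
        if any(r.validated for r in regulons.values()):
            rt_edges = regulon.link_receptor_tf(
                mal_norm, receptors, regulons, priors, min_rho=config.rt_min_rho
            )
    else:
        log.warning("malignant region too small (%d spots); regulon stage skipped", len(mal_units))

    # ---- DEG tables -----------------------------------------------------
    spot_label = weights.labels
    non_mal = ~regions.mask("Mal")
    deg_by_sender = {}
    for sender in config.sender_types:
        grp_a = geom.spot_ids[(spot_label == sender) & non_mal]
        grp_b = geom.spot_ids[(spot_label != sender) & non_mal]
        deg_by_sender[sender] = _safe_deg(tissue_n, grp_a, grp_b)
    # receiver contrast: boundary-facing malignant rim vs the non-malignant
    # compartment — the rim is where sender-driven activation concentrates,
    # and the large nMal group gives the rank test its power
    mal_mask = regions.mask("Mal")
    rim = mal_mask & (np.asarray(geom.neighbors @ (~mal_mask).astype(float)).ravel() > 0)
    nmal_mask = regions.mask("nMal")
    deg_receiver = _safe_deg(tissue_n, geom.spot_ids[rim], geom.spot_ids[nmal_mask])

    # ---- layered network ------------------------------------------------
    net = network.build_n1(lr_neigh, rt_edges, tt_edges)
    net = network.filter_n2(net, consensus)
    net = network.filter_n3(net, regulons)
    net = _multi_sender_n4(net, deg_by_sender, deg_receiver, rule=config.n4_rule)
    counts = network.signal_count(net)

    result = RunResult(
        config=config, regions=regions, weights=weights,
        lr_neighborhood=lr_neigh, lr_spatial=lr_spatial, consensus=consensus,
        regulons=regulons, net=net, counts=counts, truth=truth,
    )
    if out_dir is not None:
        result.manifest = _write_run(result, out_dir)
    return result


def _safe_deg(m: ExpressionMatrix, grp_a, grp_b) -> pd.DataFrame:
    """DEG table, or an all-insignificant table when a group is too small."""
    if len(grp_a) < 3 or len(grp_b) < 3:
        log.warning("DEG group too small (%d vs %d); nothing significant", len(grp_a), len(grp_b))
        return pd.DataFrame(
            {"gene": m.genes, "group": "A", "log2fc": 0.0, "p": 1.0,
             "p_adj": 1.0, "significant": False}
        )
    return preprocess.wilcoxon_deg(m, grp_a, grp_b)


def _subset_geometry(geom, mask: np.ndarray):
    from .datamodel import SpotGeometry

    idx = np.flatnonzero(mask)
    return SpotGeometry(
        spot_ids=geom.spot_ids[idx], x=geom.x[idx], y=geom.y[idx],
        in_tissue=geom.in_tissue[idx], neighbors=geom.neighbors[idx][:, idx],
    )


def _write_run(result: RunResult, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"spot": result.regions.spot_ids, "label": result.regions.labels,
         "cnv_score": result.regions.cnv_score}
    ).to_csv(out / "regions.tsv", sep="\t", index=False)
    result.weights.to_frame().to_csv(out / "celltype_weights.tsv", sep="\t", index=False)
    result.lr_neighborhood.table.to_csv(out / "lr_neighborhood.tsv", sep="\t", index=False)
    result.lr_spatial.table.to_csv(out / "lr_spatial.tsv", sep="\t", index=False)
    result.consensus.to_csv(out / "lr_consensus.tsv", sep="\t", index=False)
    reg_rows = [
        {"tf": r.tf, "target": tg, "abs_rho": rho, "validated": r.validated}
        for r in result.regulons.values()
        for tg, rho in sorted(r.targets.items())
    ]
    pd.DataFrame(reg_rows, columns=["tf", "target", "abs_rho", "validated"]).to_csv(
        out / "regulons.tsv", sep="\t", index=False
    )
    io.write_network(result.net, out / "network")
    result.counts.to_csv(out / "signal_counts.tsv", sep="\t", index=False)

    manifest = {
        "seed": result.config.seed,
        "stage_seeds": {
            s: stage_seed(result.config.seed, s)
            for s in ("simulate", "project", "ccc-spatial")
        },
        "config": _jsonable(result.config.to_dict()),
        "files": {},
    }
    for p in sorted(out.glob("*")):
        if p.name == "manifest.json":
            continue
        manifest["files"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file mirroring the field names."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "qc" in raw and isinstance(raw["qc"], dict):
        raw["qc"] = preprocess.QCThresholds(**raw["qc"])
    if "sim" in raw and isinstance(raw["sim"], dict):
        raw["sim"] = simulate.SimConfig(**raw["sim"])
    if "sender_types" in raw:
        raw["sender_types"] = tuple(raw["sender_types"])
    return RunConfig(**raw)
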