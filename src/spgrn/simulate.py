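"""Synthetic paired scRNA + spatial tissue with planted ground truth.

The generator emulates the structure the pipeline is built to detect: a
hexagonal Visium-like patch carrying a central malignant disc whose cells
gain a contiguous chromosome block (the CNV signal), a fibroblast/plasma
annulus on the first two rings outside the disc, and ligand->receptor->
TF->target cascades that are active only across the disc rim: the ligand
is elevated in sender-type spots, while receptor, TF and targets are
elevated only in malignant spots adjacent to a sender spot. Decoy
cascades share the shape but have effect size zero. Counts are negative
binomial (variance mu + alpha*mu^2) with lognormal library sizes; a seed
fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    CellTypeWeights,
    ExpressionMatrix,
    GenePositions,
    LRDatabase,
    PriorTables,
    SpotGeometry,
)

__all__ = [
    "CascadeSpec",
    "CNVBlock",
    "SimConfig",
    "GroundTruth",
    "hex_patch",
    "simulate_tissue",
    "simulate_scref",
    "simulate_gene_positions",
    "simulate_priors",
    "default_config",
    "compact_config",
]

CELL_TYPES = ["malignant", "fibroblast", "plasma", "other"]


@dataclass(frozen=True)
class CascadeSpec:
    """One planted signaling chain: ligand -> receptor -> TF -> targets."""

    ligand: int
    receptor: int
    tf: int
    targets: tuple[int, ...]
    beta: float = 1.5
    sender: str = "fibroblast"

    def gene_indices(self) -> tuple[int, ...]:
        return (self.ligand, self.receptor, self.tf, *self.targets)


@dataclass(frozen=True)
class CNVBlock:
    """Contiguous run of gene indices gaining ``log2_gain`` in malignant units."""

    start: int
    n_genes: int
    log2_gain: float = 0.8

    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.n_genes)


def _default_cascades() -> tuple[CascadeSpec, ...]:
    planted = []
    senders = ["fibroblast", "fibroblast", "plasma"]
    for c in range(3):
        base = 450 + 10 * c
        planted.append(
            CascadeSpec(
                ligand=base, receptor=base + 1, tf=base + 2,
                targets=tuple(range(base + 3, base + 7)),
                beta=1.5, sender=senders[c],
            )
        )
    return tuple(planted)


def _default_decoys() -> tuple[CascadeSpec, ...]:
    decoys = []
    senders = ["fibroblast", "plasma", "fibroblast"]
    for c in range(3):
        base = 500 + 10 * c
        decoys.append(
            CascadeSpec(
                ligand=base, receptor=base + 1, tf=base + 2,
                targets=tuple(range(base + 3, base + 7)),
                beta=0.0, sender=senders[c],
            )
        )
    return tuple(decoys)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic tissue.

    Defaults: a radius-12 hex patch (469 spots), 600 genes on 4
    pseudo-chromosomes, 15 markers per cell type at 5-fold elevation,
    one 60-gene CNV block at +0.8 log2, three planted cascades at
    beta = 1.5 plus three decoys at beta = 0, NB dispersion 0.5 and
    lognormal library sizes (mu = 9.2, sigma = 0.3).
    """

    grid_radius: int = 12
    n_genes: int = 600
    markers_per_type: int = 15
    marker_fold: float = 5.0
    cnv_blocks: tuple[CNVBlock, ...] = (CNVBlock(start=210, n_genes=60, log2_gain=0.8),)
    cascades: tuple[CascadeSpec, ...] = field(default_factory=_default_cascades)
    decoy_cascades: tuple[CascadeSpec, ...] = field(default_factory=_default_decoys)
    nb_dispersion: float = 0.5
    libsize_mu: float = 9.2
    libsize_sigma: float = 0.3
    burst_cv: float = 0.5  # extra TF pathway noise in active spots
    propagation_damping: float = 0.75  # exponent tying each level to the one above
    mix_alpha: float | None = None  # None -> pure one-hot spots
    seed: int = 0

    def gene_names(self) -> np.ndarray:
        return np.array([f"G{i:04d}" for i in range(self.n_genes)], dtype=object)

    def marker_indices(self) -> dict[str, np.ndarray]:
        k = self.markers_per_type
        return {t: np.arange(i * k, (i + 1) * k) for i, t in enumerate(CELL_TYPES)}

    def validate(self) -> None:
        special: set[int] = set()
        for t, idx in self.marker_indices().items():
            special.update(idx.tolist())
        for blk in self.cnv_blocks:
            if blk.start + blk.n_genes > self.n_genes:
                raise ValueError("CNV block exceeds gene universe")
            special.update(blk.indices().tolist())
        seen: set[int] = set()
        for cas in (*self.cascades, *self.decoy_cascades):
            idx = cas.gene_indices()
            if max(idx) >= self.n_genes:
                raise ValueError(f"cascade references gene index >= n_genes: {idx}")
            if set(idx) & special or set(idx) & seen:
                raise ValueError("cascade genes must be disjoint from markers/CNV/other cascades")
            if cas.sender not in CELL_TYPES:
                raise ValueError(f"unknown sender type {cas.sender!r}")
            seen.update(idx)


def default_config(**overrides) -> SimConfig:
    return replace(SimConfig(), **overrides)


def compact_config(
    seed: int = 0,
    grid_radius: int = 8,
    n_genes: int = 300,
    n_cascades: int = 2,
    n_decoys: int = 2,
    beta: float = 1.5,
    cnv_gain: float = 0.8,
    **overrides,
) -> SimConfig:
    """A smaller, internally consistent tissue for quick experiments.

    Cascade and CNV gene indices are laid out programmatically so any
    combination of ``n_genes``/``n_cascades``/``n_decoys`` is valid.
    """
    n_types = len(CELL_TYPES)
    markers_per_type = 15
    marker_end = n_types * markers_per_type
    cnv_n = max(20, n_genes // 10)
    cnv_start = marker_end + 10
    cas_start = cnv_start + cnv_n + 10
    senders = ["fibroblast", "plasma"]
    cascades = []
    for c in range(n_cascades):
        base = cas_start + 7 * c
        cascades.append(
            CascadeSpec(ligand=base, receptor=base + 1, tf=base + 2,
                        targets=tuple(range(base + 3, base + 7)),
                        beta=beta, sender=senders[c % 2])
        )
    decoys = []
    for c in range(n_decoys):
        base = cas_start + 7 * (n_cascades + c)
        decoys.append(
            CascadeSpec(ligand=base, receptor=base + 1, tf=base + 2,
                        targets=tuple(range(base + 3, base + 7)),
                        beta=0.0, sender=senders[c % 2])
        )
    needed = cas_start + 7 * (n_cascades + n_decoys)
    if needed > n_genes:
        raise ValueError(f"n_genes={n_genes} too small; need >= {needed}")
    cfg = SimConfig(
        grid_radius=grid_radius,
        n_genes=n_genes,
        cnv_blocks=(CNVBlock(start=cnv_start, n_genes=cnv_n, log2_gain=cnv_gain),)
        if cnv_gain > 0 else (),
        cascades=tuple(cascades),
        decoy_cascades=tuple(decoys),
        seed=seed,
    )
    return replace(cfg, **overrides)


@dataclass
class GroundTruth:
    """Planted truth: per-spot region & dominant type, chain tables."""

    region: np.ndarray  # {"Mal", "Bdy", "nMal"} per spot
    dominant_type: np.ndarray
    chains: pd.DataFrame  # planted cascades expanded to one row per target
    decoys: pd.DataFrame


def hex_patch(radius: int):
    """Axial hex coordinates of a patch of given radius (3r(r+1)+1 spots)."""
    qs, rs = [], []
    for q in range(-radius, radius + 1):
        for r in range(max(-radius, -q - radius), min(radius, -q + radius) + 1):
            qs.append(q)
            rs.append(r)
    q = np.array(qs)
    r = np.array(rs)
    x = q + r / 2.0
    y = r * np.sqrt(3) / 2.0
    hexdist = (np.abs(q) + np.abs(r) + np.abs(q + r)) // 2
    ids = np.array([f"spot_{i:04d}" for i in range(len(q))], dtype=object)
    return ids, x, y, hexdist


def _rngs(seed: int):
    mk = lambda k: np.random.default_rng(np.random.SeedSequence([int(seed), k]))
    return mk(0), mk(1), mk(2), mk(3)  # profile, tissue, cells, priors


def _baseline_relative(config: SimConfig, rng_profile: np.random.Generator) -> np.ndarray:
    r = rng_profile.lognormal(mean=0.0, sigma=0.5, size=config.n_genes)
    return r / r.sum()


def _type_factor(config: SimConfig, cell_type: str) -> np.ndarray:
    """Cell-intrinsic fold factors: markers for the own type, CNV gain for
    malignant, ligand elevation for sender-type cells."""
    f = np.ones(config.n_genes)
    f[config.marker_indices()[cell_type]] = config.marker_fold
    if cell_type == "malignant":
        for blk in config.cnv_blocks:
            f[blk.indices()] *= 2.0 ** blk.log2_gain
    for cas in (*config.cascades, *config.decoy_cascades):
        if cas.sender == cell_type:
            f[cas.ligand] *= 1.0 + cas.beta
    return f


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB with variance mu + alpha*mu^2 (shape k = 1/alpha)."""
    if alpha <= 0:
        return rng.poisson(mu)
    k = 1.0 / alpha
    return rng.negative_binomial(k, k / (k + mu))


def simulate_tissue(config: SimConfig):
    """Generate the spatial sample.

    Returns ``(ExpressionMatrix, SpotGeometry, CellTypeWeights, GroundTruth)``.
    """
    config.validate()
    rng_profile, rng_tissue, _, _ = _rngs(config.seed)
    baseline = _baseline_relative(config, rng_profile)

    ids, x, y, hexdist = hex_patch(config.grid_radius)
    n_spots = len(ids)
    geom = SpotGeometry.from_coords(ids, x, y)

    disc_r = int(np.ceil(config.grid_radius / 3))
    dominant = np.full(n_spots, "other", dtype=object)
    dominant[hexdist <= disc_r] = "malignant"
    # fibroblast and plasma occupy contiguous half-annulus sectors spanning
    # the two rings outside the disc, so both types touch the malignant rim
    # and each type forms one connected patch (as stromal populations do)
    annulus = (hexdist == disc_r + 1) | (hexdist == disc_r + 2)
    angles = np.arctan2(y, x)
    dominant[annulus & (angles >= 0)] = "fibroblast"
    dominant[annulus & (angles < 0)] = "plasma"

    mal_mask = dominant == "malignant"
    adj = geom.neighbors

    # cell-intrinsic per-type fold profiles
    type_factor = {t: _type_factor(config, t) for t in CELL_TYPES}
    fold = np.ones((config.n_genes, n_spots))
    if config.mix_alpha is None:
        weights = np.zeros((n_spots, len(CELL_TYPES)))
        for j, t in enumerate(CELL_TYPES):
            sel = dominant == t
            weights[sel, j] = 1.0
            fold[:, sel] = type_factor[t][:, None]
    else:
        alpha_vec = np.full(len(CELL_TYPES), config.mix_alpha)
        weights = np.empty((n_spots, len(CELL_TYPES)))
        for s in range(n_spots):
            a = alpha_vec.copy()
            a[CELL_TYPES.index(dominant[s])] += 1.0
            weights[s] = rng_tissue.dirichlet(a)
        fmat = np.column_stack([type_factor[t] for t in CELL_TYPES])
        fold = fmat @ weights.T

    # spatial cascade activation: receptor/TF/targets elevated only in
    # malignant spots adjacent to the stromal annulus (the tumor rim, where
    # sender-derived ligand is available); within each active spot the TF
    # and its targets share a per-spot activity burst so that the planted
    # signal propagates through the TF (recoverable by rank correlation),
    # not merely co-locates with it
    annulus_mask = ((dominant == "fibroblast") | (dominant == "plasma")).astype(float)
    touches_annulus = np.asarray(adj @ annulus_mask).ravel() > 0
    rim_active = np.flatnonzero(mal_mask & touches_annulus)
    for cas in (*config.cascades, *config.decoy_cascades):
        if cas.beta <= 0:
            continue
        fold[cas.receptor, rim_active] *= 1.0 + cas.beta

    libsize = rng_tissue.lognormal(config.libsize_mu, config.libsize_sigma, size=n_spots)
    mu = baseline[:, None] * fold * libsize[None, :]
    counts = _nb_draw(rng_tissue, mu, config.nb_dispersion)

    # conditional cascade propagation in active rim spots: the receptor
    # carries a clean (1+beta) shift (drawn above); the TF's mean tracks
    # the receptor's *realized* expression (optionally with extra Gamma
    # pathway noise), and each target's mean tracks the TF's realized
    # count. The signal thus travels through the chain spot by spot and
    # is recoverable by rank correlation at every link — the standard
    # generative model for benchmarking GRN inference. Expected
    # multipliers stay (1+beta) at every level.
    for cas in (*config.cascades, *config.decoy_cascades):
        if cas.beta <= 0:
            continue
        cv = config.burst_cv
        damp = config.propagation_damping
        mu_r = baseline[cas.receptor] * libsize[rim_active]
        eta_r = np.maximum(counts[cas.receptor, rim_active], 1) / (mu_r * (1.0 + cas.beta))
        g = (
            rng_tissue.gamma(shape=1.0 / cv**2, scale=cv**2, size=len(rim_active))
            if cv > 0 else np.ones(len(rim_active))
        )
        shape = eta_r**damp * g
        shape /= shape.mean()  # mean multiplier stays exactly (1 + beta)
        mu_tf = baseline[cas.tf] * libsize[rim_active]
        tf_counts = _nb_draw(rng_tissue, mu_tf * (1.0 + cas.beta) * shape, config.nb_dispersion)
        counts[cas.tf, rim_active] = tf_counts
        eta_tf = np.maximum(tf_counts, 1) / (mu_tf * (1.0 + cas.beta))
        tg_shape = eta_tf**damp
        tg_shape /= tg_shape.mean()
        for tg in cas.targets:
            mu_tg = baseline[tg] * libsize[rim_active] * (1.0 + cas.beta) * tg_shape
            counts[tg, rim_active] = _nb_draw(rng_tissue, mu_tg, config.nb_dispersion)

    matrix = ExpressionMatrix(genes=config.gene_names(), units=ids, counts=counts)
    ctw = CellTypeWeights(spot_ids=ids, cell_types=list(CELL_TYPES), weights=weights)

    region = np.full(n_spots, "nMal", dtype=object)
    region[mal_mask] = "Mal"
    touches_mal = np.asarray(adj @ mal_mask.astype(float)).ravel() > 0
    region[~mal_mask & touches_mal] = "Bdy"

    gene_names = config.gene_names()
    chains = _chain_frame(config.cascades, gene_names)
    decoys = _chain_frame(config.decoy_cascades, gene_names)
    truth = GroundTruth(region=region, dominant_type=dominant, chains=chains, decoys=decoys)
    return matrix, geom, ctw, truth


def _chain_frame(cascades, gene_names: np.ndarray) -> pd.DataFrame:
    rows = []
    for cas in cascades:
        for tg in cas.targets:
            rows.append(
                {
                    "ligand": gene_names[cas.ligand],
                    "receptor": gene_names[cas.receptor],
                    "tf": gene_names[cas.tf],
                    "target": gene_names[tg],
                    "sender": cas.sender,
                    "receiver": "malignant",
                    "beta": cas.beta,
                }
            )
    return pd.DataFrame(rows, columns=["ligand", "receptor", "tf", "target", "sender", "receiver", "beta"])


def simulate_scref(config: SimConfig, cells_per_type: int = 300):
    """Single-cell reference with the same per-type mean profiles as the
    tissue's pure-type spots (cell-intrinsic effects only: markers, CNV
    gain, sender-ligand elevation — not the adjacency-driven activation).

    Returns ``(ExpressionMatrix, labels)``.
    """
    config.validate()
    rng_profile, _, rng_cells, _ = _rngs(config.seed)
    baseline = _baseline_relative(config, rng_profile)

    n_cells = cells_per_type * len(CELL_TYPES)
    labels = np.repeat(CELL_TYPES, cells_per_type).astype(object)
    fold = np.ones((config.n_genes, n_cells))
    for t in CELL_TYPES:
        fold[:, labels == t] = _type_factor(config, t)[:, None]
    libsize = rng_cells.lognormal(config.libsize_mu, config.libsize_sigma, size=n_cells)
    mu = baseline[:, None] * fold * libsize[None, :]
    counts = _nb_draw(rng_cells, mu, config.nb_dispersion)
    ids = np.array([f"cell_{i:05d}" for i in range(n_cells)], dtype=object)
    return ExpressionMatrix(genes=config.gene_names(), units=ids, counts=counts), labels


def simulate_gene_positions(config: SimConfig, n_chromosomes: int = 4) -> GenePositions:
    """Assign genes to pseudo-chromosomes in index order (equal splits) so
    the CNV moving-average window is contiguous over each planted block."""
    genes = config.gene_names()
    per = int(np.ceil(config.n_genes / n_chromosomes))
    chrom = [f"chr{i // per + 1}" for i in range(config.n_genes)]
    start = [(i % per) * 1000 + 1 for i in range(config.n_genes)]
    return GenePositions(pd.DataFrame({"gene": genes, "chrom": chrom, "start": start}))


def simulate_priors(
    config: SimConfig,
    n_background_pairs: int = 20,
    n_decoy_tf_rows: int = 200,
    n_decoy_tfs: int = 20,
):
    """LR database and prior tables covering planted + decoy cascades plus
    background noise rows, as a stand-in for curated databases.

    Returns ``(LRDatabase, PriorTables, tf_list)``. Both planted and decoy
    cascades appear in every table: a decoy can only be rejected by the
    data, never by database absence.
    """
    config.validate()
    _, _, _, rng = _rngs(config.seed)
    genes = config.gene_names()
    all_cas = (*config.cascades, *config.decoy_cascades)
    used = set()
    for cas in all_cas:
        used.update(cas.gene_indices())
    for t, idx in config.marker_indices().items():
        used.update(idx.tolist())
    free = np.array(sorted(set(range(config.n_genes)) - used))

    lr_rows = [{"ligand": genes[c.ligand], "receptor": genes[c.receptor]} for c in all_cas]
    bg = rng.choice(free, size=(n_background_pairs, 2), replace=False)
    lr_rows += [{"ligand": genes[a], "receptor": genes[b]} for a, b in bg]

    tt_rows = [
        {"tf": genes[c.tf], "target": genes[tg]} for c in all_cas for tg in c.targets
    ]
    decoy_tfs = rng.choice(free, size=n_decoy_tfs, replace=False)
    for _ in range(n_decoy_tf_rows):
        tf = genes[rng.choice(decoy_tfs)]
        tg = genes[rng.choice(free)]
        if tf != tg:
            tt_rows.append({"tf": tf, "target": tg})

    rt_rows = [{"receptor": genes[c.receptor], "tf": genes[c.tf]} for c in all_cas]
    for _ in range(n_decoy_tfs):
        rt_rows.append(
            {"receptor": genes[rng.choice(free)], "tf": genes[rng.choice(decoy_tfs)]}
        )

    lrdb = LRDatabase(pd.DataFrame(lr_rows))
    priors = PriorTables(
        tf_target=pd.DataFrame(tt_rows), receptor_tf=pd.DataFrame(rt_rows)
    )
    tf_list = sorted({r["tf"] for r in tt_rows})
    return lrdb, priors, tf_list
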