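"""Copy-number scoring and morphological tumor-region delineation.

Expression residuals against a reference population, smoothed along the
genome with a moving average inside each chromosome, summarize
large-scale copy-number change. A per-spot score (mean squared smoothed
residual) then drives a three-way partition of the section: an Otsu-style
split picks a score threshold, the top-quantile spots seed connected
components of the above-threshold subgraph (the malignant region, Mal),
spots adjacent to it form the boundary (Bdy), and the rest are
non-malignant (nMal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .datamodel import ExpressionMatrix, GenePositions, SpotGeometry

log = logging.getLogger("spgrn")

__all__ = ["CNVProfile", "RegionLabels", "cnv_profile", "cnv_score", "define_boundary", "infer_reference"]


@dataclass
class CNVProfile:
    """Smoothed log-scale residuals, units x ordered genes."""

    units: np.ndarray
    genes: list[str]  # (chromosome, start) order
    values: np.ndarray  # units x genes
    window: int
    clamp: float


@dataclass
class RegionLabels:
    """Per-spot region assignment with the CNV score that produced it."""

    spot_ids: np.ndarray
    labels: np.ndarray  # {"Mal", "Bdy", "nMal"}
    cnv_score: np.ndarray

    def __post_init__(self) -> None:
        valid = {"Mal", "Bdy", "nMal"}
        if not set(self.labels) <= valid:
            raise ValueError(f"labels must be in {valid}")

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label


def _moving_average_truncated(x: np.ndarray, w: int) -> np.ndarray:
    """Moving average of odd width ``w`` along the last axis, window
    truncated (not mirrored) at the ends; works for any w vs length."""
    if w <= 1:
        return x
    if w % 2 == 0:
        raise ValueError("window must be odd")
    n = x.shape[-1]
    h = w // 2
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    csum = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def cnv_profile(
    m: ExpressionMatrix,
    positions: GenePositions,
    reference_units,
    w: int = 101,
    c: float = 3.0,
) -> CNVProfile:
    """Reference-centered, clamped, genome-smoothed expression residuals.

    residual = normalized expression - per-gene reference mean, clamped to
    [-c, c]; a width-``w`` moving average is applied within each
    chromosome (edge-truncated); finally each unit's median across genes
    is subtracted.
    """
    expr = m.require_normalized()
    ordered = positions.ordered_genes(m.genes)
    if not ordered:
        raise ValueError("no genes with known positions")
    gidx = m.gene_index(ordered)
    ref_idx = m.unit_index(list(reference_units))
    if len(ref_idx) == 0:
        raise ValueError("reference_units must be non-empty")
    sub = expr[gidx, :].T  # units x genes
    residual = sub - sub[ref_idx].mean(axis=0)[None, :]
    residual = np.clip(residual, -c, c)

    chrom_of = positions.chrom_of()
    chroms = np.array([chrom_of[g] for g in ordered])
    smoothed = np.empty_like(residual)
    for ch in pd_unique(chroms):
        cols = np.flatnonzero(chroms == ch)
        smoothed[:, cols] = _moving_average_truncated(residual[:, cols], w)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    return CNVProfile(units=m.units, genes=ordered, values=smoothed, window=w, clamp=c)


def pd_unique(arr: np.ndarray) -> list:
    """Unique values in first-appearance order."""
    seen: dict = {}
    for v in arr:
        seen.setdefault(v, None)
    return list(seen)


def cnv_score(profile: CNVProfile) -> np.ndarray:
    """Mean squared smoothed residual per unit (non-negative)."""
    return (profile.values**2).mean(axis=1)


def infer_reference(
    m: ExpressionMatrix,
    positions: GenePositions,
    w: int = 101,
    c: float = 3.0,
    decile: float = 0.1,
) -> np.ndarray:
    """Two-pass reference choice when no external normal is available:
    profile against all units, then take the lowest-``decile`` scores as
    the presumed-diploid reference set."""
    first = cnv_profile(m, positions, reference_units=m.units, w=w, c=c)
    scores = cnv_score(first)
    cutoff = np.quantile(scores, decile)
    ref = m.units[scores <= cutoff]
    log.info("two-pass CNV reference: %d units in lowest decile", len(ref))
    return ref


def _otsu_split(scores: np.ndarray):
    """Exhaustive two-class split minimizing within-class variance.

    Returns (tau, low_mean, high_mean, separation): tau is the midpoint
    of the two class means; separation is the gap between the class
    means in units of the low-class standard deviation, a bimodality
    measure that stays small (~2-3) on unimodal score distributions and
    grows without bound when a genuinely aberrant population is present.
    """
    s = np.sort(scores)
    n = len(s)
    if s.var() <= 1e-20 * max(1.0, float(s.mean()) ** 2):
        return None
    best = None
    csum = np.cumsum(s)
    total = csum[-1]
    for k in range(1, n):  # low class = s[:k]
        m0 = csum[k - 1] / k
        m1 = (total - csum[k - 1]) / (n - k)
        w0 = k / n
        between = w0 * (1 - w0) * (m1 - m0) ** 2
        if best is None or between > best[0]:
            best = (between, m0, m1, k)
    _, m0, m1, k = best
    sigma_low = s[:k].std() if k > 1 else 0.0
    gap = m1 - m0
    separation = gap / sigma_low if sigma_low > 0 else np.inf
    return ((m0 + m1) / 2.0, m0, m1, separation)


def define_boundary(
    scores: np.ndarray,
    geometry: SpotGeometry,
    q_seed: float = 0.95,
    min_separation: float = 4.2,
    grow_frac: float = 0.35,
) -> RegionLabels:
    """Partition spots into Mal / Bdy / nMal from CNV scores.

    Seeds are the spots at or above the ``q_seed`` score quantile; the
    malignant core is the union of connected components (over the
    neighbor graph restricted to spots above the Otsu threshold) that
    contain a seed. The core then grows hysteresis-style into adjacent
    spots whose score is still above ``m0 + grow_frac*(m1-m0)`` (m0, m1
    the two class means), recovering rim spots that noise pushed just
    below the main threshold; enclosed holes are filled. The boundary is
    the one-ring graph neighborhood of the final region.
    If the gap between the two score classes is below ``min_separation``
    low-class standard deviations (a unimodal score distribution, e.g. a
    section without tumor), or all scores are equal, everything is nMal.
    """
    scores = np.asarray(scores, dtype=float)
    n = geometry.n_spots
    if len(scores) != n:
        raise ValueError("scores must cover all spots")
    labels = np.full(n, "nMal", dtype=object)
    split = _otsu_split(scores)
    if split is None:
        log.warning("all CNV scores equal; labeling everything nMal")
        return RegionLabels(geometry.spot_ids, labels, scores)
    tau, m0, m1, separation = split
    if separation < min_separation:
        log.warning(
            "CNV score split too weak (separation %.3f < %.3f); no malignant region",
            separation, min_separation,
        )
        return RegionLabels(geometry.spot_ids, labels, scores)
    seeds = scores >= np.quantile(scores, q_seed)
    high = scores >= tau
    sub = geometry.neighbors[high][:, high]
    n_comp, comp = connected_components(sub, directed=False)
    high_idx = np.flatnonzero(high)
    seeded_components = set(comp[np.isin(high_idx, np.flatnonzero(seeds & high))])
    mal = np.zeros(n, dtype=bool)
    mal[high_idx[np.isin(comp, list(seeded_components))]] = True
    # hysteresis growth: absorb neighbors still well above the low class
    t_low = m0 + grow_frac * (m1 - m0)
    while True:
        candidate = (~mal) & (scores >= t_low) & (
            np.asarray(geometry.neighbors @ mal.astype(float)).ravel() > 0
        )
        if not candidate.any():
            break
        mal |= candidate
    # fill enclosed holes: a spot whose neighbors are all malignant sits
    # inside the tumor regardless of its own score
    degree = np.asarray(geometry.neighbors.sum(axis=1)).ravel()
    while True:
        mal_nb = np.asarray(geometry.neighbors @ mal.astype(float)).ravel()
        holes = (~mal) & (degree > 0) & (mal_nb == degree)
        if not holes.any():
            break
        mal |= holes
    labels[mal] = "Mal"
    touches = np.asarray(geometry.neighbors @ mal.astype(float)).ravel() > 0
    labels[~mal & touches] = "Bdy"
    out = RegionLabels(geometry.spot_ids, labels, scores)
    _assert_boundary_adjacency(out, geometry)
    return out


def _assert_boundary_adjacency(regions: RegionLabels, geometry: SpotGeometry) -> None:
    mal = regions.mask("Mal").astype(float)
    bdy = regions.mask("Bdy")
    touches = np.asarray(geometry.neighbors @ mal).ravel() > 0
    if bdy.any() and not touches[bdy].all():
        raise AssertionError("boundary spot without malignant neighbor")
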