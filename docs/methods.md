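# Methods

This note documents the models and numerical choices behind `spgrn`: what
each stage assumes, which knobs matter, what the synthetic tissue does and
does not emulate, and where the design was genuinely open.

## Synthetic tissue

The generator produces a hexagonal patch of radius *r* (3r(r+1)+1 spots;
469 at the default r = 12) with four cell populations:

- a **malignant disc** of radius ⌈r/3⌉ at the center, whose spots express
  one contiguous block of 60 genes at 2^0.8 × baseline (the copy-number
  signal; genes sit on 4 pseudo-chromosomes in index order so the
  genome-smoothing window is meaningful);
- a **stromal annulus** on the first two rings outside the disc, split
  into a contiguous fibroblast half and a contiguous plasma half (stromal
  populations form connected patches in real sections, and contiguity is
  what makes their expression territories detectable by spatial
  statistics);
- **other** tissue elsewhere. Every population carries 15 marker genes at
  5-fold elevation; spots are pure-type by default (a Dirichlet mixing
  option exists but blunts every planted contrast).

Counts are negative binomial with variance μ + αμ², α = 0.5 (moderately
overdispersed droplet data), and lognormal library sizes
(μ = 9.2, σ = 0.3, i.e. ≈ 10⁴ UMIs/spot). A single seed fully determines
the output; the paired single-cell reference reuses the same per-type
mean profiles.

### Planted cascades

Each cascade (ligand, receptor, TF, 4 targets; default three at
β = 1.5 plus three decoys at β = 0) is active only across the tumor rim:

- the **ligand** mean is scaled by (1+β) in all spots of the cascade's
  sender type (its half-annulus);
- the **receptor** mean is scaled by (1+β) in malignant spots adjacent to
  the stromal annulus (the rim ring) — a clean, deterministic shift;
- the **TF** tracks the receptor's *realized* expression in each rim spot
  (damping exponent 0.75 on the receptor's mean-one noise, times an extra
  Gamma pathway factor with CV 0.5), renormalized so its mean multiplier
  is exactly (1+β);
- each **target** tracks the realized TF the same way.

This conditional-propagation model is the standard way GRN inference is
benchmarked: the downstream signal travels *through* the chain spot by
spot, so rank correlation can recover each link, while the expected
multiplier stays (1+β) at every level (the empirical rim-vs-interior
log-fold-change of targets converges to log2(1+β)). The damping and
pathway-noise defaults sit at a measured balance point of an intrinsic
tension: more shared variance strengthens TF–target correlation but
weakens the targets' rank-based differential expression, and vice versa;
neither extreme serves the downstream filters.

What the generator does **not** emulate: spot-level cell mixtures and
deconvolution ambiguity, doublets, ambient RNA, segmentation artifacts,
spatial expression gradients beyond the planted geometry, or realistic
gene–gene correlation outside the planted cascades. Passing tests
therefore demonstrate that the pipeline recovers planted structure under
honest noise — not that it is robust to every failure mode of real
sections.

## QC and normalization

Cells: drop at mitochondrial fraction > 0.20 (symbol prefix `MT-`,
configurable), UMIs < 200 or > 60,000, detected genes < 200. Spots:
≥ 200 detected genes; genes must appear in ≥ 3 surviving spots with ≥ 10
total counts (the per-spot vs total reading of the count rule is
ambiguous in common usage; we adopt *total across spots*, exposed as a
config option). Both filters are idempotent. Normalization is library
scaling to 10⁴ followed by ln(1+x) — the de-facto default of the standard
single-cell toolchain; the method is otherwise unspecified upstream, so
nothing downstream depends on the constant.

Cell-type projection uses binned-control signature scores: genes are cut
into 24 equal-frequency expression bins; each signature gene draws 100
controls with replacement from its bin; the score is mean(signature) −
mean(controls). Negative scores are clipped at zero and renormalized to
per-spot proportions (a proportion cannot be negative; raw scores are
also available). Marker signatures come from one-vs-rest Wilcoxon tests
on the single-cell reference (top 15 up-regulated genes per type).

Differential expression is a two-sided Wilcoxon rank-sum with normal
approximation and tie correction — deliberately without continuity
correction, so identical groups give p = 1 exactly — with
Benjamini–Hochberg adjustment and significance at adjusted p < 0.05.

## CNV boundary

Residual = normalized expression − per-gene reference mean, clamped to
±3, moving-averaged over 101 genes within each chromosome (window
truncated at chromosome ends, the convention of the standard CNV-inference
stack), then per-spot median-centered. The score is the mean squared
smoothed residual. When no external reference exists, a two-pass scheme
uses the lowest-decile spots of an unreferenced first pass as reference.

Region calling: an exhaustive two-class split of the scores picks the
threshold (midpoint of the class means); spots at or above the 0.95
score quantile seed connected components of the above-threshold subgraph;
the seeded components grow hysteresis-style into neighbors above
m0 + 0.35·(m1−m0) and enclosed holes are filled (a spot surrounded by
malignant spots is malignant); Bdy is the one-ring neighborhood of the
final region (`--bdy-rings` widens it). Two guards make the caller safe
on tumor-free sections: exactly equal scores → all nMal, and a
**separation guard** — if the gap between the class means is below 4.2
low-class standard deviations, no malignant region is called. The 4.2
default was calibrated on the generator's two regimes (null tissue:
separation 3.2–3.7; tumor-bearing: 4.8–6.0). On null simulations the
malignant label covers zero spots; on planted discs label accuracy is
≈ 0.94 (recall ≈ 0.93, precision ≈ 0.89).

## Spatial communication

**Scheme 1 (sender-aware).** For sender type a and receiver type b,
S = Σ over ordered adjacent spot pairs (s,t), including s = t, of
w_a(s)·w_b(t)·x_L(s)·x_R(t), normalized by Σ w_a(s)·w_b(t). The null
jointly permutes the rows of the weight table across spots (expression
fixed), so the test asks: is the ligand–receptor co-expression on the
a→b interface stronger than on a randomly relocated interface?

**Scheme 2 (type-agnostic).** Each gene's library-normalized linear
expression is standardized across spots; the per-spot median of these
standardized fields over all genes — the compositional factor that
library normalization imprints on every gene wherever dominant
transcripts change — is subtracted. The pair statistic is
T = z_L′Wz_L + z_R′Wz_R with spatial weights 2 on first-ring and 1 on
second-ring neighbor pairs: a Moran-type spatial-coherence form that asks
whether both genes form coherent expression territories rather than
unstructured noise. The null permutes the assignment of expression
columns to coordinates. We evaluated a broad family of type-agnostic
statistics under this null (neighborhood cross-products on log and linear
scales, hotspot top-k products of smoothed fields, bivariate join counts,
normal-score variants, and combinations); cross-product forms carry very
little information at realistic noise because the permutation preserves
the within-spot pairing of the two genes, leaving only the adjacency of
noisy top-value sets. The within-gene coherence form was the most
powerful calibrated choice and is the package's design.

Both schemes use the add-one permutation p-value
p = (1 + #{T_perm ≥ T_obs})/(1 + n_perm) (never zero; ties counted
conservatively), BH adjustment across pairs, and the retention rule
p_adj < 0.05 capped at the top 200 pairs by score — the same rule applied
to both schemes (whether the first scheme was originally filtered
identically is not specifiable; one rule for both keeps the consensus
symmetric). Per-pair RNG streams derive from the master seed by hashing
the (ligand, receptor) names, so results are independent of database row
order. Under a global-null tissue the raw p-values are calibrated
(fraction below 0.05 ≈ 0.05 across 100 pairs) *for genes without designed
spatial structure*; cell-type marker genes form real territories and are
correctly — not spuriously — flagged, which is why null calibration must
be assessed on the non-marker gene universe.

The consensus keeps pairs retained by both schemes (carrying both scores
and the max adjusted p), and the aggregate communication matrix counts
retained pairs (and sums scores) per sender × receiver.

## Regulons

Candidate TF→target edges are Spearman correlations between the TF and
every other expressed gene within the receiver (malignant-region)
population (≥ 30 spots required; constant TFs skipped; |ρ| ≥ 0.3; top 50
per TF). Tree-ensemble importances of the standard GRN stack are
deliberately replaced by rank correlation: deterministic,
oracle-checkable, and sufficient for consensus pruning. A motif-derived
TF→target prior then removes unsupported edges; TFs keeping ≥ 3 targets
become validated regulons (the common regulon-size floor). Regulon
activity per spot is the fraction of targets among the top 5% of that
spot's genes (ties at the cutoff break by gene symbol, so activity is
rank-based and invariant to monotone transformations). Receptor→TF links
require membership in the receptor→TF prior when one is supplied *and*
Spearman ρ(receptor, activity) ≥ 0.2 — the prior-AND-correlation rule is
our reconstruction of a step that standard pipelines leave implicit.

## Layered network

Network 1.0 enumerates all L→R→TF→target paths over retained sender-aware
LR pairs, receptor links, and candidate TF→target edges. Filters: 2.0 —
LR pair in the two-scheme consensus; 3.0 — TF validated and the target in
its pruned set; 4.0 — DEG screen. Chains, not bare edges, are the filter
unit, so pruning a TF removes its whole downstream sub-path; nestedness
is asserted on every construction. The 4.0 rule defaults to the strictest
reading (ligand significant in its sender's DEG table *and* target
significant in the receiver table); `receiver` and `any` presets are
selectable. The pipeline's DEG contrasts: sender tables compare each
sender type's spots against other non-malignant spots; the receiver table
compares the boundary-facing malignant rim against the non-malignant
compartment (rim-vs-interior is cleaner compositionally but collapses
when the estimated region is ragged; malignant-vs-non-malignant cancels
in rank space because the copy-number gain deflates every other gene's
normalized value in malignant spots).

Signal counts report distinct molecules (the headline number), distinct
typed edges, and chains per layer; molecule counts are non-increasing
across layers by nestedness. When region labels are available the
communication stage runs on the full section but the regulon and DEG
stages are region-aware, which concentrates the final layers on
boundary-associated signaling.

## Recovery characteristics and limitations

At the default study conditions (469 spots, β = 1.5, NB dispersion 0.5),
measured per-stage recovery of planted cascades: sender-aware LR retention
≈ 100% of pairs, spatial-coherence retention ≈ 70–85%, regulon validation
≈ 60–75% of TFs, prior-pruned TF→target edge recovery ≈ 70–85%, receptor
links ≈ 55–70%, and target-level DEG significance ≈ 20–30% per target.
Decoy cascades essentially never reach Network 4.0. The joint probability
that *every* chain of *every* planted cascade survives all four layers in
a single run is therefore near zero at these sample sizes — the funnel is
intentionally conservative, and at ~24 active rim spots the strict
all-chains event is statistics-limited, not implementation-limited: the
TF–target correlation floor (|ρ| ≥ 0.3) and the targets' rank-based DEG
pull the same per-spot noise budget in opposite directions, and the
spatial-coherence scheme's per-pair power against a coordinates
permutation caps the consensus at ~70–85% per pair. Scaling the tissue up
(larger rim, more spots) relaxes all three simultaneously.

Problem sizes used by the test suite and the acceptance script (funnel
checks on radius-7/8 patches with 149 permutations; calibration at 999
permutations on 100 pairs; recovery and boundary checks on 10–20 default
sections) were chosen so the full suite runs in a few minutes on one CPU.
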