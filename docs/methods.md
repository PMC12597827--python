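# Methods

## Overview

`cardioniche` implements the spatially informed analysis chain used to chart
cellular niches in developmental heart tissue: per-state reference profiling
from labelled single-cell counts, reference-based deconvolution of spatially
barcoded spots, niche discovery from pairwise co-detection scores with a
temporal stability check, combinatorial in situ sequencing (ISS) decoding
with quality filtering, and a surrogate ligand–receptor score. Because the
primary datasets of such atlases are access-controlled, the package ships a
synthetic-data generator that emulates their structure with full ground
truth; every stage is validated end-to-end against that truth.

## State profiles

Counts are library-size normalized (each cell scaled to `scale = 1e4` total
counts) and log1p-transformed — the de facto standard single-cell recipe.
For each state the package keeps three summaries: the mean log-normalized
expression (`mean_expr`, used for display tables and ligand–receptor
scores), the mean *linear* counts-per-scale expression (`mean_linear`, the
deconvolution dictionary — mixtures are linear in counts, not in log
space), and the fraction of cells with raw count > 0 (`frac_expr`, the
conventional "percent expressing" semantics).

Dot-plot and heatmap tables z-score each gene across the *displayed* states
using the population SD; constant genes map to 0 rather than NaN so heatmaps
stay finite. Scaling within the displayed set (rather than over all states)
is a deliberate choice; it matches how such figures are normally read.

## Deconvolution

Each spot's counts-per-scale vector is regressed on the linear-scale state
profiles over the shared gene set with non-negative least squares
(`scipy.optimize.nnls`), and the weights are renormalized to the simplex.
Design choices:

* **NNLS rather than a probabilistic model.** The estimator is transparent,
  dependency-light and exactly reproducible; the `ProportionMap` contract
  isolates it so a probabilistic deconvolution could be swapped in without
  touching co-detection.
* **No log transform before fitting** — the mixture model is linear in
  counts; log transforms break it.
* **Count floor**: spots with fewer than 100 total counts (configurable) are
  masked, not fitted, mirroring standard spot QC. Masked spots carry
  all-zero rows plus a mask bit and are excluded from all downstream
  statistics.
* **No ridge penalty by default** (`ridge = 0`); ill-conditioned references
  trigger a warning rather than silent regularization. A Tikhonov penalty is
  available as a flag.

Scale invariance (normalization precedes fitting) and column-permutation
equivariance are tested properties. On the synthetic defaults, noise-free
mixtures are recovered to mean per-spot L1 error ~1e-15 and Poisson counts
at depth 5,000 to ~0.03.

## Co-detection and niche graphs

The co-detection score of two states is the Pearson correlation of their
per-spot proportions. Two aggregation modes:

* `per_section_weighted` (default): correlate within each section, then
  average weighted by the section's unmasked spot count. This is immune to
  artifactual correlation induced by between-section composition shifts.
* `pooled`: concatenate spots across sections, one correlation.

Zero-variance states yield missing (NaN) entries — never 0 — and missing
entries never create graph edges. The niche graph joins state pairs whose
score is **strictly** greater than the threshold (default 0.07); a node's
degree counts its co-detected partners. Connected components of the graph
at low noise recover the planted niche partition exactly.

### Age-group stability

Sections are partitioned by postconceptional week into three groups
(5.5–6, 7–8, 9–14 PCW by default). Printed interval bounds leave gaps
(6–7, 8–9); these are closed by extending each interval up to the next
interval's start, so a PCW 6.5 section falls in the first group. The
stability report compares per-group score matrices by (i) Pearson
correlation of upper-triangle score vectors (missing entries excluded
pairwise) and (ii) the Jaccard index of thresholded edge sets, defined as
1 when both sets are empty. Self-comparisons are 1 by construction.

## ISS decoding

A gene's barcode is one channel per round (one-hot per round). Decoding is
per-round max-channel: the winning channel in each round is the intensity
argmax; the barcode is matched against the codebook exactly (no
nearest-barcode rescue, which would change the decoder's semantics). The
per-round quality is the L1-normalized winner intensity,
`q_r = I_max,r / Σ_c I_c,r`, so `q_r ∈ [1/C, 1]` for C channels. The L1
rule was chosen because it makes the 0.4 minimum-quality cutoff
discriminative: a uniform (pure-noise) round scores exactly 0.2 with 5
channels, whereas an L2 rule would bound quality below at ≈0.447 and make
the cutoff vacuous. An L2 variant remains possible behind the same
function boundary.

Per spot, the mean quality averages `q_r` across rounds and the minimum
quality is the worst round. The filter retains calls with minimum quality
**strictly** over 0.4 *and* an exact codebook match; removals are counted
by reason. Conventions for degenerate inputs: argmax ties break to the
lowest channel index and are flagged; all-zero rounds score the uniform
quality `1/C` and are flagged, so dropout spots are filtered rather than
fatal. Under uniform background b at signal s the quality is analytically
`(s + b)/(s + C·b)`, strictly decreasing in b — a tested invariant.

## Ligand–receptor surrogate score

For small-molecule mediation (adrenergic, cholinergic) the synthesis enzyme
stands in for the ligand: TH→ADRB1, CHAT→CHRM2. The score of an ordered
(sender, receiver) pair is the mean of the sender's enzyme mean expression
and the receiver's receptor mean expression, gated to 0 unless at least
`min_frac = 0.1` of each side's cells express the respective gene. The
exact functional form of such "modified" scores is a convention; the
mean-of-means with an expressing-fraction gate keeps the score monotone in
both inputs and directional, and the formula sits behind one function so a
product form (exposed via `form="product"`) is a one-line swap.

## Synthetic data generator

What it emulates:

* **Reference**: K discrete states (default 6), each with 10 dedicated
  marker genes enriched 20-fold over baseline; per-cell expected counts are
  `depth ×` the state's relative profile (depth 5,000, Visium-like).
* **Sections**: spots on a square lattice partitioned into contiguous
  vertical-strip niches (contiguity guaranteed by construction; Voronoi
  layouts would be an extension). States are dealt to niches round-robin;
  a niche's Dirichlet mean puts 75% of its mass on its own states. Per-spot
  proportions ~ Dirichlet(concentration × niche mean), concentration 30; a
  `fixed_mixture` flag implements the infinite-concentration (degenerate)
  limit. Spot counts are drawn from the linear mixture of profiles.
* **Age covariate**: each section carries a PCW in [5.5, 14].
* **ISS**: 5-round × 5-channel one-hot codes; per spot, signal on the coded
  channel, additive uniform background everywhere, independent additive
  half-normal noise (keeps intensities non-negative).

Count noise is `none` (exact expected values — the noise-free limit used
for exact-recovery tests), `poisson`, or `nb` (gamma–Poisson with one
shared dispersion, variance `μ + φμ²`, the standard scRNA-seq
overdispersion convention — no noise model is prescribed by the problem
itself, so these are field conventions). One global seed drives a
hierarchical `SeedSequence` stream (reference / sections / ISS), so each
component regenerates independently and bit-identically.

What it does **not** emulate — and hence what passing tests do not show
about real data: doublets and ambient RNA, batch and donor effects,
spatially varying capture efficiency, image-level artifacts upstream of the
intensity table (PSF, tiling, registration), spot-size heterogeneity, and
biological covariance between states beyond niche co-membership. Recovery
numbers on synthetic data are upper bounds on what the same estimators
achieve on tissue.

## Problem sizes and numerical choices

Default study: 600 reference cells (6 states × 100), 3–4 sections × 400
spots on a 20×20 lattice, 2,000–10,000 ISS spots with a 150-gene codebook.
These sizes give Monte-Carlo error well below the tested tolerances while
the full test suite runs in seconds. Tolerances: simplex sums to 1 within
1e-6 (estimates) / 1e-9 (truth); co-detection matches a brute-force Pearson
oracle within 1e-10; symmetry within 1e-12. Degenerate inputs are defined,
not fatal: all-zero cells pass normalization with a warning, zero-variance
states propagate as missing, all-zero ISS rounds score 1/C.

## Known limitations

* NNLS deconvolution assumes the reference spans the spot transcriptomes;
  unmodelled states are absorbed by their nearest profiles.
* Pearson co-detection on compositions carries a negative baseline bias
  (closure: proportions sum to 1), so absolute score values depend on the
  number of states; the threshold is a convention, not an estimated
  quantity.
* The per-section-weighted average of correlations is not itself a
  correlation; it is bounded in [−1, 1] but has no single-sample
  interpretation.
* Exact-match ISS decoding cannot rescue single-round errors; with strong
  noise, recall drops before precision does (the filter trades recall for
  precision by design).
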