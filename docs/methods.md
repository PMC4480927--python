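# Methods

## Data model

An expression tensor is a real array `D` of shape `G × C × T` (genes ×
biological replicates × time points) with unique axis labels and a
boolean observation mask. Every statistic in the package is computed
over observed cells only; a tricluster slice with no observed cell is a
hard error (`DegenerateSliceError`) rather than being imputed. This is
the minimal-assumption treatment of deleted entries in the AD4-style
benchmarks: no imputation scheme is introduced anywhere in the scoring
path. (The two places that need complete vectors — k-means feature
matrices in the δ-estimation heuristic and the eigengene SVD — mean-
impute locally and say so in their docstrings.)

Indices are 0-based internally; axis labels are the external interface
and the only thing written to or read from files.

## Coherence score

A tricluster `M(I, J, K)` follows the shifting model
`m_ijk = Γ + α_i + β_j + η_k`. Its mean squared residue is the mean of
`r_ijk² = (m_ijk − m_iJK − m_IjK − m_IJk + 2·m_IJK)²` over observed
cells. MSR is exactly 0 for a perfect shifting tricluster and is
invariant under adding per-gene, per-sample or per-time constants and
under permuting members. Gene-wise variance scaling does change the
residues in general, so no scaling invariance is claimed; the additive
invariance is the one asserted and tested.

Numerical convention: residues of a perfect block cancel only to ~1e−30
at double precision. An MSR at or below `1e−9` is treated as exactly
zero by the `f1` objective (and the SDB denominator guard), so equally
perfect triclusters compare as equals instead of by cancellation noise.
Real data never produces MSR values in the (0, 1e−9] band at the scale
of normalized expression units.

## Local search (greedy repair)

Candidates proposed by the evolutionary loop are repaired into
δ-triclusters with a three-phase Cheng–Church-style heuristic:

1. **Multiple node deletion** — while MSR > δ, simultaneously remove
   every gene, then every sample, then every time point whose mean
   squared residue exceeds `λ·MSR`, recomputing MSR between phases.
   λ > 1 (default 1.2) controls aggressiveness. The phase is skipped on
   axes shorter than 50 entries (configurable), where simultaneous
   deletion overshoots; single deletion handles them.
2. **Single node deletion** — while MSR > δ, remove the one node with
   the largest mean squared residue across all three axes.
3. **Node addition** — once MSR ≤ δ, repeatedly admit every outside
   node whose mean squared residue with respect to the current
   tricluster is at most the current MSR, until a pass adds nothing.
   An absolute tolerance of 1e−12 on this comparison lets perfect
   blocks regrow to their maximal extent despite floating-point
   cancellation. A pass that would push MSR above δ is reverted, so the
   δ-property is preserved by construction. Inverted (mirror-image)
   profiles are not added; anti-correlation is rewarded at the
   objective level (`f3` uses |ρ|), and keeping addition additive-only
   avoids double counting.

Size floors (defaults: 2 genes, 1 sample, 2 time points; the engine
raises the time floor to 3 because Spearman correlation needs ≥ 3
points) are never crossed by deletion; a candidate stuck at the floors
with MSR > δ is flagged infeasible and re-seeded by the engine.
Tie-breaks everywhere are deterministic: axis order gene → sample →
time, then ascending index.

## Objectives and selection

`f1 = MSR/δ ∈ [0, 1]` for feasible solutions (minimized); `f2` is the
volume fraction (maximized); `f3` is the mean over unordered gene pairs
of `|1 − 6Σd_i²/(n(n²−1))|`, where ranks are fractional on ties and
`d_i` is the rank difference of the two sample-averaged time profiles at
the i-th member time point. The Σd² form is the no-tie Spearman formula;
under ties it is an approximation, accepted as such and clipped into
[0, 1]. A constant profile has no rank direction, so its pairs
contribute 0 with a warning. Rank direction (ascending vs descending)
is immaterial because the absolute value is taken; no per-gene direction
search is performed.

Selection is standard elitist NSGA-II: parents plus mutated offspring
are pooled, partitioned into non-dominated fronts, and filled into the
next population with crowding-distance truncation of the last front
(boundary solutions get infinite distance; a zero-range objective
contributes nothing). Reproduction is mutation-only with a per-bit flip
probability of 0.9 by default: because repair re-derives a coherent
tricluster from whatever the mutant encodes, the high rate acts as heavy
restarts that sweep the tensor for patterns, and crossover would add
nothing a batch of flips does not already do.

An external archive collects every feasible δ-tricluster found;
insertion rejects candidates dominated by an archived solution and
evicts archived solutions the candidate dominates, so archive members
are mutually non-dominated at return time. Identical membership triples
collapse to one entry. The returned set is this deduplicated archive,
ordered by volume (descending), then MSR, then indices — a deterministic
function of the seed. Per-generation traces record the population
`minSum`, front sizes and archive size; the run stops at the generation
cap or when the best `minSum` has not improved by `1e−4` for 10
consecutive generations.

Infeasible repairs (floor-size, MSR > δ) are re-seeded from fresh random
chromosomes, up to 5 attempts per slot; a persistent failure keeps the
penalized individual in the population (its `f1 > 1` makes it dominated)
but never enters the archive. Chromosome initialization sets each bit
with probability 0.5 and redraws any all-zero segment.

## Recovery scoring

The affirmation score between an implanted set `T_im` and a recovered
set `T_res` is the geometric mean of three per-axis components; each
component is the average over the *recovered* triclusters of the best
Jaccard overlap of that axis' member set against any implanted
tricluster — the score of the result set with respect to the implanted
set. It is 1 exactly when every recovered tricluster coincides with an
implanted one on all three axes (in particular when `T_res = T_im`), and
0 when no memberships overlap. Averaging over the recovered set is the
direction under which a result contaminated with spurious triclusters is
penalized; the identity at equality holds either way.

## Other statistics

* **TD** = MSR / volume (lower is better).
* **SDB** = mean over result triclusters of
  `(mean_j RMSR_j − MSR_i) / MSR_i`, with `r` (default 100) random
  same-shape triclusters drawn by uniform axis subsampling without
  replacement (higher is better). Triclusters with numerically zero MSR
  are skipped with a warning — the relative excess is undefined there.
* **Enrichment / hit scores** — hypergeometric over-representation
  p-values per annotation set (GMT input), corrected by
  Benjamini–Hochberg (default, pathway-style annotations) or
  Benjamini–Yekutieli (TF-binding-site-style, correlated sets);
  `Hit = max_i |overlap_i| / |T|` over the enriched terms. Significance
  of a tricluster's enrichment compares its per-enriched-term overlap
  ratios against those of `n_random` (default 100) uniform same-size
  gene lists with a two-sided Mann–Whitney–Wilcoxon test (a list with no
  enriched term contributes a single 0; a fully tied comparison returns
  p = 1).
* **δ estimation** — per repeat, k-means partitions genes by their
  sample-averaged time courses (`k_genes = ⌈√G⌉` by default), then
  partitions the time points of each gene group within one randomly
  chosen sample plane (`k_times = 2`); δ is the minimum MSR over all
  gene-group × time-group submatrices across (default) 100 repeats.
  Submatrices with fewer than 2 genes or 2 time points are excluded:
  a single-row or single-column submatrix has MSR identically 0 and
  would collapse the estimate. The cluster counts are heuristic
  defaults, configurable, not claims.
* **Replicate distances** — mean pairwise Euclidean distance between
  replicate profiles restricted to a tricluster's genes and time points,
  over member pairs vs over all pairs; distances use cells observed in
  both profiles.

## Eigengene

The eigengene of a tricluster is the right singular vector of the
largest singular value of the row-standardized gene × (sample·time)
matrix (sample-major flattening, fixed and consistent with the gene
profiles it is correlated against; the correlations are invariant to the
flattening convention). Although one convention in the literature
describes the singular values as arranged in non-decreasing order while
still taking the first vector, the dominant-vector reading is the only
one consistent with the eigengene concept (a one-dimensional summary
explaining maximal variance) and with near-1 key-gene correlations, so
it is used here and flagged rather than silently ignored. The SVD sign
ambiguity is resolved by orienting the eigengene so the sum of member-
gene correlations is nonnegative. Key genes are the member genes with
the highest Pearson correlation to the eigengene (default top 10, ties
by label).

## Synthetic benchmarks

The generator draws background cells i.i.d. uniform on [−2, 2] and
shifting parameters (Γ, α, β, η) i.i.d. standard normal — laws the
benchmark designs leave open; these defaults make implanted blocks
markedly more coherent than background (background MSR ≈ 1 vs block
MSR = 0) while spanning a comparable value range, which is what the
published δ ceilings discriminate on. Both choices are configurable and
recorded in the spec that every generated tensor carries in its
provenance. Noise scope differs by design: AD1 adds Gaussian noise to
the block cells only, AD2–AD4 to the whole tensor, following each
design's description; all blocks in a run share one σ. Gene index sets
are always disjoint across blocks; sample and time sets are disjoint
where capacity allows (AD2–AD4) and drawn independently where it does
not (AD1, where three 4-sample blocks share 5 samples). Explicit block
indices can be supplied instead (e.g. to construct gene-sharing blocks);
cell collisions are rejected.

What the generator does *not* emulate: heavy-tailed measurement noise,
gene–gene correlation structure in the background, batch effects,
scaling (multiplicative) patterns, and realistic missingness mechanisms
(masking is uniform). Perfect recovery on these benchmarks therefore
demonstrates correctness of the search and scoring machinery, not
performance on real microarray data.

## Problem sizes and defaults

Full-scale defaults mirror the benchmark settings: population 100, 100
generations, mutation probability 0.9, λ = 1.2. The package's own test
and acceptance runs use the reduced budget of population 30 and at most
30 generations with the convergence stop (tolerance 1e−4, patience 10),
which recovers the noise-free AD2/AD3 designs exactly in well under a
minute per dataset; the reduced budget is reported alongside every
score. δ values for the benchmarks are taken from the published
per-noise-level tables (`emoatrimax.BENCHMARK_DELTAS`).

## Known limitations

* Greedy repair is a heuristic: pathological seeds can descend to an
  infeasible floor-size candidate (the engine re-seeds them), and
  single-node deletion can occasionally discard pattern members when a
  seed is heavily contaminated.
* The archive keeps only mutually non-dominated solutions; of several
  equally perfect triclusters the larger dominates, so smaller perfect
  blocks may be represented in the population but not the archive.
  Recovery scoring is unaffected (it averages over the recovered set),
  but users wanting every Pareto-equivalent variant should inspect the
  traces or lower the generation cap.
* `f3` treats ties by fractional ranks inside the no-tie Spearman
  formula — adequate for continuous expression data, biased for heavily
  discretized data.
* MSR targets additive (shifting) coherence only; multiplicative
  (scaling) patterns are visible to it only insofar as prior
  normalization linearizes them.
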