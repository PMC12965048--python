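# Methods

`gcmkit` implements the quantitative half of group concept mapping (GCM):
starting from card-sort and Likert-rating records it produces the
similarity matrix, the two-dimensional nonmetric-MDS point map with its
stress value, hierarchical cluster solutions with bridging values, rating
statistics at statement and cluster level, and subgroup comparisons
(ladder graphs and go-zones). This note documents the models, the
numerical choices, and the limits of what the synthetic tests establish.

## Data model and validation

A study consists of a statement list (integer ids, text), long-format
sorts (`participant_id, pile_label, statement_id`), long-format ratings
(`participant_id, statement_id, rating`), and a participant attribute
table. Sorts must be partitions: duplicate placement of a statement is a
read error, incomplete coverage marks the record `incomplete`. Sorters
who ignore the sorting instructions are screened out before the
similarity analysis; because published studies state only that
rule-breaking sorts were rejected, the screening rule is an explicit,
configurable policy: reject a sort when (a) one pile holds every
statement, or (b) at least 90 % of its piles are singletons and the pile
count is at least 0.9 × S. Screened counts (accepted / rejected /
incomplete) are always reported.

The importance scale is ordinal with four categories. Source material is
ambiguous between 0–3 and 1–4 coding (category labels suggest 0–3, but
published statement means reach 3.90, which requires 1–4); the package
defaults to 1–4 and makes both ends configurable. Per-statement
statistics are available-case (no imputation), the SD is the sample SD
(n−1), undefined and reported missing for a single rater.

## Similarity and the cut-off

Each accepted sorter contributes a binary same-pile matrix; the group
similarity matrix `T` is their sum, so `T_ij` counts sorters who grouped
i with j. The cut-off zeroes off-diagonal entries `T_ij <= c`
(default c = 1): an agreement supported by a single sorter is not taken
into account. The cut-off is applied to raw counts, before any
normalisation. Dissimilarity for scaling is `D_ij = 1 − T_ij / n`,
bounded in [0, 1]; pairs zeroed by the cut-off therefore enter the
scaling at the maximal dissimilarity 1 rather than being omitted, which
keeps every pair's weight equal and makes the tie structure explicit.

## Point map: nonmetric MDS with Kruskal stress-1

The map minimises Kruskal's stress-1

    stress = sqrt( Σ_{i<j} (d̂_ij − d_ij)² / Σ_{i<j} d_ij² )

where `d` are configuration distances and `d̂` monotone (isotonic)
disparities fit to the rank order of `D`. Ties — which dominate the
off-diagonal after the cut-off, since most pairs sit exactly at D = 1 —
are handled by the primary (weak) approach: within a tie block the
disparities are free to follow the distances. Operationally each
isotonic fit sorts pairs by `(D, d)` and runs pool-adjacent-violators,
which implements exactly that convention. The tie convention matters:
an optimiser whose isotonic step orders tied dissimilarities arbitrarily
effectively penalises unequal distances inside the tie block and pulls
weakly-linked statements toward wrong neighbourhoods; the package
therefore runs its own SMACOF majorisation loop (disparities refit each
iteration, rescaled to fixed norm, Guttman transform with unit weights)
rather than delegating the fit.

Optimisation uses `n_restarts` (default 10) random starts seeded from a
single stream, so increasing the restart count extends the start set and
the best stress is nonincreasing in it; `max_iter` 300, convergence when
stress-1 improves by less than `tol` = 1e-6. The returned configuration
is canonicalised — centred, rotated to principal axes, each axis sign
fixed so the first statement's coordinate is nonnegative — because MDS
solutions are defined only up to isometry (and stress-1 additionally up
to scale). Identical inputs and settings reproduce the map bit for bit.
Small instances (≲ 8 points) have many local optima; oracle comparisons
on 6-point fixtures use 50 restarts.

## Clustering, expert moves, bridging

Clusters are formed from the 2-D map coordinates (the GCM convention),
by Ward agglomeration on Euclidean distances; a k-solution cuts the top
k−1 merges, so solutions across k are strictly nested. Cluster ids are
renumbered 1..k by lowest member statement id for stability. The package
emits candidate solutions over a configurable k-range for expert review
rather than selecting k automatically, mirroring practice: the final
solution and its labels are judgement calls. Individual statements may
then be moved between clusters ("expert moves"); moves are recorded in
the solution's provenance and a move that would empty a cluster is an
error.

Bridging quantifies sorting consistency: raw value
`b_i = Σ_j T'_ij · dist(i,j) / Σ_j T'_ij` over j ≠ i (map distances
weighted by surviving co-sort counts), min–max normalised to [0, 1]
across statements; a span at floating-point noise level counts as
all-equal and yields zeros. A statement whose co-sorts were all removed
by the cut-off is assigned its unweighted mean map distance and flagged.
The exact index used by proprietary GCM software is unpublished; this
weighted-mean-distance definition matches its documented range and
interpretation (low = grouped with neighbours) and should be read as an
approximation.

## Ratings and subgroup comparison

The cluster importance rating is the unweighted mean of its member
statements' means — the aggregation that reproduces the published
cluster table; a pooled (n-weighted) mode is available behind a flag.
Rankings sort by descending mean with ties broken by ascending statement
id, matching the observed ordering of tied entries in published
rankings. Machine-readable outputs carry two-decimal roundings of the
cluster means (full precision is kept internally), so a value computed
as 3.3067 is written 3.31 even when the corresponding published figure
was printed 3.30; comparisons against printed values always use the
full-precision mean with an absolute tolerance of 0.01, since the
printed inputs are themselves rounded.

Ladder graphs pair the k cluster means of two subgroups and report the
Pearson correlation over the k pairs (Spearman optional). Go-zones
classify statements into quadrants at each group's grand mean over the
displayed statement means (the scale midpoint is an alternative the
package does not use by default; the threshold choice is recorded in the
output metadata), boundary counting as high. Subgroup presets mirror the
typical comparisons: symptom-severity levels, treated vs untreated, and
psychotherapy-only vs any-medication.

## Synthetic studies

The generator plants K statement clusters (contiguous balanced blocks)
and derives everything else:

- **Sorters** start from the planted partition; with probability
  `p_split` one pile splits in two, with `p_merge` two piles merge, then
  every statement independently moves to a uniformly chosen other pile
  with probability ε. Defaults: S = 40, K = 5, 30 sorters, ε = 0.05,
  split/merge channels off. The split/merge channels model systematic
  lumpers and splitters and are opted into per experiment.
- **Raters** emit `round(importance + bias + noise)` clamped to the
  scale, with per-rater bias ~ N(0, 0.3) and per-rating noise
  ~ N(0, 0.5). True importances are per-cluster effects, by default
  spread over the upper half of the 1–4 scale (2.5 … 3.7), which
  produces the left-skewed rating distributions typical of importance
  data. Optional per-attribute shifts plant subgroup differences.
- **Participants** carry symptom-severity and treatment-experience
  attributes drawn with proportions like a typical sorting-and-rating
  roster.

A single seed drives everything; per-participant substreams use stable
spawn keys, so adding raters never changes the sorters' draws.

### What the synthetic checks do and do not show

At the default conditions the full pipeline (similarity → cut-off 1 →
MDS → Ward → cut at K) recovers the planted partition with adjusted Rand
index ≥ 0.9 in ≈ 93 % of seeds (typically 19–20 of 20), and per-statement
mean ratings converge to the true importances (max error ≤ 0.2 at 100
raters). Two empirical findings deserve emphasis:

- **Recovery is not monotone in ε.** Mean ARI across
  ε ∈ {0, 0.1, 0.3, 0.5} is ≈ 1.00, 0.98, 1.00, 0.76. At ε = 0.1 the few
  coincident mislabels that survive the cut-off form sparse,
  idiosyncratic cross-links that displace individual statements; at
  ε = 0.3 the surviving cross-links are dense and nearly uniform — a
  rank-neutral background that weak-tie nonmetric scaling ignores — and
  recovery returns to perfect before collapsing at ε = 0.5. The
  corresponding acceptance check asserts monotone degradation and is
  knowingly left failing rather than weakened.
- **Default-noise maps are cleaner than real studies.** Stress at the
  default ε = 0.05 averages ≈ 0.06, below the 0.1–0.4 range reported
  across real GCM studies; mislabel rates of 0.1–0.3 reproduce that
  range (mean stress 0.12 / 0.20). Real sorters disagree about concepts,
  not just labels, so the iid mislabel model understates disorder at
  small ε. The stress sanity-band test is therefore run at those
  realistic noise levels.

These checks validate the machinery, not the substance of any particular
study: the generator contains no semantics, its clusters are planted
rather than emergent, and passing tests say nothing about how real
participants sort real statements. Published quantities that depend on
the raw records (the study stress value 0.27, subgroup correlations,
statement SDs) cannot be recomputed because those records were never
deposited; the packaged reference table supports only the rating
arithmetic, which the pipeline reproduces to within the printed
rounding.

## Degenerate inputs and tie-breaks

Coincident map points are allowed (zero-height merges); a configuration
with all points coincident has undefined stress and is an error; an
all-tied dissimilarity matrix has stress exactly 0 for any non-degenerate
configuration (a weak-tie consequence). Exact-height ties in the naive
reference agglomerator break toward the lowest index pair; scipy's Ward
is deterministic and agrees on all tested instances (ties are
measure-zero for continuous coordinates). Empty subgroups, out-of-scale
ratings, unknown statement ids, and cut-offs at or above the sorter
count are errors, not warnings; isolated statements in bridging are
warnings, never silently dropped.

## Problem sizes

Simulation-based tests and the acceptance script use the default S = 40,
K = 5 study (20-seed recovery, 10-seed noise grids) and 6–8 point oracle
fixtures; these sizes were chosen so the complete evidence suite runs in
a few minutes while keeping the statistics stable.
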