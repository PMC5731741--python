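# Methods

This note documents the model behind `fgmd`, the parameters that matter,
the numerical choices made where the procedure leaves room, and what the
synthetic benchmark does and does not demonstrate.

## Co-expression network model

The object every stage works on is the complete weighted graph over the
feature universe with edge weights `a_ij = |corr(x_i, x_j)|`, the absolute
Pearson correlation of expression profiles.  Taking the absolute value
treats strong negative co-regulation as connectivity, which suits module
detection (anti-correlated members of a regulatory circuit belong
together) at the cost of conflating activation and repression.  The model
assumes profiles are continuous and roughly elliptically distributed —
appropriate for log-ratio microarray values and log-transformed RNA-Seq
abundances, not for raw counts.  Constant rows have undefined correlation
and are either rejected or dropped up front (configurable); the pipeline
drops them.

Preprocessing for tumour/normal designs follows the standard recipe: exact
zeros are replaced by the smallest positive value in the matrix (so logs
are defined; interpreting "the minimum non-zero value" as a single global
value, with a per-row variant available), then each tumour value is
normalized to `log2(tumor / mean(normals))` with the unmatched normal
samples averaged unweighted.  Isoform matrices can first drop a fraction
of the lowest-mean rows and any row that is zero in more than half of the
samples.  Ties at the drop-fraction boundary keep the lexicographically
smaller identifier, for determinism.

## Global network statistics

With connectivity `k_i = Σ_{j≠i} a_ij` over `n` genes:

* density `= Σ_{i≠j} a_ij / (n(n−1))` — the diagonal is excluded, since
  including the unit self-correlations would inflate the statistic that
  the `n(n−1)` denominator implies;
* centralization `= max(k)/n − density`, implemented exactly in this form
  even though it can be negative for flat networks; a variant normalizing
  by `n−2` ranges is deliberately not the default;
* heterogeneity `= sqrt(var(k)) / mean(k)`, with the population
  (divide-by-`n`) variance so identical rows give exactly zero.

## Quantile parameters

All pair-quantile parameters are expressed in "top percent" units exactly
as printed in parameter tables: `S = 0.005` means the top 0.005% of the
`n(n−1)/2` unordered off-diagonal pairs, `M_percent = 1.0` the top 1%.
The realized threshold is the value `t` such that `ceil(P·S/100)` pair
values are `≥ t`; pairs tied exactly at `t` are all admitted.  The run
manifest echoes both the percent and the realized value, so a manifest
suffices to reproduce a run.

## Seeding (step 1)

Degrees are counted in the candidate network of pairs above the seed
threshold.  `D_max` is the realized degree at rank
`ceil(n_ranked · 0.1/100)` (minimum rank 1) of the decreasing degree
ordering; genes tied with that degree survive.  Ranking is over genes with
non-zero candidate degree by default (`rank_over="all"` switches to the
full universe).  The degree window `[D_min, D_max]` is applied in a single
pass on the original candidate degrees: a gene keeps its surviving pairs
if its *own original* degree was in bounds, even when partners were
removed.  An iterative mode that re-evaluates degrees until stable exists
behind a flag but is not the default, because single-pass evaluation is
what "a paired gene can remain if it still satisfies the degree condition"
implies.  A pair is retained only if both endpoints survive: pairs are the
expansion unit and need two live seeds.

## Expansion (step 2)

`P_min` comparisons use strict `>` against `M`.  Per iteration the `k`
candidates with the largest `P_min` join **simultaneously**; candidates
tied with the k-th value are all admitted, so the result cannot depend on
an arbitrary ordering among equals.  The degree constraint on candidates
is an upper bound only: genes whose degree in the `a_ij ≥ M` graph exceeds
the top-0.1% degree value are never admitted (hubs passing `P_min`
everywhere would make all modules alike); applying `D_min` to candidates
would serve no such purpose and is not done.  Expansion of each pair is a
pure function, so pairs may be processed in any order or in parallel with
identical results; a 1000-iteration ceiling guards non-termination and is
reported as an error if hit.

## Adaptive tree cut (steps 3–4)

Both the merge and the split stage cluster with average linkage (UPGMA;
`complete` and `single` are available) and extract clusters with an
adaptive tree cut parameterized by `max_tree_height` (default 1),
`deep_split` (default true) and `min_module_size` (default 50).  The cut
implemented here is this package's own algorithm honouring the standard
contract of dynamic dendrogram cutting: every cluster has at least
`min_module_size` leaves, no merge above `max_tree_height` joins two
clusters, `deep_split` controls decomposition aggressiveness, and the
partition is independent of leaf input order.

Decomposition works on height bands.  Within a branch, the sorted internal
merge heights of a homogeneous cluster rise smoothly, while genuine
sub-clusters produce a wide empty band between the within-cluster merges
and the few merges joining the sub-clusters.  The branch is cut inside the
highest band whose width is at least 0.15 (deep) or 0.35 (shallow) of the
enclosing top-level branch's root height and whose cut yields at least one
component of `min_module_size` leaves; components are decomposed
recursively, and too-small components are left unassigned (outliers are
shaved, not absorbed).  Normalizing by the top-level branch height rather
than the local node height is what stops minute height differences deep
inside an already tight cluster from being read as structure.  Cutting a
band separates any number of sub-clusters at once — necessary because `m`
equally distinct clusters join at near-equal heights, leaving no pairwise
gap at the root.

Two consequences worth knowing: (i) with Jaccard dissimilarities bounded
by 1 and `max_tree_height = 1`, the height cap is vacuous at the merge
stage — the parameter is retained regardless; (ii) SPE modules left
unassigned by the merge cut each pass through as their own (flagged)
large module rather than being discarded, which preserves seed coverage at
the price of some near-duplicate large modules; the final size filter and
the duplication-ratio statistic make this visible.

At the split stage the gene dissimilarity is `1 − a_ij` (absolute PCC; a
signed variant is configurable).  Genes unassigned by the split cut are
dropped from final modules — the size filter removes fragments anyway.  A
large module smaller than `min_module_size` passes through unsplit,
flagged.

## Overlap extension

For each small module within one parent, outside parent genes are ranked
by their mean correlation to the members, and the best is added as long as
the module's mean in-module |PCC| does not decrease (adding a gene whose
mean correlation to members equals the current mean changes nothing and is
admitted).  The mean after adding gene *g* to a module with pair-sum *s*
over *P* pairs is `(s + Σ_m a_gm)/(P + |m|)`, so "does not decrease" is
exactly "the candidate's mean correlation is at least the current in-module
mean"; each parent gene is added at most once, bounding the loop by
`|parent|` steps.

## Validation battery

* **Permutation test**: `p = #{random_avg > module_avg}/N` over `N` random
  same-size gene sets drawn uniformly without replacement (the tested
  module's own genes are *not* excluded from the universe — under the null
  they are exchangeable with any other genes); Bonferroni across the tested
  modules.  A seed is mandatory.
* **Enrichment**: one-sided hypergeometric upper tail `P(X ≥ overlap)`
  with the universe set to the analysis gene count; gene sets are
  restricted to 3–300 members in the universe.  BH is applied per module
  across the terms of one collection (a global mode is available); a
  module counts as "enriched" with any term at `q < 0.05`.
* **Summary statistics**: module count, mean size, unique genes, mean
  occurrence (total membership / unique genes), mean in-module |PCC|, and
  a duplication ratio defined as (module count − distinct member sets) /
  module count — an explicit, documented convention, since "duplication"
  admits several readings.
* Module-size bounds default to 10–300 for genes and 10–500 for isoforms.

## Synthetic benchmark

`generate_block_expression` plants blocks of genes sharing a latent
Gaussian factor: a member of one block is `sqrt(r)·f_b + sqrt(1−r)·ε`, a
gene shared between blocks sums its factors plus noise and is rescaled to
unit variance, and background genes are iid `N(0, 1)`.  Two genes of one
block then correlate `r` in expectation, cross-block pure pairs correlate
0, and a shared gene correlates `sqrt(r)·sqrt(r/v)` with pure members of
each of its blocks (`v` its pre-scaling variance) — the planted analogue
of a gene serving two pathways.

The standard benchmark is 600 genes × 80 samples with five blocks of 40 at
`r = 0.8`, two blocks sharing 10 genes, run with `S = 0.5`, `D_min = 3`,
`k = 10`, `M` at the top 2% and `min_module_size = 15` — quantiles scaled
up because a 600-gene matrix has ~300× fewer pairs than a
transcriptome-wide one, and sized so the whole suite runs in seconds on
one CPU.  What passing shows: the seed→expand→merge→split chain recovers
planted co-expression structure and produces genuinely overlapping
modules.  What it does not show: performance on real data, where
correlations are heavy-tailed, blocks are unevenly sized and nested,
confounders induce global correlation, and the gene universe is 20–30×
larger.  The generator draws Gaussian factors and noise only; a
heavy-tailed option was considered and deferred.

Recovery at these study conditions is itself stochastic: with 80 samples a
block's latent factor occasionally draws an atypically low empirical
variance, its pairs miss the top-0.5% seed quantile, and that block never
seeds.  Across generator seeds roughly nine in ten replicates recover all
five blocks at Jaccard ≥ 0.7; the acceptance script therefore reports
recovery averaged over five replicate matrices rather than one draw.

## Numerical and degenerate-input conventions

* Correlation matrices are symmetrized (`(A + Aᵀ)/2`), clipped to `[0, 1]`
  and given an exact unit diagonal after `np.corrcoef`.
* All module exports sort members lexicographically and write floats with
  shortest round-trip representation; identical configuration and seed
  give byte-identical outputs.
* Empty seed networks are a warning-level outcome, not an error; an
  all-zero matrix, a constant row in strict mode, mismatched tumor/normal
  row sets, and p-values outside `[0, 1]` are errors.
* `min_module_size` larger than the item count unassigns everything, with
  a warning.

## Known limitations

* The adaptive tree cut is contract-compatible with, but not a port of,
  the published dynamic tree-cut procedures; on dendrograms without a
  clean band structure (chained or nested-gradient merges) its partitions
  will differ from theirs in detail.  Its gap thresholds (0.15/0.35) are
  design constants validated on planted partitions, not fitted quantities.
* Expansion cost is O(pairs × genes × iterations); at transcriptome scale
  with tens of thousands of seed pairs this is the dominant cost, and no
  parallel driver is shipped (expansion is pure per pair, so callers can
  parallelize trivially).
* The permutation test measures coherence only; it is blind to whether a
  coherent module is driven by a technical confounder.
* Isoform-level analysis reuses the gene-level machinery; nothing models
  the isoform-of-same-gene correlation structure explicitly.
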