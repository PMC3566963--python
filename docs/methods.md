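# Methods

This note documents the models and procedures implemented in metadiff, the
defaults and why they were chosen, what the synthetic benchmark does and
does not emulate, and the numerical conventions that make runs
reproducible.

## Hierarchies as leveled DAGs

An annotation database is represented as a directed acyclic graph with
ordered levels, leaf-first: level 0 holds the features quantified in
abundance files, higher levels hold coarser groupings. Every edge spans
exactly one level, and a node may have several parents (an ortholog in two
pathways). Node identity is the pair (name, level): the same string at two
ranks denotes two distinct nodes, because taxonomy names repeat across
ranks; non-leaf duplicates get level-qualified identifiers, while leaves
always keep their raw name so they match abundance files.

The canonical file dialect is the full-lineage row table (one row per
root-to-leaf path, header naming the levels), the form in which NCBI
taxonomy dumps and KEGG BRITE exports are commonly flattened; an edge-list
dialect is accepted behind a flag. Blank or `NA` cells inside a row mark
unranked gaps. Rather than letting an edge span two levels (which would
break the per-level aggregation walk), the parser inserts a placeholder
node named `"<child name> (unranked)"` at each gap level and records it in
the validation report. Root-side blanks are handled the same way, so every
leaf has a full-depth ancestry; this is what makes mass conservation hold
at every level even for partially ranked taxonomies. Writing a database
back to lineage form emits placeholders as blank cells, so a write/parse
round trip is the identity.

## Equal-split aggregation

The abundance of a higher node is the sum of its members' abundances; a
node with k parents contributes value/k to each. Splitting is applied *per
level step*, not over the set of target-level ancestors — the two differ on
DAGs with converging paths (a "diamond" leaf with two parents under one
grandparent ends up whole at the grandparent either way, but per-step
splitting is local, order-independent, and conserves column totals at every
intermediate level, which is the property the tests pin down). Aggregation
is linear, so counts and relative tables aggregate identically and
normalization commutes with aggregation under the bucket policy.

Features absent from the database go to a synthetic `Unmapped` node carried
through every level (default), keeping per-sample totals exact and the
unannotated fraction visible; a `drop` policy removes them and reports the
ids. Values are non-negative reals, not integers — equal splitting produces
fractions by construction.

## Metadata and grouping

Variables are typed automatically: numerical iff every non-missing value
parses as a finite real under strict full-string parsing (`1e3` yes, `3+`
no, `inf` no), else categorical. Missing markers are the empty cell, `NA`
and `NaN`, case-insensitive. Samples with a missing value in a predicate's
variable never satisfy the predicate — cohort filters exclude incomplete
records rather than erroring, matching how metadata-driven selection is
used in practice. Comparisons are strictly two-group; group specs must be
disjoint and non-empty, and overlaps are reported sample by sample.

## Two-group statistics

**Mann-Whitney U** is the default and recommended test, since relative
abundances are rarely normal. U is computed from midranks. For tie-free
data with n+m ≤ 20 the two-sided p is exact: the null distribution of U is
the coefficient sequence of the Gaussian binomial [n+m choose n]_q
(partitions of u into at most n parts each ≤ m), and
p = min(1, 2·P(U ≤ min(u, nm−u))). Otherwise a normal approximation with
tie-corrected variance and a 0.5 continuity correction is used. The ≤ 20
threshold keeps the exact path where enumeration is meaningful while the
approximation error is already negligible beyond it.

**Student's t** (pooled variance, df = n+m−2) is the parametric
alternative, with Welch behind a flag. Zero-variance degenerate cases are
reported explicitly (p = 1 for equal means, p = 0 flagged otherwise) rather
than propagating NaNs. Shapiro-Wilk, Bartlett and mean-centered Levene
diagnostics are advisory only — they never switch the chosen test, since a
data-dependent test choice invalidates the reported p-values.

**Multiplicity.** The raw p-vector is adjusted once per comparison (m =
number of features tested): Bonferroni min(1, m·p) or Benjamini-Hochberg
step-up (sort ascending, q_(i) = p_(i)·m/i, enforce monotonicity from the
largest rank down, cap at 1). The implementation is cross-checked in the
tests against a direct step-up oracle and statsmodels.

**Fold change** is (mean_A + ε)/(mean_B + ε) on group mean relative
abundances; the absolute form max(FC, 1/FC) ≥ 1 treats enrichment and
depletion symmetrically. The default pseudocount ε is half the smallest
nonzero group mean in the comparison — small enough not to distort
abundant features, large enough to keep zero means finite; ε = 0 is allowed
and reports infinite fold change (which always passes the fold-change
filter). Result filtering is the conjunction of three thresholds: adjusted
p (raw p when no adjustment was chosen), minimum absolute fold change, and
minimum mean relative abundance in at least one group.

**Correlation** with a numerical variable is Spearman by default
(consistent with the rank-based default test; Pearson by flag), excluding
missing values pairwise; features with fewer than 3 complete pairs or zero
variance are flagged unavailable and excluded from the adjustment rather
than contributing meaningless coefficients.

## Multivariate analysis

**PCA** centers the samples × features matrix (optional unit-variance
scaling, off by default — standardizing rare, noisy features inflates
their influence) and decomposes by SVD; explained fractions equal the
eigenvalue fractions of the sample covariance matrix, components are capped
at min(n_samples − 1, n_features), and each component's sign is fixed so
its largest-magnitude loading is positive, making outputs deterministic.

**Hierarchical clustering** agglomerates from the full pairwise distance
matrix (Euclidean, or correlation = 1 − Pearson r with zero-variance rows
rejected by name) under single, complete or average linkage via
Lance-Williams updates. Exact distance ties are broken toward the pair
with the lowest original cluster indices, so merge lists are fully
deterministic; the defaults (Euclidean, average/UPGMA) are the common
choice for community profiles. The merge list uses the standard
convention (leaves 0..n−1, merge i creates cluster n+i); leaf order is the
dendrogram traversal with the earlier-created subcluster first.

## Figures

All plotting is headless (Agg backend forced at import). SVG output uses a
fixed hash salt and suppressed timestamps, PDF suppresses its creation
date, so identical calls are byte-identical — which makes figure outputs
testable and runs reproducible. Bar charts show group mean relative
abundance with standard-error bars (a deliberate choice; error-bar
semantics vary across tools), ordered by adjusted p. Area profiles stack
the top-k features per sample with the remainder lumped as "Other" so
stacks always sum to 1. Pie slices under 1% merge into "Other" by default.

## Synthetic benchmark

The generator emulates a two-group shotgun-metagenomics comparison at desk
scale. The hierarchy is a random leveled DAG: a tree skeleton with
round-robin primary parents (so every parent is reachable from a leaf)
plus, with probability `multi_parent_fraction`, one extra parent per node.
Counts are Dirichlet-multinomial: leaf base proportions from a symmetric
Dirichlet (concentration 0.5, giving the skewed, heavy-tailed rank
abundance curves typical of gut communities), spiked leaves' proportions
multiplied by the fold factor in one group and renormalized, optional
per-sample gamma weighting for overdispersion, multinomial sampling at
fixed depth. One numerical covariate is constructed as 0.8·z + 0.6·noise
around a designated feature's standardized relative abundance, giving
Pearson ρ ≈ 0.8 in expectation.

Defaults — 200 leaves over 3 levels, branching 4, multi-parent fraction
0.1, 20 samples per group, 10 leaves spiked at fold 4, depth 50,000,
dispersion 0 — define the standard benchmark used by the acceptance
checks; the null configuration sets the spike fold to 1 with 10 samples
per group and 500 features.

What the generator does *not* emulate: zero-inflation, phylogenetically
structured correlation between features, read-level error, batch effects,
or uneven sequencing depth. Passing the recovery tests therefore shows the
pipeline's statistics and bookkeeping are correct under a clean
compositional model, not that any real cohort's biology would be
recovered.

### Compositional artifacts and the fold-change filter

Multiplying spiked proportions and renormalizing necessarily scales every
*other* feature by 1/(1 + (f−1)s), where s is the spiked leaves' mass
share. With 10 of 200 leaves spiked (E[s] = 5% by exchangeability,
whatever the Dirichlet concentration) the non-spiked features shift
systematically by ~10–15% between groups — a real distributional
difference that a rank test correctly detects at depth 50,000 with 20
samples per group. These compositional artifacts are bounded well below
two-fold, while fold-4 spikes remain near 4 after renormalization. The
discovery rule used in the pipeline-level recovery check is therefore the
package's full filter — BH q ≤ 0.1 *and* absolute fold change ≥ 2, the
conventional minimum effect size in differential abundance work — which
separates the two populations cleanly (typically 10/10 true spikes, 0
false positives per seed). This is also the practical lesson the benchmark
encodes: with relative data, significance filtering alone conflates
compositional spillover with genuine change; an effect-size filter is not
cosmetic.

## Numerical conventions and determinism

Relative tables tolerate 1e-9 relative deviation in column sums; all-zero
columns stay zero and are reported. Result tables are sorted by ascending
adjusted p with feature-id tie-breaks, so output files are byte-stable.
All randomness flows through `numpy.random.default_rng` seeded from
explicit configuration; the same seed reproduces every file exactly. Run
logs record the package version, all parameters and input checksums —
everything needed to reproduce a run — and deliberately omit timestamps.

Problem sizes in the test and acceptance suites (hierarchies up to a few
hundred leaves, hundreds of features, tens of samples, 10-seed recovery
sweeps) were chosen to exercise every code path at desk scale; all scale
linearly in features × samples except agglomerative clustering, which is
cubic in the number of clustered items and intended for post-filtering
heatmaps (≲ a few hundred items).

## Known limitations

- Two groups only; no paired designs, ANOVA/Kruskal-Wallis, permutation
  tests or zero-inflated count models.
- No compositional (CLR/ILR) transforms, rarefaction, or upstream
  read-processing; inputs are assumed to be already-annotated abundances.
- The equal-split rule is a modeling convention for multi-membership, not
  an inference about true assignment of reads to pathways.
- Exact Mann-Whitney p-values are unavailable in the presence of ties
  (midrank approximation is used instead), as in most implementations.
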