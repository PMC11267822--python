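# Methods

This note records the statistical model behind each stage of `regdiff`,
the defaults and why they were chosen, the numerical conventions, and the
limits of what the synthetic-cohort tests demonstrate.

## Integrated differential expression

For every gene, three statistics measure the A-vs-B contrast on log2-scale
expression: Welch's unequal-variance t, the standardized Wilcoxon rank-sum
Z with tie correction, and the log2-median-ratio (difference of group
medians). Welch rather than pooled-variance t is the default because the
target cohorts have unequal group sizes; a pooled variant would change
little but Welch is the safer general choice. All three are signed A minus
B, where (A, B) are the two group labels in sorted order.

**Permutation null.** Group labels are randomly reassigned (group sizes
preserved, identity permutation not excluded) and all three statistics are
recomputed; by default null values are pooled across genes. Pooling trades
the per-gene exchangeability assumption for far finer p-value resolution —
with 10,000 permutations a per-gene null cannot go below p = 1e-4, which is
useless for FDR control over thousands of genes; pooled mode is therefore
the default and a per-gene mode is available (`pooled=False`). Each
permutation draw is pooled together with its negation: the permutation
group is closed under complementation, which negates all three statistics,
so the symmetrized pool is the exact null and two-tailed p-values become
exactly invariant under swapping the group labels. Pools larger than a
memory budget (5e7 values per statistic) are uniformly subsampled, logged.

**Empirical p.** Two-tailed with add-one smoothing,
p = min(1, 2·min(#{null ≥ obs}+1, #{null ≤ obs}+1)/(N+1)); never zero, so
the normal-quantile transform below is always finite.

**Combination.** The three p-values are mapped to signed normal quantiles
z_i = sign_i·Φ⁻¹(1−p_i/2) (the sign of the observed statistic; a statistic
of exactly 0 contributes z = 0) and averaged with a 1/√3 scale. The three
statistics are strongly dependent — they measure the same contrast — so
under the null the combined z is wider than standard normal and the
closed-form p 2(1−Φ(|z|)) would reject ~25% of null genes at nominal 5%.
The combined p is therefore calibrated against the permutation null of the
combined z itself: each aligned null triplet (t, rank-sum, LMR from the
same permutation and gene, dependence intact) is pushed through the
identical empirical-p + signed-quantile transform, and the observed z is
ranked within the resulting symmetrized pool. `stouffer_combine` still
exposes the closed-form construction for callers that need it; the
pipeline reports the calibrated p. On all-null synthetic data the
calibrated p rejects 4.7% at α = 0.05 and 1.0% at α = 0.01 (recomputed by
the test suite and acceptance script).

**FDR.** Storey q-values with the fixed-λ estimate
π̂0 = min(1, #{p > λ}/((1−λ)m)), λ = 0.5 — the simplest published variant;
no spline smoothing. With π̂0 = 1 this is exactly Benjamini–Hochberg, a
property the tests assert.

**DEG rule.** q < 0.05 and |LMR| above the 95th percentile of pooled
|null LMR| from 1,000 label permutations. The data-driven cutoff adapts
the effect-size threshold to the cohort's noise level; it is 0 for a
constant matrix and non-negative always. Zero-variance genes get all
statistics set to 0 and are flagged; they can never be DEGs.

## Preranked GSEA

Ranking is by descending LMR with lexicographic tie-breaking (logged), so
results are bit-reproducible. The ES is the running-sum extremum: hits
increment by |score|^w normalized over hit scores (w = 1 default, matching
the convention of the standard GSEA software; w = 0 gives the literal
unweighted KS statistic), misses decrement by 1/(N−k). Significance uses
gene-tag permutation — random same-size gene sets — because the module
operates on a precomputed ranking; phenotype permutation is out of scope.
p = (#{same-sign null with |ES_null| ≥ |ES|}+1)/(#same-sign+1), NES = ES
divided by the same-sign null mean |ES|. If all hit scores are exactly 0
under w = 1 the hit increment falls back to unweighted. The leading edge
collects hits at or before the extremum (after it for negative ES).

## Master regulators

The null draws |DEG| genes uniformly *without replacement* from the
measured universe, so the marginal null count for each regulon is exactly
hypergeometric — the test suite exploits this as an independent oracle and
requires agreement within 3 Monte-Carlo SEs at 100,000 draws. The
empirical p is one-tailed with add-one smoothing; BH (via statsmodels)
controls the FDR across TFs. The universe defaults to the genes present
in the expression matrix; "number of potential target genes larger than 5"
is applied to targets among the DEGs (the quantity the test counts), with
a switch for the universe-count reading. Selection sorts by (FDR,
empirical p, TF name) — a fully deterministic tie-break — and truncates to
the top 10. The DEG set defaults to the union of both directions;
per-direction analyses call the same operation on each directional set.

## TF activity and the co-regulation network

Activity of a gene set in sample s is Σ_{g} (x_gs − mean_g)/sd_g / √m over
the m usable member genes, with population (n) standardization computed
over all samples jointly — group-blind, so group differences remain
interpretable, and the per-set scores sum to zero over samples by
construction. The 1/√m scale keeps scores comparable across regulon sizes
and gives unit variance under independence. Zero-variance members and
members absent from the matrix are dropped with a logged count; a set with
no usable members is an error.

Network semantics: node size |regulon ∩ DEG|/|DEG|; node color the
regulon-activity mean difference (A minus B); edge weight
|regulon_i ∩ regulon_j ∩ DEG|/|DEG| (the denominator is the full DEG set,
read literally from the quantity's definition; a union-of-regulons
denominator was considered and rejected). Zero-weight edges are omitted.
Export is GraphML or JSON node-link via networkx; attributes round-trip
losslessly.

## Cohort statistics

Pearson chi-square carries **no continuity correction** anywhere: the
uncorrected closed form is what reproduces the printed p-values of the
published clinical table this module is validated against (0.614, 0.003,
0.315, 0.733). The Wilcoxon rank-sum normal approximation *does* use the
continuity correction (plus tie correction): with it, the approximation
tracks the exact enumeration within |Δp| < 0.011 already at balanced
n = 8, whereas without it the error reaches 0.047; exact enumeration is
used automatically for tie-free samples with combined n ≤ 20. Fisher's
two-sided p uses the point-probability rule. The DEG-overlap test builds
the 2×2 membership table over the universe and applies the uncorrected
chi-square; note its p-value is *discrete* (one atom per overlap count),
so calibration is asserted against the exact hypergeometric-overlap law,
not a continuous uniform.

## Synthetic cohort generator

Linear-additive model on the log2 scale:

    x[g,s] = baseline_g + Σ_t R[g,t]·a[t,group(s)] + δ_g·1[group=A] + ε,
    ε ~ N(0, σ_g²)

Baselines are uniform on (4, 12) log2 units (typical microarray intensity
range); σ_g defaults to a global 0.5 log2 units (`baseline_sd_range` draws
per-gene SDs uniformly when set). TF activity is a latent per-group
constant (`tf_activity_shift` in group A for active TFs, 0 otherwise), not
a per-sample random effect, so expected activity-score differences have
the closed form δ_a·√m/σ_total used in the tests. Regulons chain a shared
target block between consecutive TFs (`regulon_overlap`), guaranteeing
non-trivial co-regulation edges; active TFs are the first
`n_active_tfs` in the chain, so their shared targets are co-regulated
differential genes. Directly planted DE genes split half up-in-A, half
up-in-B. The ground truth records *every* gene with nonzero expected
group difference — planted genes and active-TF targets — with its
expected effect size.

Defaults (2000 genes, 60+60 samples, 10% DE at δ = 1.0, noise SD 0.5,
10 TFs with 3 active at shift 0.8, regulons of 30–60 targets with 30%
overlap) are a desk-scale stand-in for a several-hundred-sample cohort;
the acceptance checks that must finish on one CPU use 1,000 label
permutations for the differential null and cutoff and the full 100,000
draws for the master-regulator null. Stratum frequencies default to
Gleason-category {lt7 0.25, eq7 0.55, gt7 0.20} and molecular subtype
{PCS1 0.02, PCS2 0.59, PCS3 0.39}, mirroring the composition of the kind
of cohort the generator emulates; strata are drawn independently of group.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: probe-level artifacts, intensity-dependent
variance, batch effects, correlated noise between genes beyond the shared
TF term, ancestry-linked covariate structure, and non-additive regulation.
Recovery results on synthetic cohorts demonstrate correctness of the
machinery under the stated model, not performance on any real cohort.

## Numerical conventions and degenerate inputs

Single RNG stream per entry point, seeded explicitly; sub-streams spawned
via `numpy.random.SeedSequence` so stages are independently reproducible.
All tabular output is TSV with floats at 6 significant digits. Duplicate
gene rows collapse to the first occurrence with a warning (configurable to
mean); genes with missing values are dropped with a logged count (the
permutation machinery assumes complete rows). Gene identifiers match by
exact string comparison after whitespace trimming — no symbol aliasing.
Empty p-value vectors, empty universes, sets without overlap, strata with
a group below 2 samples, and zero contingency margins all raise (or, for
stratified comparisons, flag the row as NA) with messages naming the
offending object.

## Known limitations

- Pooled nulls assume cross-gene exchangeability of the null statistics;
  heteroskedastic genes weaken this (per-gene mode exists but caps p
  resolution at 1/(2·n_perm)).
- The calibrated combined p inherits Monte-Carlo granularity from the
  permutation count; q-values near the decision boundary move between
  reruns with different seeds.
- GSEA significance is per-set only; no FDR across sets is computed.
- Activity scores assume additive, sign-free regulation (no mode-of-
  regulation weights); repression dilutes rather than reverses a score.
- No covariate adjustment, paired designs, or moderated-variance
  statistics.
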