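# Methods

This note documents the models, conventions and numerical choices behind
`ccnet`, in the order the pipeline applies them, followed by the generative
model of the synthetic cohorts and the package's known limitations.

## Intake data and binarization

The unit of analysis is a participant × food-group matrix of daily intake in
g/day. Validation is strict: missing values, negative values and duplicate
identifiers are rejected with the offending cells named — intake is never
imputed, because a complete FFQ administration is assumed. Item-level tables
are collapsed to food groups by summation against a user-supplied item→group
mapping (such mappings are instrument-specific and deliberately not
hard-coded); aggregation conserves each participant's total grams.

A participant counts as a *consumer* of a group when their intake is strictly
greater than the group's first quartile computed over the whole cohort
(linear interpolation between order statistics; both the quantile level and
the interpolation rule are configurable). Two consequences anchor the
convention: a tie-free column marks exactly 75 % of participants
(1125 of 1500), and a column whose first quartile is zero — any group not
consumed by more than a quarter of the cohort — marks exactly its non-zero
intakes. The rule is rank-based, hence invariant under any strictly
increasing transform of a column. Column sums of the indicator matrix are the
*consumption scores* used as node weights.

## Edge validation

All 780 pairs of 40 groups are screened by split-half resampling
(`EdgeValidationConfig`):

* `n_repeats = 100` random splits into a test and a validation half
  (`split_fraction = 0.5`; the split ratio is a package choice);
* per half, Spearman correlation with mid-ranks for ties and the
  t-approximation p-value (the scipy convention); constant columns give an
  undefined correlation and can never form an edge;
* a pair survives only if significant at `alpha = 0.05` *and* positive in
  both halves of every repeat (one failing repeat kills the edge — the
  strict reading), and the mean test-half correlation exceeds
  `r_threshold = 0.2`, which becomes the edge weight.

No multiplicity correction is applied across the 780 pairs; the all-repeats
consistency requirement is the multiplicity control in this design. The
significance level, threshold, split fraction and positivity requirement are
all configurable. Rows are internally sorted by participant ID before the
seeded splits are drawn, so results are invariant to the row order of the
input file. Negative-correlation edges are out of scope.

Network descriptives are computed on the unweighted topology: degree is the
raw edge count (the hub is the maximum-degree node), betweenness is
normalized by (N−1)(N−2)/2, and closeness uses the Wasserman–Faust
within-component scaling; isolated nodes score zero on all three. Module
"density" is *connections per node* — internal edges divided by module size —
not the conventional 2m/n(n−1); this matches how module density is reported
in the dietary-network literature this package serves.

## Modules and modularity

Communities come from asynchronous label propagation: every non-isolated
node starts with a unique label; nodes are visited in a fresh random order
each sweep and adopt the most frequent label among their neighbours, ties
broken uniformly at random; a node whose label is already modal keeps it;
the run stops after a changeless sweep. Isolated nodes belong to no module,
and an edgeless graph is an error. Because single runs are stochastic, the
pipeline takes a consensus over `community_runs = 50` seeded runs: each
result is canonicalized (modules ordered by smallest member, so module
relabelings collapse), and the most frequent canonical partition wins;
frequency ties are broken by higher modularity, then by lexicographic
canonical form, making the consensus deterministic given the seed.

Partition quality is Newman modularity Q = Σ_c (e_cc − a_c²) on the
unweighted graph. If a consensus ever yields more than two modules, the
membership analysis proceeds on the two largest (the member-comparison
design is intrinsically two-group); the full partition is still reported.

## Participant membership and module naming

Membership is a hypergeometric enrichment test per participant and module.
The population is the N food groups that carry a module label (isolated
groups are excluded; including them is a configurable alternative); the
participant's draws are the n labelled groups they consume; successes are
the k consumed groups inside the candidate module of size K. The membership
p-value is the upper tail P(X ≥ k) with X ~ Hypergeometric(N, K, n), and a
participant is a member when p < 0.1 (`membership_threshold`). A participant
enriched in exactly one module receives that module's label; enrichment in
both or neither collapses to *other*. A participant consuming no labelled
group has p = 1 for every module. This construction is the only one that
uses the binarized matrix directly and makes the three-way labelling
well-defined.

Which module is "unhealthy" is not derivable from topology. The package
names the module whose enriched members carry the higher mean CAP score
unhealthy (falling back to the larger module if a module has no members);
with real data an analyst can override the naming by inspecting the food
groups, as is standard practice.

Member groups are compared with the independent two-sample t-test (pooled
variance by default; Welch available) for age, energy, BMI and CAP, and
with the Pearson chi-square test (no continuity correction) for sex and the
steatosis-grade distribution. Steatosis grades follow the CAP cutoffs
238/260/293 dB/m: S0 below 238 (normal liver), S1 and S2 on left-closed
intervals, S3 at and above 293 — 238 itself grades S1, 293 itself S3, which
keeps the grading consistent with the disease stratification below.

## Differential and age-trend networks

Stratum-differential networks rerun the *entire* validated pipeline per
stratum with identical configuration, then take the symmetric difference of
the two edge sets; every surviving edge is tagged with its single stratum of
origin and weighted 1, and node weight is the degree within the differential
network. Strata: male vs female for sex; CAP < 238 dB/m (normal) vs
≥ 293 dB/m (steatosis) for disease, with the 238–293 band in neither
stratum. A stratum too small for split-half validation is an error naming
the stratum. Note that even strata drawn from one generative law produce a
non-empty differential network: pairs whose population correlation sits near
the 0.2 threshold flicker in and out of the halved-sample networks, so
differential edges should be read as candidates concentrated among weakly
validated pairs.

The age-trend network uses three strata — under 30, 30–50 (both bounds
inclusive in the middle), over 50 — and single full-stratum Spearman
coefficients per pair (the 100-repeat machinery validates the base CCN;
trend deltas compare one coefficient per stratum). A pair is kept when it is
significantly positive in the oldest stratum (configurable to all strata)
and either increases strictly across the three strata or rises by more than
`trend_delta = 0.25` from youngest to oldest. Edges are tagged within- or
between-module against the reference partition and carry the rise as
`trend_magnitude`. Trend edges are not required to be edges of the pooled
CCN (a configurable choice: the trend criterion is a statement about
stratum-wise coefficients, not about pooled validation).

## Module-related cliques

All maximal cliques of the CCN with at least `clique_min_size = 4` nodes
whose members share one module label are tested: a participant is a clique
consumer when their indicator is 1 for *every* clique member, and the 2×2
table (consumes-all vs not × unhealthy vs healthy member) is tested by
Pearson chi-square without Yates correction (configurable); cliques spanning
modules are skipped. P-values are Benjamini–Hochberg adjusted across the
tested cliques and an adjusted p < 0.05 marks the clique module-related.
Tables with an expected cell below 5 are flagged (`low_expected`) but still
tested, since small healthy-consumer counts are the interesting cases.

## Synthetic cohorts

The generator (`synthetic.py`) emulates the features the analysis relies
on, with defaults frozen as the package's study conditions:

* **Size and demographics.** 1500 participants; 62 % female; age
  truncated-normal 40.9 ± 11.6 on [20, 60] years.
* **Latent adherences.** Bivariate standard normal (H, U) with
  ρ_HU = 0.2; U additionally rises with standardized age (β = 0.5) and in
  women (β = 0.8), so the unhealthy pattern concentrates in older women and
  its block correlates slightly more strongly than the healthy one.
* **Intake.** 40 groups: 20 unhealthy-block, 18 healthy-block, 2 neutral.
  X = B · exp(μ + λA + σε) with B ~ Bernoulli(1−π) independent masking —
  zero-inflated and right-skewed (mean well above median), like FFQ-derived
  intake. Loadings follow a hub/mid/periphery hierarchy per block
  (λ = 0.9/0.65/0.45 unhealthy, 1.05/0.75/0.5 healthy, σ between 0.95 and
  1.15, π between 0 and 0.25 plus a margarine-like neutral group at
  π = 0.91): only pairs involving a well-loaded group clear the 0.2
  threshold, so recovered modules are sparse core-periphery structures of
  roughly 3–4 connections per node rather than near-complete blocks, and
  the two neutral groups come out isolated.
* **Outcomes.** CAP = 233 + 25·U − 12·H + N(0, 40²) dB/m (≈ 46 % of the
  cohort below 238, ≈ 17 % at or above 293); energy and BMI rise with U.
* **Ground truth.** The planted partition, each participant's dominant
  adherence, and the *population* Spearman correlation of every within-block
  pair in closed form: log-intakes are jointly normal with correlation r, a
  bivariate normal has grade covariance arcsin(r/2)/(2π), and independent
  zero-masking scales it by (1−π₁)²(1−π₂)² while inflating the marginal
  grade variances by the zero point mass — the value mid-rank sample
  Spearman converges to (verified against Monte Carlo). Pairs with
  population ρ ≥ 0.3 form the "strong" set that recovery tests must find.

What the generator does **not** emulate: nutrient composition, negative
correlations between food groups, seasonal or longitudinal intake dynamics,
measurement error of the FFQ instrument, and any real cross-block bridge
structure (the planted cross-block correlations sit below the edge
threshold). Passing recovery tests therefore show that the pipeline finds
block-correlation structure of realistic strength in zero-inflated skewed
data at realistic sample sizes — not that any specific real cohort would
yield the same networks.

## Numerical choices and degenerate inputs

* Mid-ranks for ties throughout; Spearman p-values via the t approximation.
* Constant columns: undefined correlation, never an edge; all-zero intake
  columns binarize to all-zero (not an error).
* Both member groups need ≥ 2 participants for the t-test; equal constant
  groups return t = 0, p = 1 rather than NaN.
* Per-stage seeds derive from the single run seed by hashing the stage name
  (BLAKE2, reduced below 2³¹), so stages are independently reproducible.
* Test and acceptance problem sizes: oracle checks run on graphs of ≤ 12
  nodes against exhaustive enumeration (exact to 1e−12 where real-valued);
  recovery checks run the full 1500 × 40 pipeline across 20 generator
  seeds, and the stratum-exclusive differential check uses two 600-person
  strata — sizes chosen to match the study conditions while keeping the
  suite fast.

## Limitations

* Only positive co-consumption is modelled; substitution patterns (negative
  correlations) are explicitly out of scope.
* The all-repeats significance rule is conservative and sample-size
  sensitive: halving a cohort prunes weak edges aggressively, which inflates
  symmetric-difference networks between small strata.
* The hypergeometric membership treats consumed groups as exchangeable
  draws; it ignores how *much* of each group is consumed beyond the
  consumer indicator.
* Label propagation on graphs with strong bridges can merge modules in a
  minority of runs; the consensus mitigates but does not eliminate this,
  which is why the partition, not a single run, is the reported object.
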