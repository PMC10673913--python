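# ccnet — co-consumption network analysis of dietary intake

`ccnet` analyses dietary patterns as a network. Given a participant × food-group
intake matrix (g/day, typically derived from a food frequency questionnaire) and
a covariate table (age, sex, BMI, energy intake, and the FibroScan CAP score in
dB/m as a hepatic-steatosis proxy), it builds the **co-consumption network
(CCN)**: food groups are nodes, and two groups are connected when participants
who eat more of one reliably eat more of the other. On top of the network it
detects healthy/unhealthy food modules, assigns each participant to a module by
enrichment of their consumed foods, and contrasts network structure between
cohort strata (sex, liver status, age). It is aimed at nutritional
epidemiologists who want the *combination* component of a dietary pattern — not
just variety and quantity — in a single inspectable object.

## Method

For food groups *g*, *h* with intakes *X_g*, *X_h* over *n* participants:

- **Edge validation.** The cohort is split at random into a test and a
  validation half, 100 times. An edge *g–h* is kept only if the Spearman
  correlation ρ(X_g, X_h) is significant (two-sided, α = 0.05) and positive in
  *both halves of every repeat*, and the mean test-half correlation exceeds the
  soft threshold 0.2. The edge weight is that mean; the node weight is the
  *consumption score* — the number of participants whose intake exceeds the
  group's first quartile (strict inequality, so a tie-free column marks 75 % of
  the cohort and a zero-inflated column marks exactly the non-zero consumers).
- **Modules.** Asynchronous label propagation, consensus over 50 seeded runs
  (most frequent canonical partition; ties broken by Newman modularity
  Q = Σ_c (e_cc − a_c²)).
- **Participant membership.** With N module-labelled groups, module M of size
  K, a participant consuming n labelled groups of which k lie in M is a member
  of M when the hypergeometric upper tail P(X ≥ k), X ~ HG(N, K, n), is below
  0.1. Members of both or neither module are labelled *other*. Member groups
  are compared by t-test (age, energy, BMI, CAP) and chi-square (sex,
  steatosis grade S0–S3 at CAP cutoffs 238/260/293 dB/m).
- **Differential and trend networks.** Stratum-specific CCNs (male/female, or
  CAP < 238 vs ≥ 293 dB/m) are compared by symmetric difference, each edge
  tagged with its stratum of origin. The age-trend network keeps pairs whose
  per-stratum correlation rises across the < 30 / 30–50 / > 50 age strata
  (strict monotone increase, or a > 0.25 jump from youngest to oldest).
- **Module-related cliques.** Maximal cliques (size ≥ 4) lying wholly inside
  one module are tested for differential consumption (consumes-every-member)
  between unhealthy and healthy members by 2×2 chi-square with
  Benjamini–Hochberg FDR at 0.05.

Because real FFQ + FibroScan cohorts are rarely deposited, the package ships a
synthetic cohort generator with two planted food-group blocks driven by latent
"adherence" factors coupled to age, sex, energy, BMI and CAP, plus exact
closed-form population Spearman correlations for every planted pair — so every
pipeline stage has a ground-truth recovery test.

## Worked example

```python
import ccnet

spec = ccnet.default_cohort_spec(seed=1)          # 1500 participants, 40 groups
intake, covariates, truth = ccnet.generate_cohort(spec)
result = ccnet.run_all(intake, covariates, ccnet.RunConfig(seed=1))
print(result.summary)
```

On this cohort the run prints (abridged):

```
n_nodes = 40            n_edges = 138
isolated_nodes = ['Margarine', 'Poultry']
hub = Meat.Visceral     hub_degree = 19
modularity = 0.495
module_sizes   = {'healthy': 18, 'unhealthy': 20}
module_density = {'healthy': 3.44, 'unhealthy': 3.80}   # connections per node
membership_counts = {'healthy': 232, 'other': 1027, 'unhealthy': 241}
mean_cap = {'unhealthy': 276.5, 'healthy': 203.4}
cliques_tested = 23     cliques_related = 23
```

Reading: the 40 food groups form one unhealthy module of 20 groups and one
healthy module of 18, with the two neutral groups isolated; the unhealthy
module is the denser one. 241 participants are enriched consumers of the
unhealthy module and their mean CAP (276.5 dB/m) is far above that of the 232
healthy-module members (203.4 dB/m) — the planted direction of effect. All 23
module-homogeneous cliques differ significantly in consumption between the two
member groups after FDR correction, e.g.

```
clique_size  members                                   module     pct_unhealthy  pct_healthy
8            Cereals.Refined/Egg/Mayonnaise/...        unhealthy  51.9           0.9
```

The same analysis is available from the shell:

```bash
ccnet simulate --n 1500 --seed 1 --out cohort/
ccnet run-all --intake cohort/intake.csv --covariates cohort/covariates.csv \
      --seed 1 --out results/
```

which writes `edges.csv`, `nodes.csv`, `network.graphml`, `membership.csv`,
the comparison tables, the differential/age-trend networks, `cliques.csv` and
`summary.json`. Single stages (`binarize`, `build`, `communities`,
`membership`, `compare`, `differential --by {sex,disease}`, `age-trend`,
`cliques`) are exposed as subcommands.

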