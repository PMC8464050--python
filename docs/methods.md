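# Methods

## Ontology model and information content

The ontology is a single-rooted DAG of phenotype terms under `is_a`
edges; other relation types are ignored. Obsolete terms are dropped at
parse time and their identifiers (via `alt_id` / `replaced_by`) are
registered as alternate-identifier redirects, so annotations referencing
them still resolve. Cycles, multiple roots and dangling `is_a` targets are
fatal parse errors.

Annotations are stored minimally (no term is an ancestor of another in
the same individual's set) and expanded to the inclusive ancestor closure
— the true-path rule — whenever frequencies or term presence are needed.
Frequencies are computed on closures rather than raw annotations: without
propagation the root would not reach frequency 1, and information content
would not be monotone along edges. With it, `IC(t) = −ln f(t)` satisfies
`IC(root) = 0` and `IC(parent) ≤ IC(child)` for every edge.

Numerical choices:

* **Log base.** Natural log. Lin similarity is a ratio of ICs, so the
  base cancels; nats are reported for definiteness.
* **Zero-frequency smoothing.** Terms absent from the corpus get
  frequency `1/(2·corpus_size)`. This keeps external patients' terms
  (never seen in the reference corpus) comparable instead of infinitely
  informative; the factor 2 places unseen terms strictly below the rarest
  observed frequency `1/corpus_size`.
* **MICA ties.** Among common ancestors of equal IC the lexicographically
  smallest identifier wins — deterministic output; the choice cannot
  change the Lin value.
* **Lin 0/0.** When both terms have zero IC, Lin is 1 for identical terms
  and 0 otherwise, preserving `Lin(t,t) = 1` and the [0, 1] range.

## Similarity scores

Asymmetric set similarity is best-match-average: the mean over `S1`'s
terms of the best Lin match in `S2`. The symmetric score averages the two
directions; the group score averages the symmetric score over all cross
pairs of individuals. Individuals with empty term sets are skipped with a
logged warning rather than silently scored 0; a group with no usable
individuals is an error.

Variant-by-variant similarity matrices use affected probands only (the
proband is the unit of analysis throughout; relatives inherit reporting
bias and are often asymptomatic carriers). Clustering is agglomerative on
distance `1 − similarity`; the linkage method defaults to average and is
configurable (`average`, `complete`, `single`) since nothing in the score
itself dictates one. Cluster summaries report (i) the most common closure
term, excluding the root and any term literally named "Phenotypic
abnormality", with ties resolved in favor of the most specific term (a
term always ties its own ancestors in closure counts); and (ii) the
"most specific majority terms": terms present in ≥ 50% of the cluster's
probands with no descendant also above 50% — a structural definition
(leaves of the majority sub-DAG) chosen over an IC-based one because it
does not depend on the corpus.

## Heteroplasmy–phenotype association

For each (variant, term, tissue) the presence of the term in a proband's
closure is regressed on the heteroplasmy percentage in that tissue
(univariate logistic regression, one tissue at a time — matching the way
single-tissue dose–response curves are reported; a joint blood+muscle
model is a possible extension). The p-value is a likelihood-ratio test of
slope = 0, preferred over the Wald test for its behavior at the small
per-variant sample sizes of literature cohorts. Fits require ≥ 10
probands with ≥ 3 cases and ≥ 3 non-cases (configurable); complete
separation, non-convergence and constant predictors are flagged and
reported without a p-value.

The family-wide FDR at threshold `t` divides the expected number of
p-values below `t` — the mean count over permutations of the
heteroplasmy levels among probands within each (variant, tissue) stratum
— by the observed count. The estimator reports "undefined" (not 0) when
nothing is observed below `t`. Default 100 permutations; a seed is
mandatory and one shuffle per stratum serves all terms tested in it, so
results are invariant to the ordering of tests and patients (probands are
sorted by identifier internally).

A caveat documented here because it shapes the tests: at `t = 0.05` over
50 tests the observed count is a small Poisson-like draw (mean ≈ 2.5
under the null), so a single cohort's FDR estimate is extremely noisy and
undefined in roughly 5% of null cohorts. Calibration is therefore
assessed on the pooled ratio `Σ expected / Σ observed` over replicate
null cohorts (25 cohorts in the standard benchmark), which is ≈ 1 for a
calibrated estimator; the single-cohort estimator itself is unchanged.

Blood–muscle Spearman correlations are reported per variant when at
least three probands have both measurements.

## Enrichment and under-recognized phenotypes

Carriers of a variant are compared with the non-carrier proband
background by a one-sided Fisher's exact test (upper hypergeometric tail:
enrichment direction), pooled over the cohort and within each
publication. A term is *enriched* only if the pooled p < 10⁻⁶ and the
within-publication test is significant in ≥ 2 independent publications —
replication across publications guards against author-specific phenotype
reporting. The within-publication threshold defaults to 0.05: a 10⁻⁶ bar
is unreachable at typical per-publication sample sizes, and both
thresholds are configurable. The scanned universe is every term in at
least one carrier's closure, minus the root and "Phenotypic abnormality".

Individuals harboring two pathogenic variants count as carriers of each
and are excluded from the non-carrier background of *every* variant, so
the comparison group is never contaminated by a second pathogenic allele.

An enriched term is *under-recognized* when a map of established
variant→term annotations is supplied and the term is neither in the
variant's known set nor an ancestor of a known term — listing a specific
phenotype implies recognition of its generalizations. Variants without a
map entry are "not assessed" rather than flagged.

## Classification of test patients

A patient is scored against each variant having ≥ k phenotyped probands
(k = 5 by default; smaller variants are excluded from scoring, mirroring
how sparse reference variants cannot support a stable profile) by the
mean of the k largest asymmetric similarities, ties at the k-th value
broken by (similarity desc, proband id asc). The asymmetric direction
matches the patient's terms *into* each proband's terms: the score
rewards the patient's features being explained by a reference patient and
is robust to richly annotated references; the opposite direction is
available by flag. The overall score is the maximum over variants. The
reference IC context is the reference probands only; test patients do not
enter the corpus.

Performance is summarized by bootstrap FDR-versus-sensitivity curves:
each replicate draws, with replacement, `sample_size · case_fraction`
case scores (default 20) and the complement of control scores (180); for
target sensitivity `s` the threshold is the replicate's empirical
`(1 − s)` case-score quantile (lower order statistic, so achieved
sensitivity is ≥ s), and FDR = FP/(FP + TP) at that threshold. Thresholds
are chosen per replicate rather than globally, which is the direct
reading of "thresholding to achieve a given sensitivity". Reported
values are means over replicates.

Estimator caveat: when case and control scores share one distribution the
FDR should approach the control fraction (0.90 at 10% cases) by the
FP:TP ≈ 9:1 argument. This holds for `s ≥ 0.2` in our benchmarks, but at
very small target sensitivities TP is 1–2 per replicate and
`E[FP/(FP+TP)]` falls below the ratio of means (measured ≈ 0.75 at
s = 0.05) — a small-count bias of the estimator, not a property of the
scores.

## Synthetic data

The generator emulates the statistical structure the analyses assume, at
desk scale:

* **Ontology.** `generate_ontology` grows disjoint "system" branches
  under a single root (each non-root term draws 1..max_parents parents
  within its branch), mimicking the top-level organ-system organization
  of the HPO; terms of different systems share only the root, so
  phenotypes from distinct systems are semantically separable (Lin = 0).
  A fixed 40-term ontology with six named systems (nervous, musculature,
  metabolism, cardiovascular, ear, eye), one diamond and one alternate id
  ships for tests and examples. Cross-system edges, which real HPO terms
  occasionally have, are not modeled.
* **Cohorts.** Each variant gets a phenotype profile drawn from its home
  system (default 6 terms — with noise this yields per-proband term
  counts in the range of curated mtDNA cohorts). Each proband annotates
  each profile term with probability `term_sensitivity` (default 0.85,
  in the range of inter-rater concordance of literature HPO coding) plus
  `Poisson(noise_rate)` off-profile terms (default 1.0, uniform over
  non-profile non-root terms — the simplest exchangeable noise model),
  then minimized. Publications come from a shared pool so each contains
  carriers of several variants; without this, within-publication
  carrier/non-carrier contrasts would not exist and the replication rule
  could never fire.
* **Heteroplasmy.** Muscle level ~ Normal(65, 20) clipped to [0, 100]
  (percent); blood = muscle − max(0, Normal(15, 8)), floored at 0 — a
  hard muscle-dominance rule encoding the strong empirical tendency of
  blood heteroplasmy to sit below muscle. Dose-responsive terms override
  their base rate with presence ~ Bernoulli(expit(α + β·level)).
* **Controls.** Control profiles share a configurable fraction of their
  terms with a randomly chosen case profile; the remainder is drawn from
  systems unoccupied by any case variant. Overlap 0 (with noise off)
  gives fully separable cohorts; overlap ≈ 0.3 gives the confusable
  regime resembling neurodevelopmental comparison cohorts.

Everything is a pure function of the configuration seed (independent
numpy Generator streams per artifact, so adding dose–response effects
does not perturb unrelated draws).

What passing tests on these data do **not** show: robustness to
ascertainment and reporting bias, family structure (all simulated
individuals are independent probands), multi-system profiles, missing
heteroplasmy data, or the annotation-granularity mismatch between
template-free clinical coding and literature curation. Results on real
cohorts depend on those factors.

## Benchmark problem sizes

The standard benchmarks use: 10 variants × 20 probands (150-term
ontology) for classification, with 50 held-out cases, 200 controls,
mixtures of 200 at 10% cases and 200 bootstrap replicates; 10 variants ×
40 probands with 50 eligible tests and 100 permutations (40 in the
pooled-calibration replicates) for association; 50 replicates of n = 300
for slope recovery; and a 90-carrier / 900-background three-publication
cohort for enrichment. These sizes make the full suite run in about a
minute on one CPU while keeping every planted effect comfortably
detectable.

## Known limitations

* Only `is_a` structure is used; `part_of` and cross-ontology mappings
  are out of scope.
* Lin / best-match-average is the single similarity measure; Resnik,
  Jiang–Conrath or embedding-based scores are extension points.
* The logistic model is univariate per tissue; family structure (repeated
  probands per family) is not modeled as a random effect.
* The under-recognized flag depends entirely on the completeness of the
  supplied known-annotation map.
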