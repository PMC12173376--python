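# Methods

`proteosig` quantifies how the proteostasis network (PN) — the cellular
machinery of protein synthesis, folding, trafficking and degradation — is
perturbed across diseases, disease stages and risk-factor exposures. This
note records the statistical models, the defaults and why they were chosen,
what the synthetic generators do and do not emulate, and the numerical
choices that affect results.

## Over-representation model

Every enrichment question in the package is a one-sided hypergeometric test:
for a query of `n` genes inside a universe of `N` genes, the probability that
it overlaps a category of `K` genes in at least `k` members is
`P(X >= k)` with `X ~ Hypergeometric(N, K, n)`, computed through the survival
function (`scipy.stats.hypergeom.sf(k-1, N, K, n)`), which agrees with exact
enumeration to < 1e-12 over all configurations with `N <= 12`. Depletion is
never tested. Queries and categories are intersected with the universe before
counting; query genes outside the universe are dropped with a warning (the
conservative choice when symbol spaces differ).

Multiple-testing adjustment is Benjamini–Hochberg throughout
(`statsmodels.stats.multitest.multipletests`, `fdr_bh`). Profiling flags
(below) deliberately use *raw* p < 0.01 — they are descriptive per-disease
profiles, not a discovery list — while pathway enrichment of signed signature
genes uses BH FDR < 0.05 plus an overlap of at least 3 genes, returning up to
10 pathways per direction ranked by (FDR, p, name).

## Disease profiles and proteostasis states

A disease is represented by its top-`k` associated genes (`k = 500` by
default, truncating longer ranked lists). Its profile holds:

* `pn_fraction` — |set ∩ PN| / |set ∩ universe|;
* one enrichment flag per PN pathway and per functional class at raw
  p < `alpha` (default 0.01).

By default the pathway/class tests ask whether the *disease gene set* is
enriched for that pathway within the whole annotated universe. This
reproduces differential flags: a PN branch whose genes enter the disease set
at background rate stays unflagged even when the PN as a whole is
over-represented — the pattern in which, e.g., extracellular proteostasis is
not flagged in cancers although cancer gene sets are 25–36% PN. The
alternative composition test (query = PN subset of the disease set, universe
= PN genes, `test_universe="pn"`) is retained for users who want the
internal make-up of the PN subset; it has much lower power because most of
the PN is typically co-enriched, so the within-PN composition barely shifts.

States are read off the (UPS, extracellular) flag pair — ALP is recorded but
not discriminative, being enriched in all three states:

| UPS | extracellular | state |
|-----|---------------|-------|
| +   | −             | I (cancer-like) |
| +   | +             | II (neurodegeneration-like) |
| −   | +             | III (other disease groups) |
| −   | −             | UNCLASSIFIED (residual cell) |

Anabolic/regulatory classes appear in profiles but never enter
classification.

## Moderated-t differential expression

Two-group contrasts (stage vs control, exposed vs control) use the standard
empirical-Bayes hierarchical variance model: gene-wise residual variances
`s2_g` on `d_g` degrees of freedom, with true variances drawn from a scaled
inverse-chi-square prior `(d0, s0^2)`. The posterior variance
`(d0*s0^2 + d_g*s2_g)/(d0 + d_g)` replaces `s2_g` in the t statistic, which
gains `d0` degrees of freedom. The prior is estimated in closed form by
moment-matching `log s2_g` against a scaled F distribution via
digamma/trigamma identities, with the trigamma inverse solved by Newton
iteration. When the between-gene dispersion of `log s2` does not exceed its
chi-square sampling floor, `d0 = +inf` and `s0^2 = exp(mean(e_g))` where
`e_g = log s2_g − ψ(d_g/2) + log(d_g/2)`; the sampling-bias correction in
`e_g` matters — the raw geometric mean of `s2` underestimates a shared
variance by `exp(ψ(d/2) − log(d/2))` (≈ 0.76 at `d = 4`) and would inflate
every z-statistic. Genes with zero residual variance are rescued by
moderation whenever `d0 > 0`.

Only the two-group design is implemented — no covariates, weights or
mean-variance trend. On a shipped 60-gene synthetic fixture the full chain
(fit → prior → moderated t → BH) agrees with the reference Bioconductor
implementation of this model to ~1e-13 in log-fold-changes, t statistics and
(adjusted) p-values, including the estimated prior (d0 = 5.44999,
s0² = 0.235170).

Direction calls use adjusted p < 0.05 by default (`direction_alpha`),
configurable; the sign is the sign of the log2 fold change.

## Similarity, clustering, signatures

Disease similarity is the Jaccard index of the full gene sets (a `--pn-only`
style restriction is available by intersecting beforehand). Clustering is
agglomerative with complete linkage on distance `1 − J`
(`scipy.cluster.hierarchy`), cut by `maxclust`; ids are processed in
lexicographic order so results are input-order invariant. The number of
clusters is a required parameter, not inferred.

A consensus signature for a pathway over a cluster of signed disease sets is,
per gene, the mean of the available ±1 perturbation signs (in [−1, 1]) with a
support count; mean sign was chosen over mean log-fold-change because ranked
disease sets carry directions, not magnitudes — a magnitude mode can be
emulated by supplying magnitudes as signs upstream. Directional similarity of
two sign maps is the fraction of shared genes with equal sign; it is reported
missing (not 0) on empty overlap, and zero signs are rejected so that
direction calling stays upstream.

## Progression and centrality

Stage-wise analysis runs one moderated-t contrast per stage against control.
A gene's *onset* is the earliest stage with adjusted p < alpha, so
pathway-level stage proportions partition the affected genes and sum to 1;
the alternative "significant at stage s regardless of earlier stages"
reading is available as `mode="any-stage"`. Stage labels are free-form
ordered strings; merged labels (e.g. a combined early Braak stage) are single
stages.

Centrality of the stage-annotated interaction network uses exact degree and
unnormalized betweenness over unordered node pairs, endpoints excluded, equal
credit across co-minimal shortest paths (Brandes accumulation via networkx;
a star center with L leaves scores C(L,2), each node of a 4-cycle scores
0.5). Stage groups are summarized by interpolated quartiles; the two-sided
Mann–Whitney comparisons attached to the boxplot summaries are flagged
exploratory — they describe separation, they are not confirmatory tests.

## Risk-factor scoring

An exposure's perturbed PN set is its significant DE genes (direction ≠ 0)
intersected with the PN, signs carried. Against each disease in a panel the
package reports the raw Jaccard with the disease's PN subset (full subset by
default; a signed-only mode restricts to genes with direction calls), its
min–max normalization across the panel (raw values always emitted; all-equal
panels yield missing normalized values), and the directional similarity with
overlap size. Control baselines repeat the computation with the exposure's
kinase/TF subsets against the corresponding disease subsets, and with a
seeded random sample of significant DE genes, size-matched to the exposure
PN set.

## Synthetic data: what it emulates, what it does not

Defaults: 20,000-gene universe, 2,500 PN genes split 800/700/500/500 into
ALP / UPS / extracellular / proteostasis-regulation with nested functional
classes, control groups of 500 kinases, 1,400 TFs, 330 ion channels
(disjoint from the PN), 500-gene disease sets, oversampling multiplier
`r = 3` for a state's enriched pathways, within-cluster sign concordance
0.9, log2 effect 1.0, residual SD 0.5, 10 samples per group, 3 stages,
2,000-gene expression panels. At these settings the planted states yield PN
fractions of roughly 20–31%, matching the range reported for real disease
gene sets, and state recovery is 29–30/30.

Generator-specific notes:

* **Disease sets** — weighted sampling without replacement
  (exponential-key reservoir), weight `r` for enriched-pathway genes. Signs
  follow a shared base signature oriented per state (state II opposite to
  states I/III, so cancer-like and neurodegeneration-like clusters have
  opposing consensus signatures); each sign flips independently with
  probability `(1 − c)/2`.
* **Cluster panels** — state-weighted sampling alone produces nearly uniform
  Jaccard (~0.015 both within and between states at defaults), which is the
  realistic regime for top-500 lists but useless for testing block
  recovery; `make_cluster_panel` therefore plants shared cores
  (`core_frac = 0.6` of `k`), giving within-block J ≥ ~0.43 and
  between-block J near 0.
* **Staged expression** — baseline `mu_g ~ U(4, 12)`, constant residual SD,
  effect weight 1 at every stage ("early") or `s/S` ("progressive").
  Residuals are homoskedastic here so schedule recovery reflects effect
  sizes alone.
* **DE calibration studies** — gene-wise variances from the scaled
  inverse-chi-square prior (`d0 = 4`, scale = noise SD²), the same model the
  prior-recovery check assumes; a homoskedastic switch exists.
* **Risk panels** — every disease embeds 150 of the exposure's 300 PN genes
  with signs agreeing at the planted concordance (0.8 at-risk / 0.2
  reduced-risk), so the directional-similarity estimate is measured on an
  overlap of ~150 rather than on the few genes two unrelated top-500 lists
  share.
* **Hub networks** — preferential attachment where designated-stage nodes
  receive 8 stubs instead of 2.

Not emulated: expression covariance between genes, batch effects,
platform-specific noise, probe-level artifacts, symbol aliasing, and the
multi-omics ranking that produces real disease gene lists. Passing the
planted-recovery tests shows the estimators invert the generators' models at
realistic sizes; it does not certify performance on real cohorts with
correlated genes and imperfect annotation.

Determinism: every generator call draws from an RNG stream keyed by
`(seed, call-name)`, so outputs are reproducible and adding a generator never
perturbs existing ones.

## Numerical choices and degenerate inputs

* Hypergeometric tails via the survival function (log-space internally in
  scipy); tie-breaks in ranked TSV input by (score desc, symbol asc); gene
  identity is the uppercased symbol, no alias resolution.
* Trigamma inversion: Newton from `x = 0.5 + 1/y`, asymptotic branches for
  extreme arguments; convergence tolerance 1e-10 relative.
* Jaccard of two empty sets is defined as 0 (logged); clustering of a single
  disease returns cluster 1; BH of an empty vector is empty.
* Fewer than 10 positive variances, or no excess dispersion, triggers the
  `d0 = +inf` fallback; all-zero variances are an error.
* p-values are clipped away from 0 before BH to keep logs finite.

## Known limitations

* Two-group DE only; staging designs with covariates (age, sex, batch) need
  external adjustment first.
* The power of small-cohort contrasts (3+3) after BH is intrinsically low:
  at effect = 2 pooled SD the self-consistent BH threshold caps power near
  25% under a shared-variance model and near zero under strong variance
  heterogeneity (the moderated t then has only ~8 df). The package reports
  what the data support rather than inflating calls.
* Min–max normalized similarities are panel-relative: adding a disease
  changes every normalized value (raw values are always emitted).
* The interaction network is consumed as given; no edge inference.
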