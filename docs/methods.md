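# Methods

`litterlink` reimplements, as a tested pipeline, the association and
prioritization analysis used to connect microbially modulated metabolites to
fetal gene-expression programs in germ-free (GF) versus specific-pathogen-free
(SPF) mouse studies. This note records the statistical model behind each
stage, the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was open.

## Study design assumptions

The pipeline assumes a twin-litter design: GF and SPF dams (6 + 6 by
default), with two fetuses per dam profiled by RNA-seq and two *different*
fetuses profiled by LC–MS metabolomics, in each of several tissues. Because
the two omics layers never come from the same animal, all cross-omics
statistics are computed on per-dam means ("litter averaging"), giving one
data point per dam. The twin-similarity permutation test
(`screening.twin_similarity_test`) checks the premise that littermates are
far more alike than unrelated fetuses: its statistic is the mean
within-litter pairwise sample Spearman minus the mean between-litter
pairwise Spearman, with a one-sided permutation null that reassigns fetuses
to dams with litter sizes preserved and the +1-corrected p-value
`(1 + #{perm >= obs}) / (1 + n_perm)`.

## Screening

* **Gene prefilter**: genes with >= 5 reads in >= 12 fetuses are retained
  (11 for brain, where one sample is excluded upstream). Both thresholds are
  configuration values with per-tissue overrides.
* **Normalization**: median-of-ratios size factors — the reference is the
  per-gene geometric mean over samples, computed on genes with all-positive
  counts; a sample's size factor is its median count/reference ratio. This
  approximates the normalized counts a dedicated count-model tool would
  deposit; which expression scale fed the original correlations is not
  recorded anywhere, so normalized counts are the default and Spearman
  statistics are insensitive to the choice of monotone scale.
* **Differential expression**: an externally supplied DE table is always
  used verbatim when present. Otherwise a clearly flagged stand-in runs:
  per-gene OLS of log2(normalized+1) on group and sex indicators, a
  two-sided t-test on the group coefficient (n−3 df), and
  Benjamini–Hochberg adjustment. The stand-in is a fixed-dispersion-free
  approximation, not a negative-binomial model; it exists so synthetic runs
  are self-contained, and every downstream report carries its
  `source=standin` flag. Genes that are constant across all samples report
  p = 1 with a zero-variance flag.
* **Metabolite status**: per tissue, a feature is `gf_absent` if it has zero
  GF detections and detections in at least half of the SPF samples (the
  quorum prevents a near-universally missing feature from being called
  microbially derived); otherwise `spf_higher` if a Welch t-test on
  log2(intensity+1) gives BH p.adj < 0.05 with a higher SPF mean; otherwise
  `unchanged`. A rank-sum alternative is exposed in configuration. Features
  qualifying in at least one tissue form the analysis set used by all
  association routes. Note that with litter random effects present, any
  two-sample test that ignores the litter structure is anticonservative at
  the per-test level (measured type-I ≈ 0.14 at litter SD 0.3); the BH step
  under a complete null still leaves the realized discovery rate far below
  alpha. The calibration tests therefore check the raw test at litter SD 0
  (where it is exact, measured 0.050) and the BH discovery rate under the
  default null (measured ≈ 0.005 ≤ alpha).

## Association routes

All three routes use Spearman correlation over SPF dam means only (six
points at the default design) and refuse to run with fewer than four dams.
Ties receive average ranks; constant vectors have undefined correlation and
are excluded (screen) or become singleton clusters (clustering).

1. **Direct screen**: all feature × gene pairs with |rho| > 0.9. The
   threshold is printed as `rho > 0.9` in the source analysis, which
   nevertheless reports negative associations; the default therefore screens
   on |rho| and records the sign, with a config switch for the signed
   variant.
2. **Cluster linking**: complete-linkage hierarchical clustering of genes
   and of features on the dissimilarity 1 − rho. Only the resulting average
   cluster sizes are recorded upstream (16–43 genes, 7–15 features), so the
   tree is cut at the height whose mean cluster size falls in the target
   range (closest achievable mean otherwise, with a warning). Cluster pairs
   with mean member-pair rho > 0.7 (brain 0.6) are linked; the mean is
   signed by default.
3. **Plaid biclustering** on the |rho| feature × gene matrix, with constant
   layer means (the `y ~ m` model: no row or column effects). Layers are fit
   greedily on the residual matrix; each candidate layer alternates
   simultaneous row/column membership updates by squared-error gain for
   `iter_startup + iter_layer` rounds. Three implementation choices depart
   from a textbook plaid fit and are deliberate:
   * *Pivot multistart.* A single random-binary start reliably converges to
     a broad, shallow layer on rank-correlation matrices, because at n = 6
     dams the background |rho| distribution is heavy-tailed (mean ≈ 0.37)
     and "slightly elevated" rows form a large attractive basin. Each layer
     therefore keeps the best of 8 starts: one random-binary, the rest
     seeded from a random pivot row's strongest quartile of columns.
   * *Iterated relative release.* After convergence, members whose
     squared-error reduction falls below `release` (default 0.7) times the
     strongest member's reduction are pruned, the layer mean re-estimated,
     and the step repeated to a fixed point. Relative release is scale-free:
     it tightens a layer to its coherent core instead of keeping a halo of
     weakly correlated members whose admission depends on the background
     level.
   * *Positive layers only.* The input is a similarity matrix; a layer with
     a negative mean models a block *less* correlated than background,
     which is not an association bicluster and, if subtracted, corrupts the
     residuals of blocks not yet fitted.
   A layer is accepted only if its importance (sum of squared fitted
   effects, `|rows| * |cols| * mu^2`) exceeds the best importance obtained on
   three permuted copies of the residual (independent within-row then
   within-column shuffles, which destroy blocks while approximately
   preserving marginals); fitting stops at the first rejection or at 10
   layers. The biclusters with the strongest mean internal |rho| — top half,
   minimum one — are selected, after dropping layers whose column set
   overlaps an earlier-fitted layer at Jaccard > 0.5 (greedy refits of the
   same gene space otherwise occupy selection slots).
4. **Dependency labels**: for screened pairs, the metabolite is by
   construction lowest (or absent) in GF, so linear extrapolation of the
   within-SPF correlation predicts the GF expression shift; rho < 0 predicts
   GF > SPF and vice versa. Agreement is `linear_consistent`, disagreement
   `nonlinear_discordant`, a zero shift is consistent with a zero-effect
   flag.

## Enrichment and prioritization

Over-representation uses the exact hypergeometric upper tail
P(X >= k | N, K, n) with BH adjustment across all terms of the collection
for one query; the universe is the tissue's prefiltered genes (the
measured-gene background), and terms need an overlap of at least 2 query
genes to count as significant. Per feature, three gene sets are assembled —
direct-pair partners, the union of member genes of gene clusters linked to
the feature's cluster, and the union of gene members of selected biclusters
containing the feature — and each is scored by its number of significant
terms. Features are ranked within each route by descending hit count
(average ranks for ties); the combined score is the sum of the three route
ranks, with final order ascending by combined score, ties broken by total
hits then feature id. Rank aggregation keeps the routes scale-free; a
sum-of-counts alternative is in configuration.

## The synthetic-data generator

The generator's defaults are the study conditions: 6 + 6 dams, 2 fetuses per
dam per assay, 3 tissues, 2000 genes, 500 molecular features, 5% of features
absent in GF and 15% significantly lower in GF, and 5 driver metabolites
with 30 linked genes each. Counts are negative-binomial with log-normal
gene baselines (log-mean log 200, log-sd 1.5, so the prefilter drops a
nontrivial minority), per-gene dispersion in 0.05–0.5, a per-gene × per-dam
log-normal dam effect (sd 0.3) shared by littermates, sex effects, and
GF offsets. Intensities are log-normal with a shared dam effect, a fetus
noise of 0.2, and a hard detection floor encoded as zero (configurable to
NA).

Key modelling choices, made where the emulated study reports only outcomes:

* **Dam latent exposures as a dose design.** Each driver's SPF exposures are
  a permutation of evenly spaced normal quantiles, and the five permutations
  are chosen greedily to be mutually near-orthogonal. With only six dams,
  uncontrolled random exposures frequently clump (making ranks
  unidentifiable) or collide across drivers (merging unrelated metabolite
  families); the quantile design keeps planted dose–response structure
  detectable at the stated coupling strength. Exposure-driven features carry
  no *additional* independent dam effect — the exposure is their dam-level
  biology.
* **Coupling strength.** The within-SPF |rho| target (default 0.95) is
  converted to a latent noise budget through the bivariate-normal relation
  rho_S ≈ (6/π) asin(r/2); the dam random effect consumes part of the
  budget and counting noise takes the remaining slack. Realized dam-level
  |rho| over planted pairs has median ≈ 0.94 (the n = 6 Spearman grid makes
  0.943 the first value below 1), calibrated once on seeds 1–10.
* **Driver families.** Each driver heads a family of co-varying companion
  features (default 4, exposure noise sd 1.0), emulating one compound
  observed as several LC–MS molecular features or a chemically related
  family. Without families, no metabolite cluster can pass the cluster-link
  threshold: a lone driver diluted to the forced 7–15 mean cluster size by
  unrelated features caps the mean link rho near 0.1.
* **Planted gene sets.** Each driver gets 16 small planted sets (5–10 of its
  linked genes plus 2 fillers) and the remainder of the collection is random
  sets of 10–80 genes. Many small sets make the ORA hit count *grade* with
  the fraction of linked genes a query captures, which is what lets the
  prioritization separate true drivers from features that track an exposure
  only approximately. With six dams per group, a noise feature's dam ranks
  match some exposure to within one transposition with probability 1/60 per
  driver, so a default study contains several such "phantom" features; a
  phantom with an exact rank match is statistically indistinguishable from
  its driver under any rank-based statistic, and the recovery criterion
  tolerates them via the top-20 margin.
* **Discordant pairs** couple the gene negatively to the driver within SPF
  and additionally suppress it in GF (log offset −2.0), reproducing the
  reported pattern of negatively correlated genes that are nevertheless
  lower in GF.
* **Planted effect sizes.** Linked genes take a ±2.0 natural-log GF offset.
  They need to: their own dose–response coupling (slope 1.5 per exposure sd)
  inflates within-SPF variance, and a smaller shift would not survive BH in
  a 12 vs 12 comparison. Background DE genes (100) take ±1.0; sex-effect
  genes (50) ±0.5.
* **The null generator** zeroes group effects, drivers, couplings, absent and
  reduced features, *and* sex effects. Retaining sex effects would break
  fetus-to-dam exchangeability (real litters are always F+M, permuted ones
  are not), invalidating the uniformity of the twin-test permutation p that
  the null harness exists to verify.

What the generator does **not** emulate: raw LC–MS spectra and their peak
structure, sequence-level read data, real tissue-specific biology (tissues
differ only by independent noise draws), metabolite annotation, batch or
column (RP/HILIC) effects, and the broad global GF-vs-SPF physiology axis
that makes most real metabolites and genes weakly co-vary. The last point
matters for interpreting the cluster route: in these synthetic conditions,
with orthogonal driver exposures and forced mean cluster sizes, linked
cluster pairs rarely exceed mean rho 0.7, so the cluster route contributes
few or no links on default synthetic runs (its mechanics are verified by
constructed unit tests). Passing tests demonstrate the pipeline's operating
characteristics under the planted model, not performance on real data.

## Problem sizes and determinism

Simulation-based tests use the default study (2000 genes × 72 samples,
500 features × 72) over 10 fixed seeds for recovery checks, 50 null
replicates for test calibration (at 50 genes × 200 features, which leaves
the metabolite test unchanged), and 100 replicates for permutation-p
uniformity; the full suite and the acceptance script each run in a few
minutes on one CPU. All randomness descends from explicit integer seeds
(per-tissue stage seeds are derived from the run seed plus a stable digest
of the tissue name), and repeated runs with the same configuration are
byte-identical, which the test suite asserts at the file level.

## Known limitations

* Six dams give a Spearman grid of only 720 orderings; screen thresholds
  near 0.9 are effectively "at most one adjacent transposition", and chance
  matches are common — on real data the screen should be read as
  hypothesis-generating, exactly as the original analysis reads it.
* The DE stand-in ignores count dispersion and litter correlation; supply a
  proper external DE table when one exists.
* The Welch metabolite test ignores litter correlation (see above); its BH
  discovery rate is still controlled in the conditions tested.
* Plaid layer membership is binary; a feature weakly associated with a
  family's genes receives the full bicluster gene set once admitted.
* ORA treats terms as exchangeable; there is no ontology-aware redundancy
  reduction, and results depend on the supplied GMT collection.
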