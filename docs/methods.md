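# Methods

## The procedure

`gbmscreen` implements a survival-biomarker discovery workflow for bulk
expression data across several independent datasets:

1. **Normalization.** Raw gene counts of each dataset are quantile
   normalized — every sample's values are mapped, rank by rank, onto the
   reference distribution formed by the row-wise means of the
   column-sorted matrix — and then log10(x + 1) transformed. Datasets
   (including sequencing batches of one repository) are normalized
   independently and treated as separate datasets throughout; no batch
   correction is attempted, because the screen's consensus step works on
   set intersections rather than pooled values.
2. **Per-gene screen.** For each gene, samples above the 66th percentile
   of its expression form the high group and samples below the 33rd
   percentile the low group (the middle tertile is discarded; strict
   inequalities, so a constant gene yields empty groups and is skipped).
   High vs low is compared with (a) a two-group Cox proportional-hazards
   fit whose Wald p-value tests the log hazard ratio β, and (b) the
   log-rank test. A gene is *differential* when both p-values are below
   α = 0.05; differential genes are split by sign of β into *plus*
   (overexpression → higher hazard) and *minus* sets. No multiple-testing
   correction is applied at this stage — the consensus intersection is
   the guard against false positives.
3. **Consensus.** Plus (and, separately, minus) sets are intersected
   across datasets. Significance of an observed intersection size is
   assessed by a permutation null: 1,000 iterations, each drawing from
   every dataset's own screened universe a uniform random subset of the
   same cardinality as its differential set and intersecting the draws.
   The p-value is the fraction of iterations with a random intersection
   at least as large as the observed one ("equal or higher", so p = 0 can
   occur at finite iteration counts; a (count+1)/(n+1) corrected value is
   carried in the report for auditing).
4. **Pathway level.** Pathway activation levels (PAL) repeat the same
   screen on pathway scores: each gene's case-to-normal ratio (CNR) is
   its quantile-normalized, +1-shifted value divided by the gene's
   geometric mean across the dataset's samples, and
   PAL(p, s) = Σ_g ARR(g, p) · log10 CNR(g, s) / Σ_g |ARR(g, p)| over the
   pathway's members measured in the matrix, with ARR the signed
   activator(+1)/repressor(−1) role weight. Only pathways with ≥ 10
   measured members are scored (configurable). This signed role-weighted
   mean is this package's reconstruction of pathway activation scoring;
   its defining properties — positive = up-regulation, per-dataset
   geometric-mean reference, linearity in log-ratios, exact antisymmetry
   under role flips, the ≥ 10-member filter — are tested.
5. **Enrichment.** Consensus sets with a significant permutation p are
   tested for term over-representation with one-sided hypergeometric
   tails and Benjamini–Hochberg FDR. Terms are flat sets from GMT input
   (no ontology-graph propagation). The background universe is the
   intersection of the contributing datasets' screened universes: the
   enrichment background must match the candidate pool of the screen,
   not the whole genome.

## Statistical details and numerical choices

- **Percentiles** use linear interpolation of order statistics (index
  (n−1)·q/100), the default of mainstream statistical environments.
  Group membership uses strict inequalities, so middle-tertile samples
  are always excluded. Percentiles are computed over the samples that
  carry survival records for the endpoint being screened.
- **Cox fit.** The partial likelihood of the single binary covariate is
  maximized by damped Newton–Raphson (step clipped to ±2, tolerance
  1e−10, ≤ 50 iterations) with Efron tie handling by default (Breslow
  available). Monotone-likelihood instances — e.g. all events in one
  group, where the MLE diverges — are flagged non-converged (NaN
  statistics) rather than returning ±∞, and never enter differential
  sets. The implementation is written against numpy risk-set tables so
  the screen stays around a second for 2,000 genes × 200 samples;
  lifelines' `CoxPHFitter` serves as an independent cross-check in the
  test suite, and a grid search over a naively written partial
  likelihood as the oracle on small instances.
- **Log-rank test** uses the standard hypergeometric variance at each
  distinct event time, no continuity correction, p from χ²(1). Without
  ties it coincides with the Cox score test at β = 0 (asserted to 1e−8).
- **Kaplan–Meier** estimation is delegated to lifelines; records
  censored at an event time count as at risk for that time.
- **Quantile normalization ties.** Tied values within a column receive
  the mean of the reference values at their tied ranks. With ties
  present this necessarily relaxes two otherwise-exact identities
  (identical sorted columns; idempotence): both hold exactly on tie-free
  columns, which is how they are tested; with ties they hold up to the
  within-tie-group averaging.
- **BH adjustment** is the classical step-up (q_i = min_{j≥i} p_(j)·m/j,
  capped at 1, returned in input order) and is compared against
  statsmodels' `fdr_bh` to 1e−12 in the tests.
- **Exact two-dataset oracle.** For two datasets the permutation null has
  a closed form: conditioning on how many of each set's members fall in
  the shared universe region (hypergeometric), the overlap is
  hypergeometric on that region. The permutation estimate is required to
  sit within 3 Monte-Carlo SDs of this tail over a grid of
  configurations.

## The synthetic-data generator

The generator produces multi-dataset studies with the statistical
structure the screen assumes, so the whole pipeline is testable without
repository downloads:

- **Counts**: negative-binomial via a gamma–Poisson mixture, gene means
  lognormal (base mean 100 counts, SD of log means 1.0), dispersion
  (size) 10. A per-dataset, per-gene N(0, 0.5) shift on the log mean
  creates batch structure — datasets separate in PCA the way distinct
  platforms/batches do.
- **Survival**: exponential proportional hazards. Baseline hazard 0.05
  events/month (median survival ≈ 14 months, in the range reported for
  glioblastoma); a planted marker with coefficient β multiplies the
  hazard by exp(β·z) where z is the sample's standardized log(1+count)
  of that gene. Censoring is uniform on (0, 60] months — roughly
  two-thirds of records end in an event, and censoring interleaves with
  events throughout follow-up, exercising the estimators' censoring
  paths. The exponential baseline is chosen for closed-form sampling;
  the screen only assumes proportional hazards.
- **PFS** is drawn independently of OS with the time scale multiplied by
  0.7 (progression precedes death on average); endpoints are kept
  separable on purpose so tests can distinguish them.
- **Default study conditions** (used by the benchmarks and the analysis
  scripts): four datasets of 2,000 genes × 200 samples, half the gene
  universe shared across datasets, one marker at β = 1 planted in all
  datasets as the consensus biomarker.

What the generator does **not** emulate: real expression covariance
structure and co-regulation, tumor subtypes, FFPE degradation, library
size artifacts, or non-proportional hazards. Passing benchmarks therefore
show the procedure is correct and well calibrated under its own model
assumptions — not that it is robust to their violation in real cohorts.

A caveat worth knowing: with very small gene panels (tens of genes), a
gene tends to hold the same rank in every sample, so quantile
normalization collapses its row toward a constant and the screen skips it
as degenerate. The benchmarks use 2,000 genes, where per-gene rank
variation survives normalization.

## Calibration and recovery benchmarks

`gbmscreen.evaluation` recomputes, at run time:

- agreement of the Cox fit with a grid-search maximizer on random ≤
  8-record no-tie instances (|Δβ| < 1e−4), of the log-rank statistic with
  hand-tallied tables (exact), and of BH with statsmodels (1e−12);
- permutation-vs-exact agreement on the two-dataset grid (≤ 3 MC SDs at
  10⁴ iterations);
- consensus recovery: the fraction of 20 independent studies in which the
  planted marker is the sole plus-direction four-way consensus gene
  (expected ≥ 80%; in practice nearly always);
- null calibration: the dual-filter pass rate under an all-null study.
  The dual criterion's pass rate is bounded by the size of each
  component test, ≈ 5% here; the bound is asserted at the Monte-Carlo
  resolution of the pooled 20-seed × 4-dataset estimate (3 binomial SDs),
  and the four-way consensus permutation p exceeds 0.05 in ≥ 90% of null
  seeds.

Problem sizes (20 seeds, 2,000 genes, 200 samples, 10⁴ permutation
iterations) keep the full benchmark run to a few minutes on one core
while leaving Monte-Carlo error well below the tested margins.

## Experimental-cohort tables

The two packaged tables transcribe the published patient characteristics
(16 patients) and per-library sequencing statistics (14 libraries) of the
experimental glioblastoma cohort; their checksums are pinned in the test
suite. Missing clinical values ("/", "Not performed") map to explicit
missing markers, never zero. Endpoint analysis-set membership is
range-driven: OS restricted to [2, 58] months keeps 15 of 16 patients and
progression time restricted to [2, 37] keeps 14 — reproducing the
published analysis sets, which exclude one 91-month OS record and one
90-month progression recorded after the analysis (flagged with an
asterisk in the source table). The range parameters make this exclusion
rule explicit and auditable rather than hard-coded.

## Design choices where the design was open

- **"HR > 0 / HR < 0"** for plus/minus is read as the sign of the log
  hazard ratio (a hazard *ratio* is always positive; the sign convention
  only makes sense on the log scale, which is also the axis used when
  such screens are plotted).
- **Wald p** is used as the "hazard ratio p-value": it is the
  per-coefficient p reported by standard survival packages and their
  forest plots.
- **Efron ties** by default, matching the R `survival` package;
  Breslow is exposed for oracle comparisons.
- **Random subsets are drawn from each dataset's own universe** in the
  permutation test (universes differ across repositories); the random
  intersections then live on the shared universe exactly as the observed
  one does.
- Plus and minus intersections are tested with independent draws, never
  pooled.
- Features with fewer than 2 samples in either group are skipped, not
  errored: a genome-scale screen must not abort on degenerate genes.
- GMT members may carry a `:+1` / `:-1` suffix encoding the role weight;
  plain GMT parses with all-activator defaults. This dialect is this
  package's own extension.

## Known limitations

- Single-covariate screens only; no multivariate Cox adjusting for other
  prognostic factors, by design.
- The PAL formula is a documented reconstruction (see above), not a
  reimplementation of any proprietary scoring engine, and the packaged
  pathway/term files in the analysis scripts are toy collections
  generated programmatically.
- The permutation test's closed-form oracle covers two datasets only;
  k > 2 is validated by the permutation machinery itself plus the
  end-to-end null calibration.
- No FASTQ/BAM handling and no repository download clients: the pipeline
  starts from gene-level count matrices.
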