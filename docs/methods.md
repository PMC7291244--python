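# Methods

This document records the statistical models implemented in `methsplice`,
the assumptions they make, the main parameter choices, and the design and
limits of the synthetic data generator. Everything stated here is something
the code computes or enforces; no empirical claims about real tissue data are
made.

## Coordinates and annotation

Genomic coordinates are 1-based inclusive throughout (GTF convention); BED
output converts to 0-based half-open at the I/O boundary only. Transcript
exons of a gene are flattened into disjoint *exonic bins* by cutting the
exonic footprint at every exon start and every position one past an exon end
observed in any transcript of that gene; maximal covered segments between
cuts become bins `E001, E002, …` in genomic order. Introns are the gaps
between consecutive bins; abutting bins produce no intron. Overlapping genes
are flattened independently, so a probe inside introns of two genes (e.g. an
antisense lncRNA over a host gene) pairs within each gene separately.

Flank pairs are built strand-agnostically in genomic orientation: a probe at
position *p* strictly inside an intron yields an *exon-intron* pair with the
upstream bin (distance `p − bin.end`) and an *intron-exon* pair with the
downstream bin (distance `bin.start − p`). A probe exactly on a bin boundary
is exonic and yields no pair. The probe manifest carries no strand, so
"upstream/downstream" cannot be transcript-relative; this is a deliberate
simplification and affects only the labelling of the two pair kinds, not the
set of pairs.

## Preprocessing

- Samples with fewer than 1,000,000 feature-assigned reads are dropped
  (boundary kept).
- Probes flagged as SNP-overlapping, cross-reactive, or on chrX/chrY are
  removed before any analysis.
- Bins with a total inclusion count below 6 across retained samples are
  removed.
- Size factors are median-of-ratios (median over bins positive in every
  sample of count / geometric row mean), rescaled to geometric mean 1,
  computed **per cohort** — there is no cross-cohort batch correction; the
  replication join is the only cross-cohort step.
- Beta values are clipped to `[1e-6, 1 − 1e-6]` before the M-value transform
  `M = log2(beta / (1 − beta))` so linear modelling stays finite. The clip
  constant only matters for probes with essentially degenerate betas.
- PCA covariates are sample scores of the row-centered M-value matrix (SVD),
  with each component's sign fixed so its largest-magnitude loading is
  positive, making outputs byte-stable across runs.

## PSI

Percent-spliced-in for bin *b* of width `L_b` with inclusion count `I` and
skip-junction count `E` is the length-normalized ratio

    PSI = (I / L_b) / (I / L_b + E / L_J),

with effective junction length `L_J = read_length − 1 = 99` (a junction read
of length `R` can start at `R − 1` positions that span the junction). PSI is
NA when `I = E = 0`. This is a per-bin approximation that treats inclusion
reads as uniformly attributable to the bin; it ignores positional read bias
and multi-isoform ambiguity.

## Flank regression (pooled, quasi-Poisson)

One observation per flank pair of a given kind within a sample group:

    y_pair ~ quasiPoisson,  log E[y] = log(T_gene) + a + b · beta  [+ c · log10 d]

where `y` is the bin's inclusion count summed over the group's samples,
`T_gene` the gene's total inclusion count over the same samples (offset), and
`beta` the group-mean methylation of the probe. The offset makes `b` a
statement about the bin's *share* of its gene's reads, insulating it from
differential gene expression. Standard errors are scaled by the Pearson
dispersion `φ = Σ (y−μ)²/μ / (n−p)` and the p-value is t-based with `n − p`
degrees of freedom (quasi-likelihood inference). Pairs whose gene total is
zero in the group are excluded; the fit requires ≥ 10 pairs and a
non-degenerate predictor.

Assumptions: variance proportional to the mean (the quasi-Poisson second-
moment assumption), independence across pairs. The second is knowingly
violated — pairs within a gene share the offset and neighbouring pairs share
probes/bins — so the pooled p-value should be read as a descriptive
significance bound of the genome-wide trend, not as an exact test. The
per-combination EWAS scan below is the locus-level inference tool.

## Methylation–splicing association scan

Per (intronic probe, exon bin) combination within a gene, and per group:

    PSI_s ~ quasibinomial,  logit E[PSI_s] = a + b · beta_s + Σ_k c_k · PC_k,s

fit by IRLS over samples `s` of the group, with the first two M-value
principal components as covariates (fewer when the group is small: the PC
count adapts as `min(2, n_group − 3)` so residual df stays positive).
Effects are reported as odds ratios per 0.01 beta, `exp(0.01 · b)`, with
Wald 95% CIs on the logit scale and t-based p-values using the Pearson
dispersion. Combinations with fewer than `max(min_samples, 3 + n_PCs)`
non-missing samples or constant PSI/beta are skipped. Coefficients larger
than 15 in absolute value are flagged `separated` (quasi-separation) and
should not be interpreted as finite effects.

The PSI response is a proportion, not a count of independent trials, so the
quasi-binomial fit is a working-variance approximation; the unadjusted
within-group Pearson correlation `r(beta, PSI)` is reported alongside and is
the quantity used for differential-correlation testing.

*Variance explained* is summarized as the mean squared Pearson correlation
over all testable combinations, with a normal-approximation CI
(mean ± 1.96·sd/√n). Under independence its expectation is `1/(n − 1)`, so
the summary should always be read against that baseline.

## Differential correlation and directional replication

For each combination present in both groups, Fisher's z test compares the
within-group correlations:

    z = (atanh r₁ − atanh r₂) / sqrt(1/(n₁−3) + 1/(n₂−3)),

two-sided normal p-value, requiring `|r| < 1` and `n ≥ 4` per group (input
correlations at the boundary are clipped by `1e-12` before the transform).
Screening applies Benjamini-Hochberg across all tested combinations and flags
FDR < 0.05. A screened candidate *replicates* when its raw differential-
correlation p in the independent replication cohort is below 0.05, and
replicates *directionally* when additionally the sign of r within each group
agrees across cohorts and disease and control correlations have opposite
signs. The directionality filter is what rejects confound loci that show a
strong but same-sign correlation difference.

Fisher's z assumes bivariate normality within groups and independent
cohorts; at the replication cohort's size (11 vs 5) its n−3 variance is a
small-sample approximation, one reason replication uses the raw p rather
than an FDR-adjusted one.

## Differential tests

- **DGE** — per-gene negative-binomial log-linear model with log size-factor
  offset. Dispersion is method-of-moments per gene,
  `α = max(0, Σ((y−μ)² − μ) / Σμ²)` at the Poisson fit, shrunk toward a
  log-log mean–dispersion trend by geometric interpolation with weight 0.5
  (an explicit, simple stand-in for the empirical-Bayes shrinkage of
  DESeq2-class methods). Wald test on the condition coefficient; effects are
  reported in log2.
- **DEU** — per-bin quasi-binomial logit model of the bin's share of its
  gene's reads (gene totals as binomial trials), condition t-test with the
  Pearson dispersion shrunk toward a trend as above. Bins of single-bin genes
  are structurally untestable and reported NA. Complementary bins of a
  two-bin gene carry the same information; genome-wide counts of DEU hits
  therefore double-count such genes, which is why intersection reporting is
  per pair and per gene.
- **DMR** — probe-wise linear model of M-values with covariates
  (condition, sex, age, five immunosuppressant indicators, PCs where
  supplied; age enters linearly). The condition t-statistic is moderated:
  residual variances are shrunk to
  `s²_post = (d₀ s₀² + d s²) / (d₀ + d)` with `(d₀, s₀²)` estimated by
  moment-matching of `log s²` under the scaled-F hierarchical model
  (trigamma inversion by Newton's method), and the t has `d₀ + d` degrees of
  freedom — the limma construction. `d₀ = 0` recovers the ordinary t;
  `d₀ = ∞` pools all probes.

Design matrices always contain intercept and condition; aliased columns are
dropped deterministically (later-entered first), and trailing covariates are
trimmed with a warning when a small cohort would otherwise exhaust residual
degrees of freedom. Because the generator assigns immunosuppressants only to
controls (as in a transplant-donor control design), drug indicators are
partially confounded with condition; they are retained where estimable and
their coefficients absorb part of the condition effect — an acknowledged
limit of the observational design, not of the implementation.

All families of p-values are adjusted with Benjamini-Hochberg step-up
(NaN-propagating: untestable features neither receive nor influence adjusted
values).

## Synthetic data generator

The generator produces a fully labelled dataset: gene models (two transcripts
per gene where the gene has ≥ 4 bins, the second skipping one internal bin),
intronic/exonic/intergenic probes with blocklist flags, two cohorts with
sample sheets (sex, age, batch, immunosuppressants in controls only), and
count/beta matrices.

- Expression: per-gene lognormal means, NB2 counts (`Var = μ + αμ²`) with
  per-sample lognormal library factors and multiplicative batch effects.
- Methylation: per-probe logit-normal betas (M-scale noise sd 0.5, batch sd
  0.1).
- Coupling: each flank pair's bin-usage logit gets `0.35 · (beta − 0.5)`,
  the planted analogue of the flank-regression effect.
- Counts per bin: inclusion mean `μ_gene · π_bin`, exclusion mean scaled by
  `L_J / L_b` so that PSI is centred on `π_bin`.
- Planted differentials: 5% of genes with log2FC 1 (DGE), 5% of bins with a
  usage-logit shift of 1 in disease (DEU), 5% of probes with an M-shift of 1
  (DMR).
- Special loci: group-reversed and same-sign-confound (probe, bin) pairs on
  dedicated high-expression (mean 3000), low-dispersion (α = 0.01) genes.
  Their usage scores are constructed to have an **exact sample correlation**
  with the probe's beta at the configured targets (Gram-Schmidt on the
  realized beta vector), so the planted truth is the realized correlation up
  to the logistic transform and counting noise. Reversed loci target
  (−0.6, +0.6) in screening and (−0.9, +0.9) in replication (the replication
  targets are stronger because n = 11/5 gives Fisher-z power only for large
  |r|); same-sign confounds target (0.95, 0.10) / (0.97, 0.15) so they pass
  the screen and raw replication but carry equal-sign correlations for the
  directionality filter to reject.
- An antisense gene pair (a short "-AS" gene inside a host gene's intron)
  exercises the independent-flattening path.

Realism limits, by design: reads are summarized as bin counts rather than
alignments; exclusion counts are bin-local rather than junction-resolved;
methylation is probe-independent (no spatial correlation along the genome);
coupling is linear on the logit scale; and the confounding structure
(drugs only in controls) is simpler than real transplant cohorts. The
generator is a test harness for the statistics, not a sequencing simulator.

`simulate_flank_pairs` is a separate pair-level generator
(`E[y] = T · exp(a + b·beta)`, `Var = φ·E[y]` via negative-binomial thinning,
exactly Poisson at φ = 1) used for parameter-recovery and null-calibration
experiments at arbitrary n without the cost of a full dataset.

## Numerical choices

- All GLM scans (DEU, DGE, EWAS) run as batched IRLS over features with
  einsum linear algebra; per-feature results match statsmodels single fits to
  ≤ 1e-4 relative error (tested). Linear predictors are clipped at ±30,
  singular updates fall back to a tiny ridge, and features whose update is
  non-finite are frozen rather than poisoning the batch.
- Benjamini-Hochberg uses a stable mergesort so ties are deterministic.
- Every random quantity derives from a single seed via named substreams;
  re-running any stage with unchanged inputs and seed is byte-identical
  (tested at the file-hash level).
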