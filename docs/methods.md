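# Methods

This note documents the statistical models implemented in clonotribe,
the synthetic data they are validated on, and the numerical and design
choices made where the procedure was genuinely open.

## Edit-site discovery and filtering

The pipeline starts from per-site, per-sample allele counts (edited reads
`k`, coverage `n`), not from alignments. Discovery applies per sample:
a mismatch is present in a sample when `n >= 10` and `k/n >= 0.01`.
Candidacy then requires

1. presence in at least two ADAR-fusion (treatment) samples — the
   discovery thresholds are applied to treatment samples only, since
   control frequencies at genuine edit sites are expected to sit below
   the minor-allele-frequency gate by design;
2. the mismatch type A>G on a forward-strand gene or T>C on a
   reverse-strand gene (deamination acts on the adenosine of the
   transcript); strand is taken from the annotation of the overlapping
   gene, and intergenic sites are dropped;
3. the reference allele majority in pooled control reads
   (`sum k / sum n < 0.5` across controls). Pooling is used because a
   per-sample majority rule is unstable at low coverage; a site with no
   control coverage at all fails candidacy because the condition is
   unverifiable.

Known germline variants are removed by exact `(chrom, pos, alt)` match
against a blacklist. Filtering only removes rows; counts are never
altered, which makes the discovery/blacklist order interchangeable (a
property the tests check).

Coordinates are 1-based inclusive in site tables (VCF convention) and
0-based half-open in BED, never mixed.

## Per-site negative-binomial GLM

Counts at a candidate site are modeled as NegBinom(mu_i, theta) with
log(mu_i) = b0 + b1·group_i + log(n_i); the offset makes b0 the log
editing rate in controls and b1 the log rate ratio of the fusion group.
The fit alternates iteratively reweighted least squares for (b0, b1) at
fixed theta (working weights mu/(1 + mu/theta)) with a bounded
one-dimensional ML update of theta on the log scale, initialized from a
method-of-moments estimate after a Poisson pass. Numerical choices:

* theta is capped to [1e-3, 1e6]; near the upper cap the likelihood is
  flat in theta (the Poisson limit) and the bounded search jitters by
  ~1e-4 in log(theta), so convergence is declared on the log-likelihood
  (change < 1e-9) rather than on theta itself;
* the linear predictor is clipped to ±30 to keep exp() finite;
* non-convergence after 30 alternations falls back to a Poisson GLM
  (theta → ∞) with `converged = False` — with six observations theta is
  sometimes unidentifiable, and a flagged conservative fallback beats a
  silent failure;
* all-zero counts in both groups are degenerate: p = 1, frequencies 0,
  flagged.

Inference on b1 is a Wald z-test, with one guard: when every count in
one group is zero the MLE of b1 is infinite and the Wald statistic
collapses toward zero as the standard error diverges (the Hauck–Donner
effect), silently discarding exactly the strongest sites. Such sites are
instead tested by a likelihood ratio: the null is an intercept-only NB
fit across all samples; the alternative's supremum factorizes into an
intercept-only NB fit on the nonzero group plus a zero contribution from
the all-zero group (its likelihood tends to 1 as its mean tends to 0).
The per-site `test_method` column records which test produced each
p-value. At background rates around 0.005 and coverage around 200, a few
percent of genuinely edited sites have all-zero control counts, so this
guard is what makes near-complete recovery possible.

The implementation was cross-checked during development against an
independent brute-force profile-likelihood grid search (the shipped
oracle in the test suite) and agrees to better than 1e-3 in all
coefficients and in log(theta).

Group editing frequencies are estimated per group by the no-intercept
least-squares slope of k on n, `sum(k·n)/sum(n²)`, clipped to [0, 1].
Under unequal coverages this differs from the pooled ratio
`sum(k)/sum(n)`; the pooled ratio is carried as a diagnostic column.
BH adjustment runs once across all tested sites, before the retention
criteria; retention requires diff ≥ 0.1 (inclusive), control frequency
< 0.02 (strict) and FDR < 0.05 (strict).

## Gene scores, differential expression, network

Sites are assigned to every overlapping gene on the matching strand —
the alternative (dropping ambiguous sites) would silently deflate
scores, and assignment-to-all is auditable. The gene score is the plain
sum of differential frequencies, so it is additive over arbitrary
batches of sites.

Differential expression uses a two-sided Wilcoxon rank-sum test on
counts-per-10k-normalized expression, exact when both groups are small
and tie-free, normal-approximation otherwise. Genes are tested when
expressed in ≥ 10% of cells in at least one group; BH runs over tested
genes only. Relative expression is the ratio of de-logged group means
with a pseudocount of 1e-9. The network intersects score ≥ 0.2
(inclusive), relative expression ≤ 0.95 (inclusive) and adjusted
P < 0.05 (strict).

## Motif windows and k-mer enrichment

Target windows are ±100 bp around each retained 3'UTR site, clipped to
the containing UTR (windows never extend into coding sequence), merged
when overlapping, strand-oriented and reported as RNA. Background
segments are 201-bp draws from UTRs at least that long, uniform over
feasible start positions, rejected on any overlap with a target
interval, and fully seeded; sampling aborts with a deficit message after
10× the requested number of rejections.

Every overlapping k-mer occurrence is counted (the simplest convention,
stated so tests can be exact). Enrichment of a k-mer is tested with the
one-sided conditional binomial rate-ratio test: under the null of equal
per-position rates, the target count among the pooled `tc + bc`
occurrences is Binomial with probability `t_pos/(t_pos + b_pos)`. An
unconditional test of the target count against the *estimated*
background rate is anti-conservative whenever the background is not much
larger than the target pool, because the estimate itself carries
sampling noise — in null simulations it produced spurious BH discoveries
in a third of seeds, while the conditional test is calibrated (no
discoveries in ~95% of null seeds, as the test suite checks). The
background pseudocount of 1 survives only in the reported enrichment
ratio, to keep it finite. Occurrence counting (vs per-segment
presence/absence) is the implemented convention.

## Clonal dynamics

A mutation is called when some draw has depth ≥ 100, ≥ 3 variant reads
and VAF ≥ 2%. Classification applies to the baseline-called set (first
draw passes all thresholds): persistent iff the second-draw VAF is
≥ 2%, transient otherwise; records called only at follow-up, or missing
a second draw, stay uncalled. Persistent + transient therefore always
equals the baseline-called count.

The annualized growth rate is r = (VAF2/VAF1)^(1/t) − 1, defined for
positive inputs; it is scale-equivariant in the VAF pair and inverts the
compound-interest forward map to ~1e-10 relative accuracy over realistic
trajectories (for extreme ratio/short-interval corners the 1 + r
cancellation is unrepresentable in doubles — a floating-point limit, not
a modeling one).

Growth is modeled by OLS of r on age, age², baseline VAF, sex, the
protective-allele dosage (0/1/2 — additive coding, matching the usual
GWAS convention) and driver gene one-hot encoded with the most frequent
gene as the reference level. The VAF covariate is the baseline VAF,
since growth is measured from baseline. Rank-deficient designs raise an
error naming the aliased columns. Transience is modeled by maximum-
likelihood logistic regression on the same design; per-driver-gene
refits drop the driver-gene covariate. Columns are standardized
internally for Newton conditioning (age² spans orders of magnitude) and
coefficients mapped back exactly. Separation handling: no penalized
(Firth-type) correction is applied; if the genotype term itself is
non-identified, or the fit predicts every outcome perfectly, a
`SeparationError` is raised with a diagnostic. Divergent coefficients of
*nuisance* factor levels (a rare driver gene with zero transient events)
are tolerated and marked in the `identified` column, since dropping the
whole fit for an empty cell would discard a perfectly regular estimate
of the genotype effect.

## Allelic skew and meta-analysis

Skew at a heterozygous site reports both allele fractions (summing to
1), their fold ratio rounded to one decimal for reporting with the raw
ratio alongside, and the exact two-sided binomial p-value against 0.5.
Zero alternate reads make the fold undefined; the result is flagged
instead of reporting a number. The fixed-effect meta-analysis uses
inverse-variance weights, pooled SE `(sum w)^(-1/2)`, and a 1.96 normal
multiplier for the 95% CI of the exponentiated effect.

## Synthetic data

The editing generator emulates a 3 + 3 design: per-site, per-sample
coverage is negative-binomial (default mean 200, dispersion 2) truncated
below at one read — matching the overdispersion the GLM assumes — and
edited counts are binomial at the group's true frequency. Site classes:
true edits (treatment frequency uniform on a configurable range, control
at the background mismatch rate, default 0.005), background-noise sites,
SNP contaminants (alt fraction ~0.5 or ~1.0 in all samples, mimicking
the germline variants the blacklist removes), and wrong-strand signal
sites that exercise the strand filter. True sites are A>G on forward or
T>C on reverse strands inside annotated 3'UTRs of a generated
non-overlapping gene model with uniform-random sequence. Everything is
emitted alongside a truth table; identical seeds give byte-identical
outputs.

The cohort generator draws a latent growth rate
`r = mean_growth + genotype_effect·dosage + N(0, residual_sd)` per
person, propagates the baseline VAF forward by the compound-interest map
over a uniform inter-draw interval, and resamples both VAFs binomially
at Poisson depths, so the calling thresholds act on realistic read
counts. Defaults: 6.5% heterozygote frequency of the protective allele
(with Hardy–Weinberg-scale homozygotes), baseline VAF Beta(1.2, 4)
scaled to [0.02, 0.40], mean growth 0.005/yr, residual SD 0.10/yr,
genotype effect −0.004/yr, draws 0.7–13 years apart, depth 1725× —
magnitudes chosen once to be realistic for an error-corrected serial
CHIP cohort. Age and sex are independent of genotype by construction, so
covariate-recovery tests have a known-null confounding structure.

What the generator does **not** emulate: read-level artifacts
(alignment, strand bias, UMI errors), doublets or ambient RNA in the
expression matrices, batch structure, linkage between the genotype and
any covariate, and multi-mutation clonal phylogenies. Passing tests
therefore demonstrate the correctness and calibration of the statistics
under the stated sampling models, not robustness to the full artifact
spectrum of real libraries.

## Problem sizes in the shipped checks

The test suite and end-to-end runs use desk-scale sizes chosen as the
package's own validation design: 2,000 null sites for type-I
calibration, 300-site screens over 3 seeds for caller recovery, 100
cohorts of n = 5,000 for regression parameter recovery, 100–200 cells
per group for differential expression, and 100+ background windows per
motif run (the conditional test is calibrated for any sizes, but rate
estimates stabilize when the background is at least a few times the
target pool).
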