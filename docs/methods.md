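# Methods

This note documents the models and procedures implemented in `rejuvenomics`,
the assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical choices a
maintainer should know about.

## Study design the package targets

Three groups of animals: young controls, old controls, and old animals given
one transient cycle of reprogramming-factor (OSKM) induction followed by
recovery ("old-treated" / `old_OSKM`). Assays are bulk: per-CpG bisulfite
counts from RRBS, gene-level expression matrices, and paired pre/post
longitudinal measurements (blood methylation, serum metabolites). Group sizes
are small (4–6 animals), which drives most of the statistical choices below:
empirical-Bayes variance moderation, rotation rather than permutation for
gene-set inference, and exact small-sample nonparametric tests.

## Region-level differential methylation

**Regions.** Promoters are windows −2000/+500 bp around the TSS
(strand-reflected on the minus strand; truncated at contig start with a
flag). Enhancers are H3K27ac peak intervals that do not overlap any promoter
by ≥ 1 bp, linked to the nearest gene TSS when the gap is ≤ 1 Mb (ties broken
deterministically toward the smaller coordinate and flagged). Coordinates are
0-based half-open internally; bisulfite coverage files (1-based inclusive)
are converted on read and write.

**Aggregation.** A CpG enters the analysis only when its coverage is ≥ 5
reads in *every* sample — an all-sample filter, not per-sample — so every
region value is computed on an identical CpG panel across samples. The region
value per sample is the unweighted mean of the retained CpG percentages;
regions with no surviving CpG are dropped and reported.

**Test.** Per region, a binomial GLM with logit link of methylated proportion
on the group indicator, using per-sample counts summed over the region's
retained CpGs; p from the likelihood-ratio test against the intercept-only
model. Because the group-indicator logit model has closed-form MLEs (pooled
within-group proportions), the deviance difference is computed directly
rather than by iterative fitting — identical p-values, two orders of
magnitude faster at thousands of regions. Significance requires raw p < 0.05
**and** an absolute difference of group mean region percentages ≥ 10 points;
no multiple-testing correction enters the call (a BH column is emitted for
information only). The 10-point rule operates on the difference of group
means of region percentages, not per CpG. Degenerate regions (all-0% or
all-100% in both groups) get p = 1 and a flag. A quasi-binomial variant
(deviance scaled by the Pearson dispersion, F reference) is available behind
`quasi=True` for overdispersed data; it is off by default to match the plain
binomial description of the test, and the pooled-count LRT is exactly
calibrated on the generator's data, where counts are binomial given coverage.

## Rejuvenation classification

A feature with an aging gap (young mean ≠ old mean) is rejuvenated when the
treated-old mean is *strictly* closer to the young mean than to the old mean.
Exact ties fail (the rule demands "closer") and are flagged rather than
silently assigned; features without an aging gap are flagged `no_aging_gap`
and never called. Overshoot past the young mean still counts — the rule is
purely metric — but carries an `overshoot` flag for inspection. The rule is
applied only to regions already significant in the DM test, preserving the
order of operations (select aging features first, then ask whether treatment
moved them back). The temporal classifier applies the same predicate at the
end of induction (day 7) and after recovery (day 21), partitioning features
into established-and-retained, established-then-lost, acquired-in-recovery,
and never-rejuvenated. PCA of aging-DM features (feature-centered, optional
unit scaling, zero-variance features dropped with a warning) provides the
visual check that treated-old samples sit between young and old.

## Expression preprocessing, aging-DEGs, signature scores

Raw RPKM-like matrices are log2(x+1)-transformed (pseudocount 1; the choice
only matters near zero), quantile-normalized to the mean empirical
distribution (ties share averaged-rank reference values, so tie-free columns
carry exactly the reference sorted vector), and corrected for sequencing
depth: a gene-wise linear model `value ~ group + total_reads` is fitted and
only the centered total-reads component subtracted. Including group in the
model keeps biology out of the removed component; the same mechanism is
reused for the global-signature correction below, giving one covariate-removal
primitive for both steps.

Aging-DEGs are genes with linear-scale fold change > 1.5 (two-sided, i.e.
|log2FC| > log2 1.5) and raw p < 0.01 between old and young. The default test
is the moderated t (below); a Welch t sits behind `method="welch"`. The
thresholds are the published convention for this analysis; the test behind
"raw p" was an open choice and the moderated t is the one consistent with the
small group sizes.

Gene-set signature scores: expression is z-scored gene-wise across samples;
the set score per sample is the mean z over member genes (sets with < 5
members after intersection are skipped), and the global signature is the mean
z over all genes. Adjusted scores remove the global-signature component of
`set_score ~ group + global`, which recenters each set score on the
association expected of a randomly drawn gene set — the same competitive idea
as restandardization, applied at the score level. The correction is applied
to set-level scores (not per gene before averaging), matching the reading
that it corrects gene-set scores.

## Moderated gene statistics

Per-gene residual variances s² on d degrees of freedom are shrunk toward a
prior (d₀, s₀²) fitted by moment-matching on log variances (mean and excess
variance of `log s² − ψ(d/2) + log(d/2)` identify s₀² and d₀ via the
trigamma inverse). The posterior variance `(d₀s₀² + d·s²)/(d₀+d)` replaces s²
in the t statistic, which has d+d₀ df and is mapped to a z-score by matching
tail areas (survival-function branch for numerical stability; d₀ = ∞ gives
complete pooling, d₀ = 0 the ordinary t — both forceable for testing).
Zero-variance genes receive the shrunken floor variance and a flag.

## Competitive rotation gene-set test

**Statistic.** For member z-scores, s⁺ = mean of max(z,0) and s⁻ = mean of
max(−z,0); the maxmean is s⁺ (direction up) if s⁺ ≥ s⁻, else −s⁻ (down). For
competitive testing both parts are restandardized against their mean and SD
over random same-size gene sets drawn from the catalogue
(`(s⁺−μ⁺)/σ⁺`, `(s⁻−μ⁻)/σ⁻`), and S* is the larger standardized part,
signed. Restandardizing the parts (rather than the signed maxmean itself) is
deliberate: the signed statistic's random-set mean tends to 0 by symmetry as
sets grow, carrying no catalogue information, whereas the part moments
converge to the catalogue's positive/negative-part moments (≈ 1/√(2π) for a
standard-normal catalogue) — which is exactly the behaviour the competitive
correction needs and what the enumeration and closed-form-limit tests check.
Moments come from Monte Carlo (default 2000 random sets, drawn once and
reused) or exhaustive enumeration for small catalogues. A catalogue in which
the random-set statistic has zero variance raises.

**Inference.** The design is reparametrized so the contrast is the last
coefficient; the QR decomposition whitens each gene's data into a
(d+1)-vector whose first component is the signed contrast effect and whose
remainder spans residual space. The observed statistic corresponds to the
fixed first basis vector; each rotation replaces it with one random unit
vector on the (d+1)-sphere *shared across genes*, preserving the inter-gene
correlation that makes rotation valid where sample-permutation is not (small
n, correlated genes). Per rotation, variances are re-estimated from the
remaining coordinates, moderated with the hyperparameters fixed at their
observed-data values, and the restandardized maxmean recomputed against the
rotated catalogue using the same pre-drawn random index sets.
`p_two_sided = (1 + #{|S*_rot| ≥ |S*_obs|})/(B+1)` (hence p ≥ 1/(B+1));
directional p-values are reported alongside because up/down behaviour is
scientifically meaningful. Default B = 9999; the restandardization-per-rotation
placement is the default, with `restandardize_sets=False` exposing the
self-contained statistic (used by the tests to demonstrate that a global
expression shift inflates the unstandardized test while the competitive one
stays calibrated).

**Representation.** The GSEA-style running score (+1/|set| at member
positions, −1/(N−|set|) elsewhere; statistic = signed extremum) is provided
for visualization; it is not the inferential statistic.

## Normal-Normal pattern model

Each feature follows one of the set partitions ("patterns") of the groups —
five for three groups; the rejuvenation pattern is {young, old_OSKM} | {old}.
Within a pattern, samples are Normal(cluster mean, σ_g²) and cluster means
are iid Normal(μ₀, τ²), giving the closed-form cluster marginal

    log m = −n/2·log 2π − (n−1)/2·log σ² − ½·log(σ² + nτ²)
            − SS/(2σ²) − n(x̄ − μ₀)²/(2(σ² + nτ²)),

the multivariate-normal density with compound-symmetric covariance, verified
against adaptive quadrature to < 1e-8 relative error. σ_g² is plugged in as
the pooled within-group variance shrunk 30% toward the cross-feature median
(prevents zero-variance blowups at n = 4–5 per group). EM fits π in closed
form and (μ₀, τ²) by Nelder-Mead on the expected marginal log-likelihood,
with an accept-only-if-not-worse guard so the observed likelihood is
monotone; convergence at relative change < 1e-8 or 500 iterations, from
deterministic starting values. τ² is initialized from the upper tail
(90th percentile) of between-group variances minus the noise floor: the mean
is dominated by null features, and a too-small τ² start collapses EM onto a
degenerate solution in which the all-distinct pattern absorbs everything.
`tau_sq_fixed=0` exposes the analytic limit in which marginals lose all
pattern dependence and posteriors equal the priors. Pattern ids are
canonicalized against the standard group order so they are invariant to
sample-column order (required by the randomization control).

**Selection.** Features sorted by decreasing posterior for the target
pattern; the largest prefix whose mean (1 − posterior) is ≤ the nominal FDR
is selected (Bayesian expected-FDR rule; monotone in the threshold; may be
empty). **Randomization control:** sample-to-group labels are permuted
(sizes preserved), the full fit + selection rerun per permutation, and the
permuted count distribution reported next to the unpermuted count; planted
structure shows up as a large ratio, exchangeable data as a ratio near 1.

The hierarchical model here is self-contained: feature-specific plug-in
variances, shared (μ₀, τ²), patterns as set partitions. Validation is by
parameter and pattern recovery on synthetic data, not by matching any other
implementation's numbers.

## Longitudinal analyses

Δ = post − pre per subject (incomplete subjects listed and excluded;
duplicated subject-timepoint rows are an error). Between-group Δ comparisons
use the Mann–Whitney test with an exact full-enumeration p for groups of ≤ 8
(mid-ranks; two-sided p doubles the smaller tail, the convention under which
the fully separated 4-vs-3 design gives 2/C(7,3) = 2/35 ≈ 0.0571), falling
back to scipy's tie-corrected implementation for larger samples. Within-group
mean-Δ tests use a paired t gated on Shapiro–Wilk at α = 0.05, with a
Wilcoxon signed-rank fallback and flag when normality is rejected. The
methylation clock is an OLS fit of percent methylation on age in weeks, with
multi-CpG panels averaged per animal before fitting; constant ages raise,
flat responses are flagged. Metabolite trajectories are fitted per metabolite
as `value ~ timepoint (+ batch)` with a specimen random intercept (REML,
statsmodels MixedLM) and a Wald test on the timepoint effect; metabolite
intensities are log-transformed by default (raw scale behind a flag), the
two-experiment structure is handled as a fixed batch effect, and singular
random-effect fits or single-timepoint specimens fall back to fixed-effects
OLS with a flag.

## Synthetic-data generators

The generators define the conditions under which the pipeline is validated.
All randomness descends from one seed; per-region sub-streams are spawned
deterministically so adding regions never perturbs earlier ones.

**Methylome.** Young region means p0 ~ Beta(2,2) bounded to
[floor, 1−floor] with floor 0.02 (models bisulfite non-conversion /
sequencing error). 30% of regions age, 55% of those hypermethylate (matching
the observed slight excess of methylation gains), with effects uniform on
20–35 points; 40% of aging regions are rejuvenated with strength 0.8–1.0
(treated mean pulled that fraction of the way back to young). Baselines of
aging regions are rejection-sampled into the sub-interval that leaves room
for the full effect, so planted effects are exact and the full-reversal case
(strength 1) makes treated and young means identical by construction; a
configuration whose effect cannot fit anywhere raises a "degenerate effect"
error. Per-CpG jitter (SD 0.03) is drawn once per CpG and added to every
group's mean, so regions are locally coherent and aggregation is meaningful.
Counts: coverage ~ negative binomial (mean 30, dispersion 5, the study-like
coverage depth), methylated ~ Binomial(coverage, level). An optional fourth
group emulates the day-7 timepoint with per-region retain/lose/acquire
states. Defaults (5 animals/group, 30× coverage) mirror the study design;
group variance components are free parameters of the generator, not estimates
of any dataset.

**Transcriptome.** Gene sets are assigned patterns (default: 50% null, 20%
rejuvenation pattern, the rest spread); member genes share the group-mean
shift (±1 log2 unit) plus a ρ-weighted common latent factor (ρ = 0.3), which
makes the competitive null non-trivial — inter-gene correlation is exactly
what breaks naive set tests. A per-sample library multiplier acts on the raw
scale so preprocessing has a real covariate to remove.

**Pattern features.** Two modes: `model` draws cluster means iid
Normal(μ₀, τ²) — data exactly from the model, for FDR-calibration checks —
and `spaced` draws from the same prior conditioned on a minimum pairwise
cluster separation (default 3 observation SDs), for recovery checks at a
guaranteed effect size. Dispersed per-feature levels are part of the model's
assumptions; planting every null feature at exactly μ₀ is a misspecification
under which no method resembling this one recovers patterns well.

**Longitudinal.** Subject intercepts Normal(baseline, between-SD²), pre/post
values with within-subject noise, so Δ ~ Normal(group Δ, within-SD·√2). The
default scenario (+4 control drift, −4 treated, between-group difference 8)
mirrors the blood-methylation design with 4 vs 3 animals.

**What the generators do not emulate:** read-level artifacts (bisulfite
conversion failure beyond the error floor, mapping bias, UMI structure),
genomic covariates of methylation (CpG density, chromatin state), isoform
structure, heavy-tailed expression noise, batch-by-gene interactions, or
cell-composition shifts. Passing tests therefore demonstrate that the
statistics recover what was planted under their own assumptions at realistic
sample sizes and noise — not that the pipeline is robust to every artifact of
real sequencing data.

## Problem sizes and numerical choices

The test-suite and acceptance-script simulations use 500–2000 regions or
features, 5–20 samples per group, B = 499–1999 rotations and 400–2000 random
sets per restandardization — sizes at which every planted quantity is
recovered with comfortable margin while the whole suite runs in about a
minute. Tolerances: closed-form vs quadrature marginals at 1e-8 relative;
quantile-normalized columns identical exactly; posteriors sum to 1 within
1e-10; Monte-Carlo oracle agreements at 3 SEs. Tie-breaks are deterministic
everywhere (maxmean resolves s⁺ = s⁻ to "up"; nearest-gene ties to the
smaller coordinate; rejuvenation ties to "not rejuvenated"). Degenerate
inputs fail loudly (empty intersections, constant catalogues, zero
within-group variance, constant ages) or are flagged and routed to fallbacks
(separable DM regions, singular random effects, flat clock responses).

## Known limitations

- The DM test on aggregated counts assumes binomial sampling within groups;
  biological replicate overdispersion inflates its p-values (use the
  quasi-binomial flag, at some power cost, when replicates scatter more than
  binomially).
- The pattern model's shared (μ₀, τ²) across all clusters is a deliberate
  simplification; strongly non-Normal feature-level distributions (e.g.
  z-score-bounded signature scores concentrated at one value) violate it.
- Restandardization per rotation reuses one pool of random index sets across
  rotations (a documented budget approximation); with very small catalogues
  use the exhaustive mode.
- The mixed model tests the within-specimen timepoint effect; group × time
  interactions require fitting per group and combining, which the per-batch
  Stouffer mode supports only for batches.
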