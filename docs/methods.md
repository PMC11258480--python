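# Methods

## Scope and data model

The pipeline starts from integer count matrices (features × samples) with a
genotype design: wild type (WT), single mutants A and B, and the double
mutant AB, with replicate and batch labels. Upstream read alignment,
quantification, splicing-event detection and genomic region assignment are
outside the package; their outputs (counts, splicing-event count tables,
feature-category annotations, GMT gene-set files) are its inputs.

## Differential expression

Counts are normalized by per-sample size factors — upper-quartile (75th
percentile of nonzero counts) by default, median-of-ratios as an
alternative — rescaled to geometric mean 1. Log2 fold changes use group
means of normalized counts with a pseudocount of 0.5 per mean, so
zero-count features stay finite; for means above ~100 the pseudocount
perturbs β by less than 0.01.

Two testing paths:

- **Replicated groups** use a Wald test of β against a standard normal, with
  negative-binomial variance μ + φμ². The per-feature dispersion φ is a
  pooled within-group method-of-moments estimate, (s² − μ)/μ², floored at
  1e-8 and squeezed toward the across-feature mean with a fixed prior weight
  of 20 effective degrees of freedom. The squeeze is essential: raw
  per-feature moment estimates at 2–3 replicates make the Wald statistic
  behave like a t with ~4 degrees of freedom read against a normal
  reference (≈12% type-I error at nominal 5%); the squeeze target is the
  across-feature mean rather than the median because the median of few-df
  moment estimates is biased low by the skew of s². With the squeeze the
  null rejection rate at p<0.05 sits at 3–5% on 2000-feature 3v3 panels.
- **No-replicate pairs** (either group a single sample) use an exact
  conditional test: under the null both samples share one expression level,
  and conditioning on the pair's sum n gives a discrete distribution over
  the n+1 splits, negative-binomial with dispersion bcv² (bcv 0.1 by
  default, the standard no-replicate assumption). The two-sided p-value
  sums the probabilities of all splits no more likely than the observed one
  (small-p convention). With equal size factors the distribution is free of
  the unknown mean; with unequal factors the common level is estimated as
  the factor-weighted pooled rate.

DEGs require fold change > 2 **and** BH-adjusted p < 0.05 (both
configurable); β = 0.9 with q = 0.001 is therefore not a DEG. BH adjustment
delegates to `statsmodels.stats.multitest`.

## Epistasis coefficient

Features enter the epistasis fit when their BH-adjusted p is below 0.1 in
the required contrasts. The default requires all three contrasts (A, B, AB
vs WT): x = β_A + β_B and δ = β_AB − x are only jointly informative when all
betas are estimated from real signal. The exception is built in: a
repressive interaction nulls the AB contrast *by construction* (the double
mutant is transcriptionally wild type), so when the triple intersection is
empty the estimator falls back to requiring only the two single-mutant
contrasts and records the fallback in the result metadata.

The coefficient is the through-origin orthogonal-distance regression slope
of δ on x, minimizing Σ(δᵢ − m·xᵢ)²/(1 + m²). Stationary points solve
m²Sxy + m(Sxx − Syy) − Sxy = 0; of the two roots the one with smaller
objective is kept, ties broken toward smaller |m|. Degenerate cases: δ ≡ 0
returns 0 (perfectly additive); Sxy = 0 with Syy > 0 falls back to a dense
grid scan; x ≡ 0 is an error. Orthogonal (rather than ordinary) regression
is used because x and δ carry comparable estimation noise; the slope is
invariant to a common rescaling of all betas and to swapping the A/B labels.

Uncertainty comes from resampling features with replacement (5000
replicates by default; percentile 2.5/97.5 interval). The reported central
value is the bootstrap mean. Resamples with all x = 0 are redrawn up to 10
times, then dropped.

### Model classification

Six candidate architectures are compared. Pseudo-data keep the observed
single-mutant betas (pairing preserved, features resampled with
replacement) and replace β_AB by each architecture's composition:

| model | β_AB | implied δ | analytic s |
|---|---|---|---|
| additive | β_A + β_B | 0 | 0 |
| branched | β_A + ĉ·β_B | (ĉ−1)β_B | interior of (−1/2, 0) |
| unbranched | (β_A + β_B)/2 | −x/2 | −1/2 |
| repressive | 0 | −x | −1 |
| A masks B | β_A | −β_B | data-dependent |
| B masks A | β_B | −β_A | data-dependent |

The branched attenuation ĉ is fit by through-origin least squares of
(β_AB − β_A) on β_B and clipped to [0.1, 0.9]: branched is a composite
family, and the clip keeps it from collapsing onto the additive (ĉ→1) or
masking (ĉ→0) hypotheses it must be distinguished from. The unbranched
composition uses the per-feature mean of the single-mutant betas so it
stays defined when the two vectors differ by noise.

Each model's slope distribution is generated with **common random
numbers** — the identical resampling stream used for the observed
bootstrap. This matters: on data where β_A and β_B are exchangeable, the
two masking hypotheses produce distributionally identical slope statistics,
and with independent streams their ranking would be decided by Monte Carlo
noise. With a shared stream the generating architecture reproduces the
observed replicates exactly (score 0 on noise-free data) while the
alternatives differ by their realized compositions. Models are ranked by
|mean(model s) − mean(observed bootstrap s)|, ascending, with the fraction
of model draws inside the observed 95% CI reported alongside.

On synthetic panels (500 features, unit effect SD, 0.05 log2 noise) the
bootstrap mean recovers 0 / −1/2 / −1 within ±0.05 for the
additive/unbranched/repressive architectures, branched lands strictly
inside (−1/2, 0), and the generating model is ranked first in ≥95% of
seeded noise-free runs for all six architectures.

## Cross-dataset integration

Counts are upper-quartile normalized and transformed as log2(normalized+1),
a monotone stand-in for the regularized-log transform (the shrinkage of the
original rlog is estimator-internal and not reproduced; all downstream
statistics only require a variance-tamed log scale). Unwanted variation is
removed RUVg-style: features with nominal p > 0.1 in *every* supplied
contrast serve as in-silico empirical negative controls; the top-k left
singular vectors of the centered control submatrix (samples × controls)
estimate nuisance factors, and each feature's log expression is regressed
on them with the fitted component subtracted. k = 0 is the identity after
normalization; zero-variance controls yield zero factors and likewise leave
the panel unchanged.

Sample geometry uses classical (Torgerson) MDS — double-centering of the
squared Euclidean distance matrix and eigendecomposition — on the 500
most-variable features of the transformed panel ("top" interpreted as
variance across samples, the conventional selection). Classical MDS is
exact for distance matrices of Euclidean origin, which the tests exploit.
Perturbation similarity uses Pearson correlation of β profiles on the
intersection of finite entries, displayed in average-linkage
hierarchical-clustering order on 1 − r. DEG-set overlaps are reported as
exclusive intersections (UpSet semantics), which partition the union.

## Gene-set enrichment

Preranked GSEA with the classic weighted Kolmogorov–Smirnov running sum:
features ranked by β descending (a signed −log10 p alternative is
available), hit increments |metric|^p normalized over set members (p = 1),
miss decrements 1/(N − set size); the enrichment score is the extreme
running-sum deviation, signed. The null permutes genes (random same-size
sets), because the pipeline consumes contrast summaries rather than
per-sample expression. NES divides the score by the mean |null score| of
matching sign; the FDR q follows the GSEA convention — fraction of pooled
null NES at least as extreme (same sign) over the fraction of observed NES
at least as extreme, capped at 1. Note that all sets scored against one
realized ranked list share that list's tail asymmetry, so per-list mean NES
over a null collection fluctuates more than independent draws would
suggest; calibration checks average over multiple lists. Term-reporting
filters keep terms whose minimum q across conditions passes 0.05 and whose
|NES| exceeds 1.5 in at least 4 conditions, with a dual-rule variant
(≥5 conditions at 1.5 **or** ≥6 at 1.25).

## RNA elements and splicing

Per-category expression (exonic, intron-derived, intergenic, lincRNA) is
the per-sample sum over annotated features; group differences use
two-tailed Welch's t with Satterthwaite degrees of freedom (scipy). The
zero-variance conventions are explicit: equal-mean degenerate groups give
p = 1, unequal-mean give p = 0. Splicing-event counts (events significant
at nominal p < 0.05, split by direction) are tested two-sided with Fisher's
exact test against an explicit background row — the comparator the original
figure leaves implicit — or, alternatively, a binomial 50:50 sign test that
needs no background. Both modes are surfaced in configuration because the
2×2 construction is an interpretation, not a printed rule.

## Consensus network

Pairwise perturbation similarities are scored by absolute Pearson, absolute
Spearman, and mutual information on 8 equal-frequency bins normalized by
the smaller marginal entropy. Each method's off-diagonal scores become
fractional ranks in [0, 1]; the consensus intensity is the mean rank across
methods, rescaled so the strongest link is 1. This rank-aggregation
combiner replaces the original service's trained aggregator, so published
intensity values are reference points rather than reproduction targets;
rank aggregation preserves each method's edge ordering and is invariant to
monotone rescaling of any single method. Links with intensity ≥ 0.8 form
the reported network (SIF and GraphML export).

## Synthetic data generator

The generator emulates the genotype-design experiments the analysis
consumes. Non-null features draw β_A ~ Normal(0, effect_sd²); β_B is
correlated with β_A per the architecture (the branched preset uses
correlation 1 — a shared linear pathway with an attenuated second step —
because with independent single-mutant vectors the attenuated composition
produces slopes below −1/2, outside the branched regime; all other presets
use independent vectors); β_AB follows the architecture's composition, with
the branched attenuation drawn once from Uniform(0.1, 0.9) so the analytic
slope (c−1)/2 lies in (−0.45, −0.05). Gaussian noise (default 0.05 log2
units in tests) is added to all three vectors.

Counts are negative-binomial via a Poisson-gamma mixture: per-feature
wild-type means are log-normal around a configurable depth (default 200,
log-sd 1), genotype g scales them by 2^β_g, per-sample library factors are
log-normal (sd 0.2, emulating normalizable depth variation), and variance
is μ + bcv²μ² (bcv 0.1 by default, matching the no-replicate testing
assumption; bcv = 0 gives the Poisson limit). Batch effects, when enabled,
are per-feature log-normal loadings applied to the second half of each
genotype's replicates — a rank-1 structure in log space. A scalar per-sample
factor would be a pure library-size effect that normalization removes
exactly, leaving nothing for factor correction to do.

All randomness flows through explicit seeds (`numpy.random.default_rng`);
identical inputs and seed reproduce outputs bit-for-bit, which the
end-to-end manifest checksums verify.

What the generator does **not** emulate: count overdispersion heterogeneity
across features (one global BCV), gene–gene correlation beyond the planted
effect and batch structure, transcript-isoform structure, and read-level
artifacts. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to every
property of real RNA-seq.

## Problem sizes and defaults

Default simulated panels use 500 features × 12 samples (4 genotypes × 3
replicates); calibration checks use 2000 features; bootstrap and
permutation defaults are 5000 and 1000 (reduced in unit tests, which the
test code states explicitly). Key thresholds: DEG fold change 2 and
q < 0.05; epistasis selection q < 0.1; empirical controls nominal p > 0.1;
|NES| > 1.5 recurrence filters; link intensity ≥ 0.8; splicing significance
nominal p < 0.05; no-replicate BCV 0.1.

## Known limitations

- The Wald/moderated-moments DE path is a self-contained reimplementation,
  not a DESeq2/edgeR wrapper; shrinkage LFCs, quantile-adjusted conditional
  likelihood and independent filtering are out of scope.
- The regularized-log stand-in does not reproduce shrinkage rlog values;
  only the monotone log scale is preserved.
- The GSEA FDR follows one documented convention; the original tool's
  pooling across set sizes differs in detail.
- The consensus combiner is a documented surrogate for the original
  service's trained aggregator.
- Classification between masking directions relies on asymmetry between the
  realized single-mutant effect vectors; on exactly coincident vectors
  (unbranched data) the unbranched and masking hypotheses are algebraically
  degenerate and the ranking falls back to a fixed candidate order.
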