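# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `methylsel`.

## Data model and coordinates

The unit of analysis is a called cytosine in CpG context, keyed by
`(chrom, position, watson_base)` with 1-based inclusive coordinates (as in
CGmap and GFF3; BED export converts to 0-based half-open at the boundary).
Watson and Crick calls of a symmetric CpG are treated as independent sites
by default, matching per-cytosine caller output; `merge_symmetric_cpgs`
can sum them, but it is off everywhere because the original analysis gives
no indication the strands were merged. Missing data are explicit (NaN
cells in the count matrix), never conflated with observed zero counts.

## Site filters

Filters run in a fixed order, each shrinking the site set and logging the
surviving count:

1. **Minimum coverage** (default 10×): cells below the threshold are set
   missing; sites missing everywhere are dropped.
2. **Invariant extremes**: a site is dropped iff its ratio is 0 in every
   non-missing library or 1 in every non-missing library. The literal
   reading retains a (0%, 100%) site — it is not uniform; a site like that
   is exactly the kind of signal the tests should see.
3. **Coverage percentile** (default keep 99.9%): within each library,
   sites are ranked by coverage ascending and the `ceil(0.999·N)` lowest
   are kept, ties at the cut broken by genomic order; a site survives
   overall only if it survives in every library where it is present.
   Ranking is per library rather than on summed coverage because
   excess-coverage artefacts (collapsed repeats, mapping pile-ups) are
   library-specific. The ceil rule means a single-site library is never
   emptied. Note this cut removes a fixed fraction by construction, so it
   is monotone but not idempotent.
4. **Presence**: pooled design — present in every pool; paired design —
   present in ≥14 of 16 individuals **and** in ≥7 complete families,
   where a family counts only if both siblings are present. The
   completeness requirement guarantees the GLMM always sees matched pairs.

## Pooled two-group test

With one library per group the binomial logistic model is saturated, so
the MLE and its Wald standard error have closed forms (difference of
empirical logits; square root of the sum of reciprocal cell counts). We
use the closed form and verify it against an IRLS fit (statsmodels GLM)
to ≤1e-6 in tests. The Wald z (not a likelihood-ratio test) matches the
default coefficient summary of standard GLM software. Zero cells mean
complete separation: those sites are flagged, refit iteratively so the
reported finite-precision numbers match what a GLM fitter prints, and
excluded from DMC calling — but they still count toward the Bonferroni
denominator, which uses the number of sites entering testing.

## Family GLMM

Per site, for sibling j of family f:

    c_j ~ Binomial(n_j, expit(beta0 + beta1 * I[FE] + u_f)),  u_f ~ N(0, sigma_u^2).

The marginal likelihood factorizes over families; each one-dimensional
integral is evaluated by Laplace approximation at the posterior mode of
u_f (found by damped Newton, warm-started between optimizer steps; the
integrand is strictly log-concave so this is globally convergent).
Adaptive Gauss–Hermite quadrature centred and scaled at the same mode is
available with any node count and serves as the accuracy oracle: on
simulated sites at study scale (8 families, 20× coverage) the Laplace and
51-node estimates of beta1 agree to ~3e-4. A frozen cross-check against R
lme4's `glmer` (the conventional fitter for this model) agrees to ~1e-5
in all three parameters.

Numerical choices:

* The variance is parameterized as s = log(sigma) with box bounds
  [-8, 2.5]; fits with sigma_u^2 < 1e-6 are flagged `singular` (boundary
  estimate, as `glmer` reports for these data sizes). Responses that are
  all-methylated or all-unmethylated make the intercept diverge and are
  flagged `nonconverged` rather than raised.
* Optimization is L-BFGS-B on (beta0, beta1, s) with the analytic
  gradient of the Laplace objective, obtained by implicit differentiation
  through the posterior mode including the curvature term; the gradient is
  verified against finite differences in tests. Convergence uses the
  optimizer's projected-gradient tolerance (1e-5, configurable).
* The Wald SE of beta1 comes from the inverse observed information of
  (beta0, beta1) at the optimum with the variance parameter held fixed —
  the conventional mixed-model Wald summary. p = 2(1 − Φ(|z|)).
* Per-site fits are independent; the implementation is sequential and
  deterministic, so any parallel execution must reproduce it byte-for-byte.

### Overdispersion statistic and HPD filter

λ = Σ_j r_j² / k with r_j the Pearson residual at the conditional
(family-specific) fitted mean and k = 2 × (2 fixed + 1 random) = 6. The
denominator convention (counting the intercept among fixed effects) is
configurable since it only rescales λ; the subsequent filter ranks sites,
so the choice does not change which sites are removed. The genome-wide λ
values of converged, non-singular fits define an empirical 95%
highest-density interval, computed as the shortest window of
`ceil(0.95·N)` consecutive order statistics (ties broken toward the
lowest window). Sites outside the interval — over- or under-dispersed
relative to the binomial GLMM — are excluded from DMC calling, together
with singular and non-converged fits. An order-statistic interval was
chosen over a density-smoothed one because it is exact, deterministic and
assumption-free on ≥20 values.

## DMC calling

A site is a DMC iff −log₁₀(p) exceeds −log₁₀(α/N) (α = 0.05, N = sites
entering testing after filters) **and** the absolute FE − SE
methylation-ratio difference exceeds 0.10. The difference is the mean of
per-sample ratios in FE minus that in SE (for pools, the single pooled
ratios); positive values mean hypermethylation in fast explorers.

## Feature annotation

Windows per gene, strand-aware and clipped at position 1, with the
analysis' literal definitions as defaults: promoter = 200-bp window whose
far edge lies 2,000 bp upstream of the gene start; TSS region = 50-bp
window whose far edge lies 300 bp upstream of the TSS; gene body = the
annotated span; upstream/downstream = 10 kb beyond the gene start/end.
The promoter and TSS windows are unusual in not touching the TSS; they
are kept literally but every anchor and length is configurable. The
published up/downstream phrasing anchors upstream at the transcription
termination site and downstream at the TSS, which appears transposed;
the defaults here use the conventional anchors (upstream of the gene
start, downstream of the gene end). When a site hits several windows the
most specific class wins (TSS > promoter > gene body > upstream >
downstream), and cross-gene ties go to the gene with the nearest start.

## Profiles

Sample profiles are per-site methylation ratios over complete-case sites.
The dendrogram uses d = 1 − Pearson r and Ward's criterion applied to
the unsquared dissimilarities (the classical `ward.D` behaviour, matching
the original analysis; `ward.D2` is selectable). The agglomeration is a
direct Lance–Williams implementation with index-based tie-breaking —
scipy's linkage only offers the squared-dissimilarity variant — and is
validated against frozen R `hclust` merge heights for both variants. PCA
is column-centred SVD with the largest-magnitude loading of each
component forced positive. QQ tables use expected quantiles
−log₁₀((i − 0.5)/n); Manhattan tables use cumulative per-chromosome
offsets. Rendering is deliberately left to the caller: the contract is
the plot-ready tables.

## Synthetic cohorts

The generator emulates the study geometry: 8 families × 2 extreme
siblings (paired design) or two 6-member pools (pooled design); per-site
counts follow the binomial logit-normal hierarchy of the GLMM above, with
coverage drawn negative-binomial (mean 15, size 8 by default — matching
the 10–18× library averages — clamped to ≥1) and optional per-cell
dropout. Baseline levels mix a hypomethylated Beta(0.4, 12) component
(TSS-proximal sites, mean ~3%) with a Beta(8, 8) component near 50%; the
RRBS preset solves the mixture weight so the expected cohort mean is 16%,
the level reported for CpG-enriched reduced-representation libraries.
Group effects are spiked on the logit scale via a helper that converts a
desired ratio-scale difference at a site's baseline into a logit shift
(published candidate effects span 10–36 points, which the default spike
table mirrors). Fractions of invariant (all-0/all-1) and
extreme-coverage sites can be injected to exercise the filters.
Random-effect SDs default to sigma_fam = 0.5 and sigma_ind = 0.3 on the
logit scale — moderate familial clustering, chosen so sibling profiles
correlate strongly without being duplicates, as observed for the real
cohort's family-dominated dendrogram.

Randomness: one root seed; every stream (genome, site parameters, each
sample) derives from `SeedSequence(root, spawn_key=(k,))` with a fixed
stream key, so outputs are byte-identical across runs and adding samples
never perturbs earlier draws.

What the generator does **not** emulate: read-level error and bisulfite
conversion failure, sequence context (no real CpG spacing or islands),
SNP interference with C/T calls, mapping artefacts, and any non-binomial
technical overdispersion beyond the injected logit-normal effects.
Passing tests therefore show the pipeline is correct and calibrated under
its own model class, not that the model is adequate for any particular
real library.

## Calibration conditions used in tests

Two deliberate choices in the simulation-based checks:

* The null type-I-error check simulates mid-methylated sites
  (Beta(8, 8) baselines) with sigma_ind = 0. Calibration of a binomial
  test is only interpretable where the data carry information (at 3%
  methylation and 15× coverage most samples have 0–1 methylated reads and
  the Wald p-distribution is dominated by discreteness), and a nonzero
  individual effect deliberately violates the fitted model, which is the
  overdispersion filter's job, not the calibration check's. Under these
  conditions the retained-site p < 0.05 fraction sits at ~0.05 and zero
  sites reach the Bonferroni threshold at N = 2,000.
* The pooled null-calibration check uses homogeneous pool members
  (sigma_fam = sigma_ind = 0): biological variation between pool members
  induces genuine extra-binomial variance that the two-cell binomial test
  cannot see, and inflates its significance. That inflation is a real
  limitation of pooled designs (see below), not an implementation error,
  so the calibration check is run under the test's own model.

Problem sizes in tests and in `scripts/acceptance.py` (2,000-site null
cohorts, 100-site oracle comparisons, 300–500-site recovery sets,
800-site clustering cohorts) are chosen to put Monte-Carlo error well
inside the asserted tolerances while keeping the default runs fast.

## Known limitations

* The pooled test treats each pool as one binomial draw; between-member
  biological variance is invisible to it and inflates significance. The
  paired GLMM plus λ filter is the principled route for individual data.
* Wald inference with 8 families is mildly anti-conservative in the
  tails; the analysis leans on the stringent Bonferroni + effect-size
  rule rather than on exact small-sample p-values.
* The λ denominator phrase ("two times the number of fixed and random
  effects") admits several readings; k = 6 is the default here and only
  the HPD ranking matters.
* Annotation is gene-level only: no transcript isoforms, no exon/intron
  subdivision, no CpG-island track.
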