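# Methods

## Scope and data model

The package implements an exposome-omics-wide association scan and its
downstream analyses for a multi-cohort child study design. Inputs are
tab-delimited sample-by-variable matrices: an exposome table of mixed
continuous/categorical exposures annotated with window (pregnancy or
childhood), family and correlation group; one matrix per omics layer
(methylation betas in [0,1], log2 expression/miRNA/protein/metabolite
abundances); a covariate table (cohort, sex, age, zBMI, ancestry, maternal
education, technical extras); and optional feature genomic annotation
(BED-like 0-based half-open intervals, converted to 1-based point
positions, strand-aware TSS for transcripts). Missing exposure values are
rejected at load time: imputation is an upstream concern and deliberately
out of scope, as are assay preprocessing and reference-curve zBMI
computation.

Samples are aligned as the intersection of exposome, covariate and layer
sample IDs, in exposome order, separately per layer; every association
record carries the n actually used.

## The association model

Each exposure-feature pair is fit by ordinary least squares with classical
two-sided t-tests. Continuous exposures are entered as x / IQR(x) with the
linear-interpolation quantile definition, so the coefficient is the
per-IQR effect; an IQR of zero is a hard error. Categorical exposures are
reference-coded against their first declared level, one record per
contrast. Outcomes are used on their declared scale, so coefficients read
as log2 fold changes (log2 layers) or methylation-level differences.

We chose classical OLS over an empirical-Bayes moderated-variance fit: at
the sample sizes this design targets (hundreds to ~1300), variance
moderation changes almost nothing, while plain OLS is exactly testable
against the normal-equations closed form (the suite checks agreement with
an independent reference implementation at 1e-8 relative tolerance). A
moderated variant could be slotted behind the same interface later.

Fitting is vectorized: for each exposure, one design factorization serves
all features of a layer simultaneously (multi-outcome OLS), which is what
makes 25-seed simulation studies and the full scan cheap on one CPU.

A guard requires at least (design columns + 10) samples per model; the
bound is exposed as a parameter because tiny pedagogical examples are
legitimate uses of the single-pair fitter.

## Surrogate variables

Genome-wide layers (methylation, expression, miRNA) receive surrogate
variables: the feature matrix is residualized on the known covariates and
the top-K left singular vectors of the residual matrix are added to every
model for that layer. K is chosen by permutation parallel analysis:
component i is retained while its singular value exceeds the 95th
percentile of the i-th singular values from 20 matrices whose columns were
independently row-permuted. With only 20 permutations the percentile is
estimated with the discrete "higher" method; interpolated percentiles put
the null false-retention probability near 2/21 per run, noticeably above
the nominal 5%, while the discrete estimate is conservative. These latent
covariates stand in for whatever shared structure the measured covariates
miss — in blood omics practice, batch effects and cell-type composition
jointly. Targeted panels never receive SVs. SVs are standardized to unit
variance; adding them changes effects and SEs, never the record count.

## Multiple testing

Correction is applied independently per exposure within each layer.
Genome-wide layers: BH-FDR, significant at q <= 0.05. Targeted layers: the
effective number of tests ENT = sum_i [ 1(lambda_i >= 1) + (lambda_i -
floor(lambda_i)) ] over eigenvalues of the feature Pearson correlation
matrix, and significance at p < 0.05 / ENT. ENT is computed once per layer
on the analysis samples, not per exposure stratum, so the thresholds are
per-layer constants. Eigenvalues are rounded to 8 decimals before the
integer/fraction split; without this, an exactly duplicated feature whose
eigenvalue lands at 10 - 1e-12 would contribute ~1 spurious test through
the fractional term. Constant features are excluded with a warning. A
global cutoff p < 1e-09 — the order of 0.05 divided by the tens of
millions of tests a full two-period, six-layer scan performs — flags the
strongest associations on top of the per-layer rules.

BH itself delegates to statsmodels and is oracle-checked against a
brute-force "minimum over the tail" step-up implementation, exactly, on
random vectors with ties.

Note on realized error rates: BH controls FDR within each
exposure-by-layer stratum. Pooling flags across many all-null strata
(e.g. pregnancy copies of exposures that only act in childhood) mixes in
strata whose every discovery is false, so the pooled realized FDP can
exceed the nominal level even when every stratum is controlled. The
calibration experiments therefore report both the per-stratum FDP (the
quantity BH bounds) and the pooled FDP over the planted-exposure strata.

## Sensitivity analyses

Percent effect change between a main and an alternative model is
(beta_main - beta_alt) / beta_main * 100, undefined (NaN, logged) when the
main effect is exactly zero, and flagged when its magnitude exceeds 100 —
"more than a doubling". Model variants provided: ancestry-restricted and
zBMI-unadjusted.

Per-cohort meta-analysis: fixed effects with weights 1/se^2 (beta = sum
w b / sum w, se = (sum w)^-1/2), Cochran's Q = sum w (b_i - beta_fixed)^2,
DerSimonian-Laird tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),
random-effect weights 1/(se^2 + tau^2), and I^2 = max(0, (Q-(k-1))/Q) x
100 (0 when Q = 0; NaN for a single cohort, where fixed = random = the
cohort estimate). Per-cohort models drop the cohort covariate; SVs are
recomputed within a cohort only when it has >= 100 samples, otherwise the
global SVs restricted to the cohort's rows are reused — a deliberate
bias/stability trade-off for small cohorts, switchable via the function's
parameters.

Multi-exposure models: for each feature significant for more than one
exposure (per period), candidates are reduced to one representative per
correlation group (smallest single-exposure p, ties lexicographic), then
pairs with correlation magnitude >= 0.8 are pruned greedily, strongest
first. The exposure correlation matrix uses Pearson r for continuous
pairs, sqrt(R^2) of the one-way fit for continuous-categorical and
Cramér's V for categorical pairs, so all mixed-type entries live in [0,1];
whether the 0.8 cutoff is compared against the magnitude (default) or
against R^2 itself is a config switch, since either convention is
defensible. Features retaining >= 2 exposures get one joint OLS with all
selected exposures plus the standard covariates; a singular joint design
drops the weakest collinear exposure and logs it. Correlation groups
default to the exposure family, except members of diet, metals and
parabens, which each form their own group.

## Networks

Significant associations of one period form an undirected bipartite graph:
exposures and features as nodes, one signed edge per exposure-feature pair
(multiple categorical contrasts collapse to the smallest-p contrast's
sign). Topology statistics: mean degree 2E/N; average shortest path as the
mean BFS distance over unordered reachable pairs, counted in edges by
default with a switch for the node-counting convention (edges + 1), since
either reading appears in applied network summaries; statistics are
computed on the full period network by default, with a flag for the
display subset (components with >= 2 molecular features, the convention
used for network figures). Communities come from deterministic greedy
(CNM) modularity maximization on the largest connected component; smaller
components keep their component as their cluster; the partition modularity
is reported. Exact parity with layout-coupled GUI clusterers is not a
goal — summaries are structural. Cluster summaries rank exposures by
within-cluster association count and tally per-layer features and unique
annotated genes across CpGs, transcripts, miRNAs and proteins. Exports:
GraphML plus node/edge TSVs.

## Cross-layer integration

cis-eQTM candidates are all same-chromosome CpG-transcript pairs with
|CpG - TSS| strictly below 500 kb (strand-aware TSS). Each pair is fit as
expression ~ methylation + age + sex + cohort, with BH across all pairs at
0.05 for the significance flag — the multiple-testing rule is ours and is
stated rather than inherited, and both window and level sit in the config.

miRNA-target concordance consumes an externally supplied miRNA-to-gene
map (target prediction itself is out of scope) and retains (exposure,
miRNA, gene) triples where a target transcript is nominally associated
(p < 0.05) with the same exposure in the direction opposite to the miRNA
effect (higher miRNA, lower target expression).

Cross-matrix replication: a significant exposure-metabolite association in
one biofluid replicates if the mapped metabolite in the other fluid is
nominally associated with the same exposure and — by default, a stricter
choice than nominal-p alone, switchable off — with the same sign.
Fractions are reported per direction; the two directions have different
denominators by construction. Unmapped features leave the denominator
(logged); an empty denominator yields NaN, never 0.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not any real cohort's distributions. Covariates are drawn per sample with
cohort assignment over up to 6 cohorts (ancestry ~90/8/2%
European/Pakistani/other, zBMI standard normal, age uniform on 6-11).
Exposure families are block-equicorrelated Gaussians (within-family rho,
zero across families); the childhood copy of each variable correlates with
its pregnancy copy at rho_p (default 0.2, reflecting the low inter-period
correlation typical of these designs); categorical exposures arise by
median-thresholding the latent Gaussian. Features are intercept +
small covariate effects + planted per-IQR effects + (genome-wide layers)
dense latent factors on a random 30% of features + Gaussian noise (SD 0.5
by default, putting single-feature R^2 for a 0.3-0.5 per-IQR effect in the
few-percent range typical of omics signals). Methylation is simulated on
the logit scale and squashed, with intercepts near logit(0.5) so planted
logit-scale effects are approximately the methylation-difference effects
the models estimate; the truth table records the pre-squash coefficient
with a scale tag. The adiposity-confounding scenario adds
zBMI -> pollutant and zBMI -> protein paths with zero direct effect.
Cohort-heterogeneous effects (for exercising I^2) multiply planted betas
by per-cohort factors, off by default.

The default "mini" scenario — 300 samples, 2 cohorts, 40 exposures over 7
families, five layers of 500 (methylation) + 100 (expression) + 50 + 30 +
50 features — runs the full pipeline in seconds and is the basis of most
tests. Everything is driven by numpy's seeded Generator through a spawned
seed sequence: identical scenarios give bit-identical fixtures.

What passing tests on these fixtures do not show: robustness to
non-Gaussian exposure distributions, detection-limit censoring,
platform-specific noise, missing-data mechanisms, or real LD-like
correlation along the genome. They do establish the estimators' algebra,
calibration under the stated model, power at planted effect sizes, and
the determinism of the whole pipeline.

## Numerical choices and degenerate inputs

- Quantiles: linear interpolation (the common default of mainstream
  numeric stacks), making IQR translation-invariant and scale-equivariant.
- Text I/O uses 17-significant-digit floats and round-trip parsing, so
  write/read cycles are bit-exact.
- p-values are floored at the smallest positive double; plot tables cap
  -log10 p rather than emitting infinities.
- Singular designs raise with the offending column indices; the
  multi-exposure fitter instead drops the weakest collinear exposure and
  logs the decision.
- Zero-variance exposures yield NaN correlation entries with a warning;
  zero-IQR exposures are hard errors at fit time.
- Ties in BH need no special handling; group-representative and pruning
  ties break by smallest p, then lexicographically, so selection is
  deterministic under input permutation.

## Problem sizes used in validation

Calibration and power experiments use n = 1000 with a 500-feature
genome-wide layer over 25 seeds, and 50 replicates for the 0.30 per-IQR
recovery check; the null-calibration scan uses the mini scenario's 29 200
models. These sizes put Monte-Carlo error well below the tolerances being
checked while keeping the whole suite under a minute of compute for the
statistical parts.

## Known limitations

- No variance moderation, robust/clustered SEs, or mixed models; no
  omnibus F-test option for categorical exposures (per-contrast t-tests
  only).
- ENT is a spectral approximation; for panels with strong block structure
  it can differ from permutation-based effective-test counts.
- Greedy modularity is order-deterministic but not globally optimal;
  cluster counts on dense networks should be read qualitatively.
- The per-cohort SV policy (reuse vs recompute at the 100-sample cutoff)
  is a heuristic; both variants are exposed.
- The generator plants linear, homoscedastic effects only.
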