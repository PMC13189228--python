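# Methods

## The single-variant selection model

For variant *j*, samples (or sample clusters) indexed by *i* contribute
allele counts `y_i ~ Binomial(d_i, p_ij)` with

```
logit(p_ij) = alpha_j + s_j * t_i + g_i,     g ~ MVN(0, sigma_j^2 K).
```

The logit link makes the model linear in time under genic selection:
the expected per-generation change of the log-odds of an allele's
frequency is approximately its selection coefficient, independent of
the current frequency. `t_i` is the negative sampling date in units of
twice the generation interval (default 29 years per generation; the
factor two reflects the two allele transmissions per diploid
generation), so `s_j` reads directly as a per-generation coefficient
and modern samples sit at `t = 0`.

`K` is the genetic relationship matrix (GRM): the empirical covariance
of standardized genotypes, built leave-one-chromosome-out (LOCO) so a
variant is never tested against relatedness estimated partly from
itself or its LD neighbors. The random effect `g` absorbs whatever
frequency variation is predictable from relatedness — shared ancestry,
migration, admixture, drift along the genealogy — and `sigma_j^2` sets
its per-variant scale. Both `alpha_j` and `sigma_j^2` are re-estimated
at every variant; the test for selection is whether `s_j` is non-zero
*beyond* what that structure explains.

### Clusters as binomial units

Fitting the GLMM per variant at full sample size is quadratic-to-cubic
in n, so samples are grouped into ancestry–date clusters: agglomerative
(Ward) clustering on the top 30 PCs of the GRM, then, within each PC
cluster, complete-linkage clustering on dates with a distance threshold
G (default 500 years). Complete linkage is chosen deliberately: it is
the one standard linkage that guarantees the max-gap invariant (no two
members of a cluster more than G years apart). A binary search on the
number of PC clusters targets T total clusters (default 2000; tests use
tens), accepting within T±1 or returning the best clustering seen if
the search interval collapses. A cluster's time is the mean member date
(the MLE under symmetric date error; the median is a defensible
alternative, and the choice is internal to `ClusterSet`). Cluster-level
covariance is the GRM block average
`K_mn = mean over (i in c_m, j in c_n) of A_ij`, which preserves
positive semidefiniteness.

### Fitting: penalized quasi-likelihood

PQL iterates a working linear mixed model: with `mu = logistic(eta)`,

```
z = eta + (y/d - mu)/(mu(1-mu)),   W = d * mu(1-mu),
z = X b + g + e,   e ~ N(0, W^-1),   V = W^-1 + sigma2 K.
```

Per outer iteration we eigendecompose `W^(1/2) K W^(1/2)` once, which
turns the REML profile in `sigma2` into a cheap 1-D problem solved by
bounded scalar optimization on `[floor, 50]`; `(alpha, s)` come from
GLS and the random effect from its BLUP. Convergence is a relative
parameter change below 1e-5 within 100 outer iterations; the
`converged` flag is honest (false at the iteration cap). Standard
errors are Wald, from the inverse expected information of the working
LMM at convergence — with `sigma2 = 0` and `K = I` the scheme *is*
Fisher scoring for logistic regression, and the test suite pins that
equivalence to the statsmodels GLM fit.

We do not monitor a monotone objective: the penalized working
quasi-likelihood is not a Lyapunov function of the iteration once
`sigma2` is re-estimated by REML (a different objective), and flagging
its fluctuations as failures marked demonstrably converged fits wrong.
Parameter-change convergence matches standard PQL engines.

Initialization: `alpha` from the Haldane-corrected pooled frequency,
`s = 0`, `sigma2` at the floor. Degenerate variants (count 0 or d in
every cluster) are skipped with status `monomorphic`.

### The variance floor

An unconstrained `sigma2` can collapse to zero at individual variants,
letting the time term absorb drift and inflating false positives. The
floor is estimated genome-wide: unconstrained fits at randomly drawn
variants, binned by MAF (equal-count bins), per-bin median, then
isotonic smoothing across bins (direction picked by rank correlation —
the drift scale generally rises with MAF on the logit scale, but the
data decide). The per-bin median is our choice of "genome-wide estimate
conditional on MAF"; it is robust to the long right tail of per-variant
estimates. Floors are enforced by clamping the REML search interval.

### Variance explained and windows

The proportion of logit-scale frequency variance attributable to
selection is `s^2 var(t) / (s^2 var(t) + sigma2)` with `var(t)` the
empirical variance of cluster times. Time-resolved coefficients come
from refitting in sliding windows (default 2000 years, step 100,
minimum 2000 samples per window; tests scale these down), with modern
samples excluded from windowing — their density would pin the window
median date to zero — and the point-estimate series smoothed by a
rational-quadratic GP (nugget 1e-5, length-scale bounds (1, 1e6)).

## Calibration

The naive Z is inflated by unmodeled features (imputation biases,
pervasive LD with true signal), and median-chi-square rescaling is
invalid when much of the genome carries signal. Calibration instead
uses an external truth set: the rate at which variants beyond a
threshold are independently GWAS-significant. The enrichment curve is
the hit rate beyond each |X| threshold divided by the MAF-matched
expected rate (20 equal-count MAF bins by default; the threshold-0
point is exactly 1 by construction), smoothed by isotonic regression;
its plateau `E_max` is the mean of the smoothed top decile. The default
rescale factor is 1.51 — the ratio of the empirically calibrated
threshold (8.23) to the two-sided normal quantile at 5e-8 (5.45) — and
is configurable because it is data-derived.

The posterior probability of selection uses the unique linear mapping
consistent with a two-group mixture in which only true signals are
enriched: `pi(X) = clip((E(X) - 1)/(E_max - 1), 0, 1)`, `FDR = 1 - pi`.
Independent loci are chosen greedily (max |X| above threshold, prune
r² > 0.05 in a caller-supplied reference panel, repeat; ties broken by
genomic position).

### HAF scores

A haplotype's HAF is the sum, over window sites at which it carries the
derived allele, of the derived-allele count (the classic first-order
HAF; a squared-count variant is exposed via `exponent=2` because the
statistic's one-line verbal descriptions in the literature are
ambiguous between the two). The summary statistic is mean(HAF)/n.
Sweeps concentrate high-frequency derived alleles on the sweeping
haplotypes and raise it; background selection lowers it; so the
evidence statistic is the residual after OLS on background-selection
covariates. The covariate matrix is caller-supplied: real analyses
would pass annotations such as B-statistics alongside window SNP count
and heterozygosity; the synthetic tests use SNP density and
heterozygosity only. No annotation downloads are bundled.

## Polygenic tests

Trait SNP sets come from two-step clumping of the trait's own GWAS:
greedy P-ordered clumping (P < 1e-3, prune r² ≥ 0.05 within 500 kb),
then greedy D′ pruning (prune D′ > 0.2 within 500 kb). r² is the
squared dosage correlation in the LD panel; D′ uses haplotype
frequencies counted directly when phased haplotypes are available and
otherwise estimated by EM from genotypes (50 iterations, tol 1e-8).

The polygenic score is the weighted dosage sum (weights = betas, or
their signs for robustness to effect-size error), centered at the
modern-sample mean and scaled by the modern-sample *standard deviation*
— the natural reading of scaling "by the spread of the modern scores"
so the trend coefficient is in modern-SD units; a per-individual score
has no standard error, so SD is the only coherent interpretation.
Missing dosages are filled with the variant's modern-mean before
weighting (never in the GLMM response).

The trend model is `y_i = alpha + t_i*gamma + g_i + e_i` with
`t = -date/10000` (gamma per ten millennia), `g ~ MVN(0, sigma_g^2 K)`,
`e ~ MVN(0, sigma_e^2 I)`, fit by REML on the GRM spectrum with the
variance ratio profiled out; with `sigma_g^2 = 0` the estimate equals
OLS (pinned in tests).

Residual inflation is corrected per trait by sign-flip randomization:
100 re-fits with random ±1 weights on the same SNPs,
`lambda = clip(median(Z^2)/0.455, 1, 3.16)` — 0.455 being the printed
chi-square(1) median — and `Z_adj = Z/sqrt(lambda)`. Division by
`sqrt(lambda)` follows from lambda being a chi-square scale factor. The
cap 3.16 is an across-trait median inherited from a large real cohort;
it is a configurable constant here because it is data-derived. The
randomizations re-run the full LMM rather than reusing cached variance
components (the GRM eigendecomposition *is* cached, so this costs only
a 1-D REML search per draw).

The locus-dropping robustness curve removes, at each step, a region
around the SNP with the largest `|beta * s * f(1-f)|` (its expected
contribution to the score trend) — ±1 cM with a genetic map, else ±1 Mb
under the 1 cM/Mb convention — and re-runs the test until significance
is lost, distinguishing oligogenic from genuinely polygenic signals.

## Trajectories

Raw (deliberately structure-uncorrected) frequency tracks: sliding
windows of 1000 years stepping by 100, binomial MLE per window,
`SE = sqrt(p(1-p)/2n)`, Jeffreys credible intervals (the Beta(1/2,1/2)
posterior; any standard binomial interval would do, Jeffreys behaves
well at boundary counts). A sample belongs to the window centered at c
if its date is in `[c - w/2, c + w/2)` (half-open; no double counting
within a window). Smoothing is a GP with a rational-quadratic kernel,
observation noise 1e-4 and length-scale bounds (10, 1e6), posterior
mean and SE clipped to [0, 1]; hyperparameters by marginal-likelihood
maximization from a fixed start, so results are deterministic. Grouped
point estimates (e.g. archaeologically defined source populations) use
the same binomial machinery.

## The simulator

`synth_cohort` emulates a structured time transect: Balding–Nichols
per-population frequencies (Beta around a shared ancestral frequency,
FST-like divergence, default 0.05 — typical of diverged West-Eurasian
source populations), logit-scale random-walk drift per 1000-year epoch
(default SD 0.05 per millennium), optional admixture events (frequency
mixing at a dated event), dated samples uniform over the configured
range (default 500–10000 BP, plus moderns at 0), binomial genotype
draws, and injected deterministic logit-linear selection at chosen
variants. Ancestral frequencies fold a uniform MAF in [0.05, 0.5] to a
random orientation (a real modern frequency spectrum would be used when
data are available; uniform keeps every MAF bin populated for
floor/enrichment machinery).

`simulate_variant` is the scan's generative model verbatim —
`g ~ MVN(0, sigma2 K)`, `p = logistic(logit(f0) + s t + g)`, binomial
counts — so parameter recovery against it tests the inference engine,
not the simulator. PSD is validated with tolerance
`-1e-8 * trace/n` on the smallest eigenvalue (small negatives clipped).

What a green test does and does not establish: the simulator has no
linkage (variants independent given structure), no sequencing or
imputation error, no sampling bias correlated with ancestry, and its
sweep/neutral haplotype windows are exchangeable-site caricatures
(logistic sweep + distance-decaying hitchhiking), not coalescent
simulations. Green tests establish internal correctness and calibration
under the stated model; robustness to realistic confounders at
biobank scale is out of desk-scale reach.

## Numerical choices

- Working-response clipping of mu at 1e-10; sigma2 search bounded at 50.
- GLMM convergence: max relative parameter change < 1e-5, 100 outer
  iterations; gamma-LMM REML on log variance ratio in [-12, 12] with an
  explicit boundary comparison at ratio 0.
- PCA signs fixed by "largest-magnitude loading positive"; binary
  search midpoint floor((l+r)/2).
- Clumping and loci ties broken by (chrom, pos); missing r² against a
  monomorphic panel variant treated as linked (conservative pruning).
- The chi-square(1) median is used at its printed precision 0.455 so
  the inflation factor matches the published definition exactly.

## Known limitations

- PQL is first-order: at very small cluster counts or extreme
  frequencies its variance components are biased; the variance floor
  and the empirical calibration layer are the practical mitigations.
- s is assumed constant in space and time within a window; fluctuating
  selection is diluted (windowed refits recover only slow variation).
- The enrichment calibration needs an external GWAS truth set with hits
  rare relative to the variant panel; with pervasive true signal in the
  baseline the plateau, and hence pi, is depressed.
- Exact per-window trajectory CIs and several clustering internals
  (linkage, cluster-time statistic) are underdetermined by the method's
  published description; the choices above are recorded, not inferred.
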