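# Methods

`trimetaqtl` implements a two-stage, three-layer integrative association
analysis linking SNP gene doses, blood gene expression and targeted
metabolomics (amino acids and acylcarnitines), together with a synthetic
cohort generator that plants known effects so every stage can be scored
against ground truth.

## Statistical model

All pairwise associations are covariate-adjusted ordinary least squares.
For a trait y, a focal predictor x (a gene dose in [0, 2] or a transcript
level) and covariates C,

    y = α + βx + Cγ + ε,

with a two-sided p-value from the t distribution at df = n − (#regressors).
Listwise deletion is applied per test and the complete-case n is reported,
so n varies across tests exactly as complete-data analysis sets do.  The
focal predictor's explained variance is the partial R²,

    R²_partial = t² / (t² + df),

which equals (RSS_reduced − RSS_full)/RSS_reduced; the test suite asserts
this identity against an explicit two-model fit.  The scan implementation
uses the Frisch–Waugh partialling-out identity: covariates (plus intercept)
are projected out of both sides once per missingness pattern, after which
every (SNP, trait) slope, SE and t statistic is a vectorized cross-product.
This is algebraically identical to per-pair OLS (asserted to 1e-10).

## Metabolite preprocessing

Order is fixed and enforced: derive → dichotomize → transform → mask.

1. **Derived quantities.** Ratios ((Σ numerator)/(Σ denominator)) and sums
   are computed on the raw concentration scale *before* transformation —
   arsinh of a ratio is not a difference of arsinhs, so the order matters.
   A zero denominator yields a missing value (counted and logged).
2. **LOD dichotomization.** A quantity with strictly more than 20% of
   values below its limit of detection becomes binary (0 = below,
   1 = above).  Exactly 20% stays continuous.  Dichotomized traits run
   through the same OLS engine (a linear probability model); the trait kind
   is recorded in outputs.
3. **arsinh transform.** x ↦ ln(x + √(x²+1)): log-like for large values,
   defined at zero, roughly variance-stabilizing for skewed positive
   concentrations.
4. **Outlier masking.** Values outside mean ± 5 SD of their column are set
   missing.  Column statistics are computed once on the pre-masking data
   (a single interval rule, not iterated), so every surviving value lies
   within the original interval.

## Expression preprocessing

Probes are kept when detected (detection p ≤ 0.05) in at least 5% of
samples.  Each sample's value distribution is then mapped onto the mean
quantile profile (ties receive the mean of tied quantiles) and log2-taken.
Three sample-outlier rules follow, each at median + 3·IQR (the count rule
two-sided at median ± 3·IQR): (1) number of expressed genes; (2) Euclidean
distance to an "artificial individual", the mean profile after removing
the ⌈10% n⌉ samples farthest from the plain mean (the exact trim count is a
recorded choice, since "10% of samples" may be fractional); (3) Mahalanobis
distance of per-sample QC features to the average QC individual, with a
ridge of 1e-6·trace/dim added if the QC covariance is singular.  The
Euclidean rule operates on normalized values (it precedes batch adjustment
in the chain).

Batch adjustment harmonizes per-probe batch means and variances.  The
default `eb` mode shrinks per-probe batch location/scale parameters toward
their across-probe means with a moments-estimated normal / inverse-gamma
prior — a deliberately compact empirical-Bayes location-scale adjustment
whose contract (batch moments harmonized; infinite-prior limit gives one
affine correction per batch) is what the tests pin down.  `meanscale` is
the no-shrinkage special case and is the identity on a single batch.

Finally each probe is residualized on covariates (age, sex in the
synthetic design) and then on the first five principal components of the
covariate-residualized matrix.  Re-estimating PCs on an already
residualized matrix necessarily finds further directions, so strict
re-application idempotency is impossible; instead the function can return
the PC scores it used and re-applying the projection with that fixed basis
is a no-op (asserted), and covariate-only residualization is idempotent
outright.

## Two-stage mQTL design

The discovery scan tests every (SNP, quantity) pair and keeps the full p
table.  A liberal cut-off of 1e-7 defines the top list; study-wide FDR is
controlled at 5% with empirical q-values against a permutation null in
which the metabolite block as a whole is re-assigned to the genotypes
(1000 permutations by default).  Permuting the block preserves LD among
SNPs and correlation among metabolites — the exchangeable null for
correlated multi-trait scans; sample-level covariates stay attached to the
genotypes so the null reflects covariate-adjusted exchangeability.  The
pooled-count estimator is used:

    FDRhat(t) = mean over permutations of #{null ≥ t} / max(1, #{obs ≥ t}),
    q(s) = min over thresholds t ≤ s of FDRhat(t), capped at 1.

Lead SNPs are pruned greedily: order SNPs by minimal p across metabolites,
retain the best, drop everything at LD r² ≥ 0.3 with a retained SNP,
repeat.  Loci are single-linkage merges of lead SNPs within 1 Mb on a
chromosome (the merge distance is a recorded assumption; it matches the
cis-window scale and is configurable).

Replication pairs each top SNP with its best proxy in the replication
panel: candidates within ±50 kb, imputation info > 0.3, LD computed in the
*discovery* cohort, best r² above 0.8.  Allele orientation is the sign of
the discovery dose correlation between lead and proxy (dose-based rather
than allele-string matching; synthetic data has no strand ambiguity).
A pair is replicated when sign(β_rep·orientation) = sign(β_disc) and its
one-sided empirical q (signed z oriented by the discovery direction,
against the replication permutation null) is ≤ 0.05.  The replication
covariate set omits the genetic principal components.

## eQTL mapping and triangles

Lead SNPs are tested against all prepared probes; a pair is cis when SNP
and probe center share a chromosome and are at most 1 Mb apart
(inclusive), otherwise trans.  Significance uses separate Benjamini–
Hochberg thresholds within the cis and trans layers at FDR 5%, optionally
confirmed by permuting expression sample labels and estimating the
realized FDR at the fixed thresholds (100 permutations by default).

Expression–metabolite associations are tested on the triangle candidate
grid only — eQTL-significant probes × metabolites associated at the
corresponding SNP — with BH at 5% within that grid.

An association triangle is a SNP significantly associated with a probe and
a metabolite whose probe–metabolite edge is also significant.  Strict mode
follows the study recipe (top SNP per locus, its best metabolite, that
SNP's significant eQTL probes); exhaustive mode enumerates all significant
closures for the network view.  The null expectation is estimated by
shuffling the expression block and (independently) the metabolite block
against the genotypes and re-running the entire chain — including lead
re-pruning, with a switch to freeze leads — with identical thresholds.
Inside the null (and the observed triangle chain) the mQTL layer uses the
fixed 1e-7 cut-off rather than nested permutation q-values: the
re-analysis runs "with the same cut-offs", and a nested 1000-permutation
FDR inside each of 100 pipeline permutations would change the estimand
while being computationally pointless.  The observed count k is compared
with a Poisson tail P(X ≥ k) at λ̂ = mean permutation count.

## Causal inference

For each triangle, with dose g, transcript e, metabolite y and covariates C:

* **Adapted Mendelian randomization.**  A direct SNP→metabolite path
  violates the exclusion restriction of plain MR, so the metabolite is
  first residualized for the *remaining direct* SNP effect: fit
  y ~ g + e + C, take the SNP coefficient c, set y* = y − c·g, and form
  the covariate-adjusted IV ratio β_MR = β(y* ~ g + C)/β(e ~ g + C).
  Under a direct + mediated generating model this provably restores the
  mediated-path effect (tested: a 0.3 direct path leaves the recovery of a
  planted 0.4 unbiased within jackknife error).  Instruments with |t| < 2
  for e ~ g are flagged weak and receive no p-value.
* **Beta-attenuation mediation test.**  β_SNP from y ~ g + C versus
  y ~ g + e + C on the same complete-case set; Δ = |β_without| − |β_with|
  is tested against zero.  The |·|-difference reading of the attenuation is
  a recorded choice.  This test is the more conservative of the two and
  drives causal conclusions.

Both use leave-one-out jackknife SEs,
SE = √(((n−1)/n)·Σᵢ(θ₍₋ᵢ₎ − θ̄)²), with a two-sided normal reference
(justified at cohort-scale n).  The replicates use the exact closed-form
leave-one-out OLS update β₍₋ᵢ₎ = β − (X'X)⁻¹xᵢeᵢ/(1−hᵢ) — identical to
brute-force refitting to machine precision (asserted) at O(np²) total cost.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed:

* **Cohorts.** 2000 discovery and 1000 replication individuals drawn
  independently from the same founder pools; the replication panel drops a
  random 10% of SNPs so proxy search is exercised.
* **Genotypes.** 500 SNPs in 5-SNP LD blocks.  Each block has a pool of 10
  founder haplotypes; an individual draws two per block (no recombination
  within a block, independence across blocks).  Per-SNP target MAFs are
  drawn from U(0.10, 0.45) with small within-block jitter; blocks carrying
  planted effects use nested carrier sets so block mates are strong
  proxies (r² near 1), other blocks mix nested and random carrier sets for
  a realistic LD spectrum.  Dose = allele count + N(0, 0.05²) truncated to
  [0, 2], mimicking imputation; the info field is 1 − noise/dose variance.
* **Expression.** 120 probes on a latent Gaussian scale: planted per-dose
  effects + per-(batch, probe) shifts N(0, 0.3²) across 4 batches + N(0,1)
  noise.  Cis targets are placed within 1 Mb of their SNP, trans targets
  on another chromosome.  Positive intensities 2^(latent+8) feed the
  normalization chain; six trailing probes are below the detection floor
  in ~98% of samples and exercise the detection filter.
* **Metabolites.** 24 quantities: latent = direct SNP effects + transcript
  effects + covariate effects (age/sex on odd columns) + N(0,1), mapped to
  a skewed positive scale by exp(latent + 3) so the arsinh step is
  meaningful.  Each column's LOD is its 2% quantile; two trailing columns
  use the 30% quantile and are dichotomized downstream.  Default derived
  definitions add one ratio and one sum over null metabolites.
* **Planted design (20 effects).** 8 direct SNP→metabolite effects of
  0.30 SD/dose, 4 mediated SNP→probe→metabolite chains (cis eQTL 0.70,
  transcript→metabolite 0.50, marginal SNP effect 0.35), 2 standalone cis
  eQTLs (0.50) and 2 trans eQTLs (0.40).  Sizes were chosen once so that
  every planted mQTL clears the 1e-7 discovery cut-off with near
  certainty at n = 2000 and the mediated chains yield detectable triangles
  with realistic explained variances (cis eQTL ≈ 13–16%).
* **Covariates.** age ~ N(60, 10²), sex ~ Bernoulli(0.5), three synthetic
  genetic PCs ~ N(0, 1).  The generator reproduces the adjustment set's
  structure, not real confounding.

What the generator does **not** emulate: recombination gradients within
loci, population structure and relatedness, assay drift between plates,
non-Gaussian expression noise, metabolite missingness mechanisms other
than the LOD, and strand ambiguity.  Passing tests therefore demonstrate
the correctness and calibration of the machinery under exchangeable,
well-specified noise — not robustness to the full messiness of cohort
data.

## Numerical choices and problem sizes

Permutation defaults follow the study design (1000 mQTL, 100 eQTL/triangle
permutations).  The test suite and the acceptance script shrink
permutation counts and some cohort sizes (e.g. 200 permutations for the
FDR calibration, 20 pipeline permutations for the triangle null, bundles
of 400–700 individuals for permutation-heavy checks) — sizes chosen so the
checks are sharp at interactive runtimes; the statistical conditions
(effect sizes, planted fractions, n = 2000 wherever a check depends on
power) are kept.  Degenerate inputs are handled explicitly: zero-SD
metabolite columns mask nothing (warning), monomorphic SNPs raise in
single fits and return NaN within vectorized scans, singular QC
covariances are ridge-regularized, collinear covariates are dropped with a
warning, BH layers with no rejection report a zero threshold, and
λ̂ = 0 with k ≥ 1 observed triangles gives a Poisson tail of 0.

## Known limitations

* The linear probability model for dichotomized traits ignores
  heteroscedasticity near prevalence extremes.
* The empirical-Bayes batch adjustment is a compact location-scale
  shrinkage, not a full published-method clone.
* Single-instrument MR only; no pleiotropy-robust estimators, no
  bidirectional testing.
* Locus definition (1 Mb single linkage) is a convention, not an
  inference.
* VCF input is read-only and expects DS or GT.
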