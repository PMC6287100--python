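# Methods

## Model and statistics

All association fits are ordinary least squares of a standardized trait on
allele dosage (plus intercept, plus standardized covariate traits for the
conditional model). Standardization is always performed within the analyzed
complete-case sample with the population-variance convention (ddof = 0), so
that sample regression coefficients on the standardized scale coincide with
(partial) correlation algebra.

The residual variance uses the $\hat\sigma^2 = \mathrm{RSS}/n$ convention,
and the reported test statistic is

$$T_u^2 = n\hat\rho_{yg}^2/\hat\sigma_u^2, \qquad
  T_c^2 = n\hat\beta_{g,\mathrm{std}}^2/\hat\sigma_c^2 ,$$

with the standard error defined accordingly as
$\mathrm{se}(\hat\beta_g) = \sqrt{\hat\sigma^2/(n\,\widehat{\mathrm{Var}}(g))}$
on the per-allele scale (so $T^2 = (\hat\beta/\mathrm{se})^2$ always holds
on the record). This convention — rather than the textbook OLS standard
error $\sqrt{s^2 (X'X)^{-1}_{gg}}$ with $s^2 = \mathrm{RSS}/(n-p)$ — is a
deliberate design choice: it is the convention under which the log-ratio
decomposition below is an exact algebraic identity. The textbook Wald
standard error differs by the factor $\sqrt{(X'X/n)^{-1}_{gg}} =
1/\sqrt{1-R^2_{g|C}}$ and by the degrees-of-freedom adjustment; both are
available via `se_mode="ols"` on the scan functions for standard-error
reporting, but the decomposition and all shipped defaults use the
$\mathrm{RSS}/n$ convention. For a genuinely associated SNP the two differ
by $O(\rho_{cg}^2)$; under the null, where the SNP is independent of the
covariate traits, the difference is $O(k/n)$ and the default statistic is
very slightly conservative.

## The noise/pleiotropy decomposition

Writing $\hat\beta_{g,\mathrm{std}} = \hat\rho_{yg} - \sum_i \hat\beta_i
\hat\rho_{gi}$ (the conditional normal equations on the correlation scale)
gives the exact identity

$$\log_{10}\frac{T_c^2}{T_u^2} =
  \log_{10}\frac{\hat\sigma_u^2}{\hat\sigma_c^2} +
  \log_{10}\Big[1-\frac{1}{\hat\rho_{yg}}\sum_{i=1}^k \hat\beta_i\hat\rho_{gi}\Big]^2 .$$

The identity requires both fits to use the *same sample*. Conditional
records therefore carry $\hat\rho_{yg}$ and $\hat\rho_{gi}$ for their own
analysis sample, and `decompose_from_conditional` reconstructs the matched
univariate fit from them ($\hat\sigma_u^2 = 1-\hat\rho_{yg}^2$), which
guarantees the identity (enforced to 1e-9) and the nesting property
noise ≥ 0 even when the full-sample univariate scan used a different
complete-case set. `decompose_log_ratio` accepts an explicit (uGAS, cGAS)
record pair and raises if the identity fails, which indicates mismatched
samples.

Degenerate cases: $|\hat\rho_{yg}| < 10^{-8}$ (the log-ratio is dominated
by a near-zero denominator) and a bracket of exactly 0 (true conditional
null; the ratio is $-\infty$) are flagged rather than reported.

## Covariate selection

Covariates for trait $y$ are its direct neighbors in an undirected trait
network, sorted lexicographically for determinism. The network is either
supplied (BN mode, e.g. fatty-acid biosynthesis / β-oxidation adjacency) or
estimated as a Gaussian graphical model: full-order partial correlations
$\hat r_{ij} = -\Omega_{ij}/\sqrt{\Omega_{ii}\Omega_{jj}}$ from the inverse
trait correlation matrix, p-values from
$t = \hat r\sqrt{(n-m)/(1-\hat r^2)}$ on $n - m$ degrees of freedom
(conditioning on $m-2$ traits), and an edge where
$p \le \alpha_{\mathrm{total}}/\binom{m}{2}$ with
$\alpha_{\mathrm{total}} = 0.01$ by default (for 151 traits this is the
8.83e-7 cutoff). Partial correlations use one coherent complete-case sample
for the whole matrix; a numerically singular correlation matrix is a fatal
error (regularized precision estimation is out of scope). A trait with no
measured neighbors falls back to the univariate fit, tagged as conditional
with zero covariates, so BN-mode scans degrade gracefully.

## Summary-level conditional fit

Given univariate rows $(\hat\beta, \mathrm{se}, n)$ for the SNP against the
target trait and each covariate, each row yields the sample correlation
through $\hat\rho = z/\sqrt{n-2+z^2}$ — exact when the summary SEs follow
the classical $\mathrm{RSS}/(n-2)$ convention, which is what
`records_to_summary_stats` writes. With the trait correlation matrix
$R_{cc}$ and $\rho_{yc}$, the conditional coefficients solve
$P\beta = s$, $P = \begin{bmatrix}1 & \rho_{g\cdot}'\\ \rho_{g\cdot} &
R_{cc}\end{bmatrix}$, $s = (\rho_{yg}, \rho_{yc\cdot})$, with
$\hat\sigma_c^2 = 1 - s'\beta$. On the standardized-genotype scale this
reproduces the individual-level fit to machine precision (the equivalence
is tested to 1e-6 over 50 datasets). The per-allele effect divides by
$\mathrm{sd}(g) = \sqrt{2\,\mathrm{eaf}(1-\mathrm{eaf})}$ (Hardy–Weinberg),
the only scale information a summary row carries; it therefore differs from
the individual-level per-allele effect by $O(1/\sqrt n)$ sampling noise in
the genotype variance, while the standardized-scale quantities
(`beta_std`, `se_std`, `chi2`) agree exactly. When per-row sample sizes
differ, the minimum across the involved rows is used and recorded. A
non-positive-definite $P$ (mutually incompatible inputs) is a fatal error
reporting the smallest eigenvalue.

## Preprocessing

Traits are adjusted in a fixed order: OLS residualization on the nuisance
covariates (sex, age as numeric, batch one-hot with reference level
dropped; collinear design columns are dropped with a warning), then the
rank-based inverse-normal transform
$\Phi^{-1}((\mathrm{rank}-c)/m)$ with offset $c = 0.5$ by default
(configurable; $c = 3/8$ gives a Blom-style variant) and average ranks for
ties. Missing values stay missing; a constant trait cannot be transformed
and is a per-trait fatal error.

SNP QC thresholds default to call rate ≥ 0.95, imputation R² ≥ 0.3, HWE
p ≥ 1e-6 and MAF ≥ 0.01; all configurable (a stricter MAF ≥ 0.1 is a
supported setting). Call rate and MAF are recomputed from dosages; the HWE
goodness-of-fit test (1-df χ² against $p^2 : 2pq : q^2$) runs on hard
genotypes obtained by rounding dosages only when every non-missing dosage
is within 0.1 of an integer — imputed fractional dosages carry no genotype
counts, so HWE is skipped for such SNPs with a warning. Absent metrics
never exclude a SNP. The filter is monotone in its thresholds.

## Genomic control, loci, comparisons

Genomic control is applied per (trait, model) scan:
$\lambda = \mathrm{median}(\chi^2)/0.45494$, dividing the statistics only
when $\lambda > 1$ (deflated scans are not inflated). P-values are computed
with `scipy`'s 1-df χ² survival function, accurate to below 1e-300, and the
inverse quantile is used when reconstructing statistics from published
p-values.

Loci are purely physical: significant hits (GC-corrected p when available)
on one chromosome chain together while successive positions are < 500 kb
apart; a gap of ≥ 500 kb (or a chromosome change) starts a new locus. The
locus representative is the member with the smallest p (ties: smaller
position, then trait name). Scan comparison scores each locus by its
maximum χ² per method, keeping — when several SNPs in a locus hit the same
trait — only the SNP with the lower p-value under the reference scan, and
summarizes the paired per-locus maxima with their mean ratio and a
two-sided Wilcoxon signed-rank test (p reported as 1 when all differences
are zero).

## Simulator

`simulate_dataset` draws allele dosages $g \sim \mathrm{Binomial}(2, f)$
and builds traits on the standardized genotype $g^*$:
$c_i = b^{\mathrm{cov}}_i g^* + \varepsilon_i$,
$y = b^{\mathrm{direct}} g^* + \sum_i b^{\mathrm{med}}_i c_i +
\varepsilon_y$ with $(\varepsilon_y, \varepsilon) \sim N(0, R)$, unit
residual variances, and traits standardized afterwards so population
correlations equal the closed forms used by the analytic machinery. The
`b_med` vector expresses mediation paths (trait loading on covariates),
needed for the mediation regime. Null SNPs share the scenario MAF and are
independent of all traits. Randomness uses one master `SeedSequence`;
power experiments spawn one substream per replicate, so replicates are
independent and individually reproducible, and the same seed is
bit-reproducible.

Named scenarios fix the study conditions: *discordant* (b_direct = 0.15,
b_cov = −0.25, residual correlation +0.6), *concordant* (same with
b_cov = +0.25), *mediation* (b_direct = 0, b_cov = 0.4, b_med = 0.5),
*null* (all zero), each at n = 2000, MAF 0.3. `power_experiment` reports
empirical rejection fractions at the scenario α with binomial Monte Carlo
standard errors, together with the noise/pleiotropic components evaluated
analytically at the population parameters (via the same correlation-scale
solve as the summary-level fit).

One design note on the power comparisons: at the discordant scenario's
default effect sizes the univariate analytic power at α = 1e-4, n = 2000
is ≈ 0.998 (noncentrality ≈ 45 against a critical value of 15.1), so both
empirical powers sit at 1.0 in most 500-replicate runs and a strict
power comparison is uninformative. The power-contrast test therefore uses
b_direct = 0.08 — chosen from the analytic power curve (univariate ≈ 0.4,
conditional ≈ 1.0) so the strict dominance of the conditional scan is a
property of the model rather than of a particular seed — while the
default-parameter scenario is exercised for the exact per-replicate
theorem: whenever the estimated discordance condition
$\sum_i \hat\beta_i\hat\rho_{gi}/\hat\rho_{yg} < 0$ holds, $T_c^2 > T_u^2$
with no sampling error involved.

### What the generator does and does not emulate

It reproduces the features the method's behavior depends on: binomial
dosages at a controlled allele frequency, controlled genetic and residual
trait covariance, network-structured covariate sets (star/chain/custom),
and exact seed reproducibility. It does **not** emulate linkage
disequilibrium between SNPs, polygenic background, non-Gaussian residuals,
assay missingness patterns, batch structure, or ascertainment — so passing
tests demonstrate correctness of the statistics and the power theory under
the stated model, not robustness of the method to those real-data
complications.

## Numerical choices and edge cases

- Complete-case analysis per (SNP, trait, covariate-set); the partial
  correlation matrix uses one complete-case sample for coherence.
- Monomorphic SNPs in an analysis sample are skipped and counted, never
  fitted.
- Covariates that are exactly collinear are dropped greedily (rank test),
  recorded on the result; a SNP collinear with its covariate set is
  skipped.
- The genomic-control reference constant is the exact 1-df χ² median from
  `scipy`, 0.454936…
- Effect alleles follow the VCF ALT (or `effA` column); dosages outside
  [0, 2] are rejected at construction.
- Floats are written with 17 significant digits, making every
  reader/writer pair a lossless round trip.
- Pipeline outputs embed a hash of the analytical configuration (output
  directory excluded) so re-runs are byte-identical and provenance-checked.

## Problem sizes used by the shipped test suite

The suite exercises a 1000-SNP × 10-trait conditional scan at n = 500 for
the identity checks, 50 datasets at n = 500 for the summary/individual
equivalence, 100 replicates at n = 5000 for GGM edge recovery, and
500–1000 replicates at n = 2000 for the power and unbiasedness
experiments — sizes at which every Monte Carlo criterion has comfortable
resolution while the whole suite runs in well under a minute on one CPU.

## Known limitations

- No LD-aware clumping or joint multi-SNP conditional analysis; loci are
  physical-distance clusters only.
- No mixed-model or kinship adjustment; genomic control is the only
  inflation correction.
- Binary traits, meta-analysis, regularized (graphical-lasso) networks and
  low-order partial correlations are out of scope.
- The summary-level route assumes the trait correlation matrix and the
  univariate rows come from (approximately) the same sample; incompatible
  inputs surface as a non-positive-definite predictor matrix.
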