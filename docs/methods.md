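# Methods

## Model

For one biallelic SNP and two zero-centered phenotypes y_i = g_i β_i + e_i
(i = 1, 2), with genotypes g coded 0/1/2 under Hardy–Weinberg equilibrium at
coding-allele frequency f, the per-SNP effects (β_1, β_2) are treated as
random with variances σ²_β1, σ²_β2 (allele-count scale) and correlation r_G,
and the residual pairs are correlated r_E only for the N0 individuals
present in both studies. The least-squares estimate β̂_i = g'_i y_i / g'_i g_i
has sampling variance σ²_βi + σ²_i (g'_i g_i)⁻¹, and with the HWE
approximation g'g ≈ 2f(1−f)N the correlation of the Wald Z-scores
z_i = β̂_i / sd(β̂_i) is

cor(z1, z2) =
  [2f(1−f)√(N1N2) r_G σ_β1 σ_β2 + (N0/√(N1N2)) r_E σ1 σ2]
  / [√(2f(1−f)N1 σ²_β1 + σ²1) · √(2f(1−f)N2 σ²_β2 + σ²2)].

Setting σ_β = 0 — or letting f → 0 — collapses this to
(N0/√(N1N2))·r_E: the phenotypic correlation times the overlap shrinkage
factor. Two consistent estimation strategies follow:

- **Low-MAF estimator** (recommended): Pearson correlation of the two
  traits' Z-scores over SNPs with minor allele frequency strictly below a
  cutoff (default 5×10⁻⁴). The filter constrains the genotype, never the
  association statistic, so no selection bias on the Z-scores arises.
- **Z-cut estimator** (comparator): the same correlation over SNPs with
  |z| strictly below a bound on *both* traits. Conditioning a bivariate
  normal on the box |Z1| < c, |Z2| < c attenuates its correlation — e.g. at
  true ρ = 0.5 and c = 1 the truncated correlation is 0.183 — so this
  classical "putative null SNP" strategy is biased toward zero. The filter
  is applied jointly on both traits.

In a polygenic background, the "residual" of any single tested SNP contains
every other SNP's genetic effect, so the low-MAF Z-score correlation
estimates the full phenotypic correlation of the realized sample, not the
residual correlation parameter alone. With partial overlap, dividing the raw
correlation by N0/√(N1·N2) recovers the full-overlap value; the package
never clamps the adjusted value to [−1, 1] and instead flags out-of-range
results, because clamping would hide the instability the adjustment develops
as N0 → 0 (flagged below an overlap fraction of 0.1; at N0 = 0 the summary
statistics carry no information about r_P at all and the adjustment refuses
to run).

## Standard errors and p-values

Rare variants are in near-linkage-equilibrium, so the selected Z-score pairs
are treated as independent observations of a bivariate distribution. The
p-value of the estimate is the two-sided Pearson t-test with n_snps − 2
degrees of freedom; the reported SE is back-calculated from it as
|r| / Φ⁻¹(1 − p/2), falling back to the analytic √((1−r²)/(n−2)) at r = 0.
The back-transform runs in log space (`scipy.special.ndtri_exp`); for
statistics so extreme that the t log-survival underflows, Wallace's
normal-quantile approximation of the t tail is used. The back-calculated SE
exceeds the analytic SE increasingly with |r| (≈ +8% at r = 0.5, ≈ +12.5%
at r = 0.6, for any n ≥ 100) because the t and normal tails diverge at large
|t|; this mild conservatism is inherent to the recipe.

The independence approximation has a regime of validity worth stating: each
rare variant's Z-score is driven by its few carriers' phenotype values, so
when the number of selected rare SNPs approaches the sample size the
Z-scores share carriers and the effective information saturates at n. The
reported SE then understates the replicate-to-replicate SD. The estimator
itself remains unbiased in that regime (it tracks the realized
individual-level correlation); only the SE calibration degrades. Real
applications (hundreds of thousands of samples, tens of thousands of rare
SNPs) sit comfortably inside the valid regime.

## Harmonization

Two tables are aligned on shared variant ids. A variant whose effect/other
alleles in the second table are swapped relative to the first has its
Z-score negated (and allele frequency mirrored); a variant whose allele sets
disagree even after the swap check is dropped and counted — strand flips are
never guessed, because silent strand resolution corrupts the sign of exactly
the quantity being estimated. Palindromic (A/T, C/G) variants are dropped by
default since their orientation is unresolvable without frequency
heuristics. Per-SNP MAF is min(eaf, 1−eaf) taken from the first trait's
table by default (configurable to the second table or the mean); variants
lacking a field the downstream filter needs are dropped, never imputed.
Frequency-free dialects (LDSC `SNP A1 A2 N Z`) are supported for the
all-SNP and Z-cut estimators via `require_maf=False`.

## Simulator

`simulate` generates what the validation study needs and nothing more:

- **Genotypes**: independent binomial(2, f) draws (as two Bernoulli
  haplotypes), no LD, no population structure. In-sample monomorphic SNPs
  are dropped from GWAS output.
- **MAF spectrum**: default log-uniform on [10⁻⁴, 0.5], chosen so each
  cutoff in {0.05, 0.005, 5×10⁻⁴} retains a usable SNP count (tail mass
  ln(c/10⁻⁴)/ln 5000). Point and uniform spectra are available.
- **Phenotypes**: a single causal set of round(causal_prop·m) SNPs shared
  by both traits; effect pairs bivariate normal with correlation r_G;
  residual pairs correlated r_E on the overlap block only (individuals
  ordered [overlap | trait-1 only | trait-2 only]); phenotypes
  mean-centered. The implied population correlation is
  r_P = r_G √(h²1 h²2) + r_E √((1−h²1)(1−h²2)).
- **Effect scale**: by default effects have constant per-SNP variance on
  the allele-count scale, σ²_β = h²/Σ 2f(1−f) over the causal set, so a
  variant's explained variance is ∝ 2f(1−f) and vanishes as f → 0 — the
  mechanism by which the MAF filter removes genetic contamination when SNPs
  are simulated without LD. The `standardized` option instead draws
  variance h²/M per standardized causal column, mirroring polygenic
  simulations on real genotype panels, where rare variants shed explained
  variance through low LD rather than low heterozygosity.
- **GWAS**: per-SNP simple least squares of the centered phenotype on the
  mean-centered genotype, SE from that SNP's own residual variance with
  n − 2 df. Z-scores are invariant to genotype rescaling, so 0/1/2 coding
  suffices. Binary traits are produced by thresholding the continuous
  liabilities at the (1 − prevalence) quantile, and their GWAS uses the same
  least-squares score on the 0/1 outcome (linear-probability Z), since the
  Z-score correlation — which then targets the liability-scale correlation —
  is the object of interest.
- **Determinism**: every randomized operation accepts a seed or Generator;
  the study runner spawns an independent child stream per
  (scenario, replicate), so results are bit-reproducible and independent of
  scenario order.

What the simulator deliberately omits — LD structure, population
stratification, genotyping error, covariates — bounds what passing tests
show: they validate the estimator's selection logic, the overlap algebra and
the SE recipe under the model's own assumptions, not robustness to
confounding (the real-data virtue of rare variants, whose noisiness only
pushes their genotypes closer to the pure-noise ideal, has no desk-scale
analogue here).

## Validation-study design choices

The replicated studies in `tests/test_acceptance.py` use desk-scale sizes
chosen once: 2,000 individuals × 20,000 SNPs × 50 replicates for parameter
recovery (true r_P = 0.5 recovered within 0.02); 30 replicates for the
zero-overlap null, SE calibration and the shrinkage law; ≥ 2,500 single-SNP
replicates per point for agreement with the closed form (within 3 Monte-
Carlo SEs on a 6-point grid over f, overlap and r_G).

Two designs are regime-sensitive at desk scale and were set accordingly:

- *SE calibration* (n = 1,000) uses a 6,000-SNP panel so the rare subset
  (~430 SNPs) stays well below the sample size, per the independence-regime
  argument above. The observed mean-SE/SD ratio is ≈ 0.86.
- *Shrinkage law* uses the r_G = 0 grid cell and a 0.05 MAF cutoff: with
  r_G = 0 there is no genetic contamination at any frequency, and
  carrier-rich SNPs avoid an ascertainment subtlety of ultra-rare variants
  at small n — a variant with a single carrier can only be polymorphic in
  both GWAS if that carrier lies in the overlap, which drags the effective
  shrinkage of the retained set toward 1. At production sample sizes a
  5×10⁻⁴ variant has dozens of carriers and the effect disappears.

## Numerical choices

- Truncated-bivariate-normal oracle: tensor-product Gauss–Legendre
  quadrature, 201 nodes per axis on [−c, c]²; the integrand is entire, so
  the moment error is far below the documented 10⁻⁴ bound and values are
  bit-reproducible (cross-checked against a 10⁷-draw Monte-Carlo sample).
- Correlation filters use strict inequalities (maf < cutoff, |z| < cutoff).
- Estimates are refused below 3 SNPs; a warning is emitted below 100.
- GWAS is vectorized in 4,000-column blocks (float64 accumulation) to bound
  peak memory; residual sums of squares are floored at 0.
- When no overlap specification is given, fully overlapping samples are
  assumed (shrinkage 1) and logged prominently.

## Limitations

- No LD modelling anywhere: the closed form is single-SNP, and simulated
  SNPs are independent. Multi-SNP LD effects enter real data only.
- The Bonferroni-only multiple-testing policy matches the intended
  pairwise-matrix use; no FDR option.
- Genetic-correlation and heritability estimation, LD-score regression and
  reference-panel computations are out of scope.
- The liability-scale claim for binary traits is validated qualitatively
  (sign and approximate magnitude), not with a sharp attenuation formula;
  unbalanced case–control Z-statistics are inflated per SNP, which the
  cross-trait correlation tolerates but the per-SNP calibration does not.
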