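# Methods

## The model

Disease liability for individual *i* at age bin *a* (five baseline-age
quintiles spanning 40–79 years) is

    L_ia = G_i + E_i + sum_{b <= a} e_ib,        e_ib ~ N(0, sigma2_EA)

where `G` is the additive genetic component (variance h²), `E` the baseline
environmental component (variance 1 − h²), and the `e_ib` are independent
per-bin environmental increments — the *exposure accumulation* (EA) term.
Under EA, var(E) grows linearly with age while var(G) is constant, so
heritability declines as h²_a = h² / (1 + a·sigma2_EA), and the correlation
of liability across an age gap Δ behaves like exp(−βΔ).  The competing
*proportional amplification* model scales var(G) and var(E) by the same
factor, leaving h² flat; the two are separated by the per-bin variance
decomposition (EA moves points above the var(G)=var(E)-change diagonal,
amplification moves them along it).

Disease onset follows a liability-threshold process: at each age bin the top
`bin_fraction` of current liability among the not-yet-diseased becomes that
bin's incident cases.  Onset is percentile-based (ranking, ties broken by a
seeded permutation), which makes the construction invariant to proportional
amplification.  In the linear variant liability is fixed and the effective
threshold walks down the liability distribution; in the EA variant every
individual also receives a cumulative N(0, `increment_var`) perturbation when
moving to each older bin, so late bins re-rank individuals.

Default simulator parameters are the stated simulation world: n = 100,000,
h² = 0.3, five bins of 2% each, increment variance 0.05 per bin (hence 20%
extra environmental variance by bin 5, matching an observed ≈20% h² decline
over ≈20 years in biobank quantitative traits).

## Estimation

**Heritability.**  Haseman–Elston (HE) regression substitutes for
mixed-model REML at desk scale: phenotypes are residualized on covariates
(sex, within-bin age), standardized, and pairwise products y_i·y_j are
regressed with intercept on off-diagonal GRM entries; the slope estimates
h².  The GRM is (1/m)·ZZ' from per-SNP empirically standardized dosages,
monomorphic SNPs dropped.  Standard errors come from a delete-one-block
jackknife over 100 contiguous individual blocks (every pair touching the
deleted block is removed, via closed-form sufficient-statistic updates).
Estimates are never truncated to [0, 1]: truncation would bias the
downstream trend fits.  Per-bin estimates use baseline-age quintiles, which
are disjoint samples — the property the trend Monte-Carlo relies on.

**Genetic correlation between age bins.**  Cross-sample HE: products
y_a,i·y_b,j over all pairs from two disjoint bins are regressed on the
cross-GRM block; the slope estimates the genetic covariance, divided by
√(ĥ²_a ĥ²_b).  Disjoint samples mean no shared environment enters the
cross-products — the analogue of constraining a summary-statistic
cross-trait covariance intercept to zero.  The jackknife deletes aligned
blocks from both samples and holds the h² denominators at their point
estimates, so the s.e. reflects numerator noise; a fully nested jackknife of
the denominators would be quadratically more expensive and changes little
when the h²s are well determined.  Non-positive ĥ² raises an error rather
than silently clamping.

**Correlation scaling and pooling.**  Correlations over different age gaps
are made comparable by rho_10yr = exp(10·ln(rho)/gap) (exact under
exponential decay; the identity at rho = 1).  Non-positive raw correlations
cannot be log-scaled and are excluded with a warning.  The four
neighbouring-bin-pair estimates (1–2, 2–3, 3–4, 4–5) — the independent
degrees of freedom among the ten pairs — are pooled by inverse-variance
weighting, and the deficit below 1 is tested one-sided (z = (1 − rho)/se);
the two-sided p is also reported.

**Longitudinal denoising.**  With three visits per individual, measurement
error attenuates corr(v1, v3) and corr(v1, v2) by the same factor, so their
ratio is the liability correlation over the average t3 − t2 gap; it is then
rescaled to 10 years.  Bootstrap (B = 200, resampling individuals) gives the
s.e. and 95% CI.  The cancellation is exact only when liability variance is
constant over visits, so the generator offers a stationary exponential-decay
process (AR(1) with unit variance) alongside the Wiener
(linearly-growing-variance) process; the stationary process is the one used
for exact-recovery checks, the Wiener one matches the scaling assumption
used for cross-bin genetic correlations.  Pearson correlations throughout.
Individuals with heterogeneous visit spacing share the cohort-average
t3 − t2; per-individual gap scaling is not implemented.

## Prediction accuracy

**Designs.**  Incident case prediction at bin k: cases diagnosed within the
interval, controls followed (or, matching the stated convention, lost to
follow-up) through it without diagnosis, down-sampled 1:1.  Prevalent case
association at an age point (the median case age of the corresponding
incident interval): cases diagnosed before it, controls undiagnosed among
those followed past it, 1:1.  Each set records the eligible-population case
fraction K for the ascertainment correction; P = 0.5 after down-sampling.

**Metrics.**  Observed-scale R² is the squared Pearson correlation between
the covariate-residualized outcome and the score.  AUC is the Mann–Whitney
probability with Hanley–McNeil s.e. and deliberately no covariate
adjustment; logOR, linear effect, and logHR are the score coefficients of
logistic, linear, and Cox models with covariates included (complete
separation or non-convergence is reported as such, not raised).
Observed-scale R² maps to the liability scale with the standard
ascertainment-corrected transformation (threshold t = Φ⁻¹(1−K), mean case
liability z/K); the same map converts point-biserial trait–disease
correlations for the biomarker screen.

**Calibrated predictors.**  A predictor at target liability-scale R² = t is
liability + N(0, var(L)(1−t)/t), standardized.  The simulation tiers are
0.99 / 0.5 / 0.2 / 0.05 (near-perfect, strong, clinical-score-like,
PRS-like).  In synthetic mode the PRS-like score is calibrated against G,
standing in for a cross-validated mixed-model score; real score tables can
be supplied instead.

**Estimated liability and QRS.**  Disease liability is estimated from the
quantitative-trait panel with an L1-penalized *linear* model (the
liability-threshold view treats case status as thresholded liability), 10-fold
CV, penalty at the 2se rule (the largest penalty whose CV error is within
two CV standard errors of the minimum; 1se is the usual default, 2se
regularizes harder), out-of-fold predictions as the score, and no age
covariate so the score reflects liability at the measurement age.  The QRS
pipeline then (1) rank-normalizes (Blom offset c = 3/8, average ranks for
ties), (2) residualizes QRS on age + sex and the standardized PRS on sex
(+ PCs when present; standardize-then-residualize order), (3) computes both
whole-population liability-scale R²s, (4) adds Gaussian noise to the QRS to
match the PRS's liability-scale R² (closed-form attenuation; if the QRS is
already weaker a warning is issued and no noise added), (5) computes
per-incident-bin observed R² on the same case-control sets, and (6) repeats
the noise draw and control sampling 50 times, reporting means and s.d.s.

## Trends and attribution

Per-bin metric series are fitted by weighted least squares (weights 1/se²,
the ML solution with known noise); a likelihood-ratio statistic against the
flat model is referred to χ²(1).  Slope uncertainty is Monte-Carlo: each bin
value is redrawn from N(point, se²) — "variance equal to s.e." is read as
s.d. = s.e., the conventional meaning — and the refit slopes' s.d. is the
slope s.e. (1000 draws by default; the replicate count is a choice, no value
being stated).  Ten-year changes are reported relative to the
whole-population estimate.  Age coordinates are per-bin median baseline ages
for h² series and median onset ages for prediction-accuracy series.

The threshold-model share of the PRS decline is
τ = Σ_d max(ΔR²_QRS,d, ΔR²_PRS,d) / Σ_d ΔR²_PRS,d over diseases, with
signed relative 10-year changes (negative = decline); the elementwise max
clamps any disease whose predicted decline overshoots the observed one.
The combined EA + threshold expectation is 1 − (1 + ΔR²_QRS)(1 + Δh²),
positive for a decline (the reporting layer negates it when plotting against
signed changes); its s.e. treats the two inputs as independent, which they
approximately are (case-age quintiles + baseline measurements vs genetic
data).  Differences between trends use z = (x − y)/√(se_x² + se_y²).

## The synthetic world

The generator emulates: baseline ages uniform on [40, 79] (the distribution
within the range is unstated; uniform assumed), sex Bernoulli(0.5), unlinked
biallelic SNPs with MAF uniform on [0.05, 0.5] (independence is the
desk-scale idealization of LD-pruned panels), per-SNP effects
N(0, h²/m) on the standardized scale, up to three visits with iid
measurement noise, Bernoulli medication flags, and censoring ages uniform on
[60, 85] so interval censoring is active.  Traits may instead load directly
on a disease's liability (`loads_on`/`loading`), giving the biomarker
structure the estimated-liability and QRS stages need.  Medication
corrections add the published constants (sd-mode corrections use the whole-
population s.d.).  Age-matched resampling matches the two groups' age
histograms exactly by stratified inverse-probability sampling toward the
per-bin minimum-availability distribution.

What a green test does **not** establish: there is no LD, no population
structure (synthetic PCs, when used, are independent covariates), no
ascertainment into the cohort, no diagnostic miscoding, no competing
mortality, and no age-dependent genetic effects (ρ_G < 1 worlds are out of
scope).  Real-data idiosyncrasies — differential follow-up, medication
confounding beyond the additive corrections, visit-age heterogeneity — are
absent, so recovery tests certify the estimators under the generative model,
not robustness to model violation.

## Numerical choices and edge cases

- All generators and pipelines are bit-reproducible under a fixed seed;
  stage seeds are derived from one root generator and logged.
- Liability ranking ties are measure-zero but guarded by a seeded
  permutation; per-bin case counts use ⌊f·n⌋ with the remainder dropped.
- Constant phenotypes (before or after covariate adjustment), all-equal
  rank-normal inputs, empty case sets, disjoint age supports, and
  non-positive correlations for log-scaling all raise typed errors rather
  than returning silently degraded values.
- The denoising ratio requires |corr(v1, v2)| above a small floor (default
  0.05) and fails loudly otherwise; bootstrap resamples that trip the floor
  are dropped, and the estimate errors out if most do.
- Interchange tables are header-checked TSV; extra columns are preserved
  with a warning, missing ones are named in the error.

## Known limitations

- The HE cross-bin r_g s.e. understates denominator uncertainty when per-bin
  h² is poorly determined (see above).
- At the desk-scale default (6,000 individuals) the EA trait's expected h²
  decline (≈ −17% per 10 years) is comparable to per-bin HE standard errors,
  so single-cohort trend tests are honest but underpowered — exactly the
  regime the full-scale analysis escapes by using ~180K individuals.
- Only 1–3 visits are supported; >3-visit denoising and REML-based
  longitudinal variance components are out of scope.
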