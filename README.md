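# agearch

Why do polygenic risk scores (and most other disease predictors) work worse
in older patients?  `agearch` is a simulation and estimation toolkit for one
answer: an **exposure accumulation (EA)** model layered on the classical
liability-threshold model.  Disease liability is

    L = G + E + sum_a E_a,    E_a ~ N(0, sigma2_EA) per age bin,

so environmental variance accumulates with age while genetic variance stays
fixed, heritability h² declines as h²/(1 + a·sigma2_EA), and any predictor's
accuracy falls for late-onset cases — fastest for weak predictors and for
incident (newly diagnosed) rather than prevalent case designs.

The package is aimed at statistical geneticists and risk-prediction
methodologists who want to reproduce, probe, or extend these mechanisms at
desk scale.  It provides:

- a synthetic biobank-style cohort generator (unlinked SNP genotypes,
  baseline ages 40–79, longitudinal visits with measurement error,
  medication flags and corrections, liability-threshold disease onsets);
- linear and EA liability-threshold disease simulators with incident and
  prevalent case-control constructions;
- Haseman–Elston heritability and cross-age-bin genetic correlation with
  block-jackknife standard errors (a desk-scale stand-in for REML/LDSC that
  also accepts externally computed estimate tables);
- the denoised longitudinal phenotypic correlation
  corr(v1,v3)/corr(v1,v2), which cancels measurement-error attenuation, on a
  common 10-year scale exp(10·ln ρ/Δage);
- accuracy metrics per age bin (observed/liability-scale R², AUC, logOR,
  logHR), the ascertainment-corrected observed-to-liability R² transform,
  LASSO-estimated disease liability, and the noise-matched quantitative
  risk score (QRS) Monte-Carlo pipeline;
- weighted age-trend fits with likelihood-ratio tests, the
  genetic/environmental variance decomposition, and the attribution
  statistics τ = Σ max(ΔR²_QRS, ΔR²_PRS) / Σ ΔR²_PRS and
  1 − (1 + ΔR²_QRS)(1 + Δh²).

## Worked example

The central simulation experiment — accuracy across onset-age bins under
both models and both designs — in a few lines:

```python
import numpy as np
import agearch as a

lin = a.simulate_linear_threshold(100_000, h2=0.3, n_bins=5, bin_fraction=0.02, seed=11)
score = a.calibrate_predictor(lin.state.liability_at_bin[:, 0], 0.5, seed=12)  # R2liab = 50%

for design in ("prevalent", "incident"):
    r2 = []
    for k in range(1, 6):
        cc = a.sim_case_control_sets(lin, design, k, seed=k)
        r2.append(a.observed_r2(score.values[cc.ids()], cc.outcome()))
    print(design, np.round(r2, 3))
```

Running the fuller driver `python analysis/04_threshold_model_sims.py`
prints (among other lines):

```
linear/prevalent: R2obs [0.495 0.461 0.427 0.411 0.398]; R2liab [0.487 0.502 0.492 0.498 0.501]
linear/incident: R2obs [0.495 0.413 0.352 0.335 0.311]; R2liab [0.487 0.377 0.306 0.288 0.263]
EA/incident:     R2obs [0.499 0.374 0.303 0.267 0.22 ] (decline 55.8% vs linear 37.2%)
tier 0.05: R2obs [0.079 0.057 0.034 0.034 0.024] (relative decline 69.3%)
```

Reading: observed-scale R² falls with onset age in every design, but on the
liability scale the prevalent design is flat (~0.50 throughout — the
predictor still explains half the liability) while the incident design
declines — the signature that case ascertainment near the threshold, not a
loss of genetic signal, drives the drop.  Exposure accumulation (EA) steepens
the incident decline further, and a PRS-strength predictor (tier 5%) loses
accuracy fastest.

## Analysis drivers

`analysis/01…06` run the full narrative on a shared 6,000-individual
synthetic cohort: cohort construction, per-age-bin heritability with its
trend and variance decomposition, longitudinal denoising across a decay
grid, the threshold-model simulation experiments above, cohort-level
PRS/QRS incident prediction, and the final attribution table.  Each writes
small TSV tables under `results/` and prints what it found.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the simulators at their stated parameters (n = 100,000, h² = 0.3,
five 2% onset bins, increment variance 0.05, weakest predictor tier 5%) and
writes the recomputed headline quantities — the accumulated environmental
variance at the fifth bin (% of initial liability variance), the realized
whole-population var(G)/var(L), and the realized liability-scale R² (%) of
the weakest calibrated predictor — as JSON.

See `docs/methods.md` for the model, estimators, numerical choices, and the
limits of what the synthetic world can certify.
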