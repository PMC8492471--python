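# telocausal

A causal-inference workbench for leukocyte telomere length (LTL) studies at
biobank scale. Telomere attrition is a proposed determinant of ageing and
disease, but observational LTL–disease associations are confounded and
attenuated by measurement error. This package implements, as a tested and
reusable pipeline, the full analytical arc such a study needs:

1. **Synthetic cohorts** (`syncohort`) — biallelic dosages with block LD,
   an additive polygenic LTL, measurement error calibrated to a chosen
   regression-dilution ratio, traits/diseases with configurable causal
   effects, and competing-risk cause-specific mortality by LTL group.
2. **Association** (`assoc`) — covariate-adjusted single-variant scans
   (MAF ≥ 0.1%, INFO ≥ 0.3), exact joint conditional modelling with backward
   elimination at *P* < 8.31 × 10⁻⁹, Benjamini–Hochberg-derived thresholds,
   ΔR² variance explained, and relatedness exclusion at kinship *K* > 0.088.
3. **Instrument selection** (`instruments`) — greedy LD clumping
   (*r*² > 0.01 within 1 Mb) then a pleiotropy filter (≥ 3 annotated
   biological domains removes a variant).
4. **Mendelian randomization** (`mr`) — IVW with multiplicative random
   effects, MR-Egger, weighted median, and a contamination-mixture profile
   likelihood with multimodal confidence sets; Cochran's *Q* and *I*².
5. **Observational analysis** (`obsassoc`) — winsorization at the 0.5/99.5
   percentiles, log transforms for skewed traits, regression-dilution
   correction to "usual LTL", quadratic/fractional-polynomial nonlinearity
   checks, and stratified Cox models with a proportional-hazards
   time-interaction test.
6. **Burden testing** (`burden`) — per-gene rare-variant scores
   (MAF < 0.1%, capped at one) regressed on LTL with a Bonferroni flag.
7. **Life expectancy** (`lifeexp`) — cause-specific hazard ratios by LTL
   group applied to population mortality rates, annual life tables from age
   40 to 95, years of life lost, and a Shapley-style cause partition.
8. **Workbench** (`workbench` + `telocausal` CLI) — plain-text formats,
   flat key=value configs, and a deterministic, checksummed
   simulate → scan → cojo → clump → mr → observe → yll → burden pipeline.

## The core estimators

With per-instrument exposure associations (β̂ₓⱼ, σₓⱼ) and outcome
associations (β̂ᵧⱼ, σᵧⱼ), the IVW estimate is the origin-constrained WLS

  θ̂ = Σⱼ wⱼ β̂ₓⱼ β̂ᵧⱼ / Σⱼ wⱼ β̂ₓⱼ², wⱼ = 1/σᵧⱼ²,

with SE inflated by √max(1, Q/(J−1)) (multiplicative random effects), where
Q = Σⱼ (β̂ᵧⱼ − θ̂ β̂ₓⱼ)²/σᵧⱼ² and I² = max(0, (Q−(J−1))/Q)·100. MR-Egger adds
an intercept (average directional pleiotropy) after orienting β̂ₓⱼ ≥ 0; the
weighted median interpolates Wald ratios β̂ᵧⱼ/β̂ₓⱼ at the 50% point of their
centred inverse-variance weights; the contamination mixture classes each
ratio as valid N(θ, seⱼ²) or invalid N(0, seⱼ²+ψ²) at every grid θ and
profiles the likelihood. Observational estimates per s.d. measured LTL are
divided by the regression-dilution ratio λ (slope of a standardized repeat
measurement on the first, ≈ 0.68 in the motivating data) to give effects per
s.d. *usual* LTL. Life expectancy differences come from discrete annual
life tables with all-cause hazard Σ_c rate(sex, band, c) · HR(group, c) and
annual survival exp(−h).

## Worked example

Simulate a 20,000-participant cohort whose 12 causal variants explain 8% of
LTL variance, run the discovery-to-MR arc for a trait with a true causal
effect of 0.1 s.d. per s.d. LTL, and compare with the dilution-corrected
observational estimate:

```python
import telocausal as tc

cfg = tc.SimulationConfig(
    n_participants=20_000, n_variants=120, ld_block_size=4, ld_rho=0.4,
    n_causal_variants=12, var_explained=0.08, dilution_ratio_target=0.68,
    n_repeat=5_000, traits={"bmi": tc.syncohort.TraitSpec(theta=0.1)}, seed=42)
cohort, genotypes = tc.simulate_cohort(cfg)
# ... scan, joint model, clump, per-instrument outcome regressions, MR ...
```

(the complete script is the `mr` stage of `telocausal pipeline`). Output:

```
sentinels: 12 (of 12 stage-one candidates)
instruments after clumping at r2<0.01: 11
                   ivw: theta=+0.096  95% CI (-0.008, +0.199)
                 egger: theta=+0.206  95% CI (-0.310, +0.723)
       weighted_median: theta=+0.067  95% CI (-0.031, +0.164)
 contamination_mixture: theta=+0.319  95% CI (-0.025, +0.518)
dilution ratio from 5000 repeat pairs: 0.672
observational beta per s.d. measured LTL: +0.060; per s.d. usual LTL: +0.089
```

IVW lands on the generating effect (0.1) with a CI reflecting 11
instruments at n = 20,000; Egger and the contamination mixture are wide, as
expected at this instrument count; the repeat-measurement slope recovers the
0.68 calibration and the corrected observational estimate moves from 0.060
toward the causal 0.1 (residual gap = sampling noise, no confounding was
simulated here).

The same arc runs from the shell:

```sh
telocausal pipeline --seed 7 --out runs/demo
telocausal yll --rates runs/demo/population_rates.csv \
               --hazards runs/demo/group_hazards.csv --out runs/demo/yll.csv
```

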