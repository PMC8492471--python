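# Methods

This note documents the models behind `telocausal`, the defaults and why,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic cohort model

**Genotypes.** Each variant is biallelic with MAF drawn uniformly from
`maf_range` (default 0.05–0.5, floor 0.001). Alleles are thresholded
Gaussian latents (a Gaussian copula): within an LD block of
`ld_block_size` variants the latents follow an AR(1) with parameter
`ld_rho` (corr(i,j) = ρ^|i−j|), blocks are independent, and a
participant's two haplotypes are independent, giving Hardy–Weinberg
dosages in {0,1,2}. On chromosome X males carry one haplotype coded 0/2
and are analysed jointly with females plus a sex covariate. The realized
dosage correlation is the phi coefficient implied by the copula — smaller
than ρ, and attenuating further as the two MAFs diverge; the LD tests
compare against a Monte-Carlo evaluation of the same copula rather than ρ
itself.

**Polygenic LTL.** `ltl_true` is the standardized sum of per-allele
effects, an optional confounder contribution and Gaussian polygenic noise.
Effects are drawn Normal and rescaled so that Σⱼ 2mⱼ(1−mⱼ)βⱼ² equals
`var_explained` (default 0.05, matching the 4–6% a well-powered LTL GWAS
instrument set explains). When `n_causal_variants` is set, effects
concentrate in that many variants with *equal per-variant variance*
(random sign, magnitude ∝ 1/√heterozygosity). This is the scaled-down
architecture the demo pipeline uses (12 causal variants, 8% total) so
each sentinel is individually detectable at n = 2×10⁴ under genome-wide
stringency; with effects proportional to 1/√n-scaling, it is the desk-size
analogue of a few hundred loci at half a million samples. Note the scan
runs on *measured* LTL, so detectable variance is attenuated by λ²
(≈ 0.46 at λ = 0.68) relative to the generative ΔR².

**Measurement error.** With target regression-dilution ratio λ
(`dilution_ratio_target`, default 0.68), each measurement is

  m = λ·t + √(1−λ²) · (√s·u + √(1−s)·v),  s = λ/(1+λ),

where t is true LTL (unit variance), u is a technical component *shared*
between a participant's repeat measurements and v is independent noise.
This calibration gives simultaneously corr(m, t) = λ, Var(m) = 1, and
corr(m₁, m₂) = λ² + (1−λ²)s = λ. Consequently (i) the slope of a
standardized repeat on the first — the estimator of the dilution ratio —
converges to λ; (ii) outcome regressions on standardized measured LTL are
attenuated by exactly λ; and (iii) dividing by the repeat-estimated ratio
is a *consistent* correction to effects per s.d. true ("usual") LTL.
Purely classical error cannot deliver (i) and (ii) at the same value
(it forces repeat-slope = attenuation²), so a shared technical component —
plausible for a qPCR assay run per sample batch — is a structural
requirement of the usual-LTL correction, not a convenience. The shared
fraction s is fully determined by λ; there is no extra knob.

**Outcomes.** Continuous traits: θ·t + γ·U + noise with total variance ≈ 1.
Binary traits and prevalent disease: logistic on the same linear
predictor. Incident disease and death: exponential times from
cause-specific hazards (latent-failure-time competing risks; the observed
death is the earliest cause), administratively censored at
`followup_years` (default 12, a biobank-typical follow-up). Death hazards
are `cause_hazards` (defaults 0.002/0.004/0.003 per year for
vascular/cancer/other, mid-life all-cause ≈ 0.9%/yr) multiplied by the
LTL-group hazard ratios `cause_group_hr` (defaults: short-telomere groups
at 1.1–1.4× the longest-telomere group, vascular steepest — the
qualitative pattern the projection machinery is meant to exercise). A
fraction `invalid_fraction` of instruments adds a direct
`pleiotropy_alpha` effect to outcomes flagged pleiotropic, violating the
exclusion restriction for exactly those instruments. The single shared
confounder U (standard normal) affects LTL via `confounder_to_ltl` and
outcomes via per-outcome `confounding`, creating observational–MR
divergence when switched on; it is off by default.

**What is not emulated.** Realistic human LD maps (blocks are
exchangeable AR(1), no recombination-rate structure); ascertainment and
selection; genotyping-batch artifacts; age-varying baseline hazards
within the follow-up window; informative censoring. Passing tests
demonstrate the *estimators'* statistical behaviour under the stated
generative model, not robustness to these real-data complications.

## Association and selection

The scan uses covariate-adjusted least squares via Frisch–Waugh
partialling (identical to joint OLS coefficients, t-distributed Wald P),
after filtering MAF ≥ 0.1% and INFO ≥ 0.3; logistic regression per variant
for binary outcomes, with separation flagged and P set missing. The joint
conditional model fits all stage-one candidates (marginal P < 10⁻⁶)
jointly and backward-eliminates the weakest conditional P until all
survivors pass the genome-wide threshold 8.31 × 10⁻⁹ (both thresholds
configurable; strict inequalities throughout). Elimination ties break by
larger SE, then later position; exact collinearity drops the later
variant (position, then id) before fitting — the elimination order on
near-collinear sets is a declared choice, logged at run time.

Relatedness exclusion removes the complement of a maximum independent set
of the K > 0.088 graph — exact branch-and-bound per connected component up
to 30 nodes (kinship components are small in practice), greedy
highest-degree removal above that, with seeded shuffling choosing among
equally valid optima. This keeps the most participants possible while
leaving no related pair, and reduces to "drop one of each pair" for
isolated pairs.

Clumping is greedy by ascending P (ties: smaller SE, then position) with
r² > 0.01 discarding within a 1 Mb window and cross-window r² treated as
zero; the pleiotropy filter then removes variants with ≥ 3 annotated
domains. The pipeline fixes the order clump-then-filter; the orders are
not interchangeable and a test pins this. Domain counts are a supplied
table — the curated phenome-scan resource behind them is out of scope —
and artifact loci are excluded via a user blacklist rather than inferred.

## MR estimators

Defaults chosen where the methods' sources leave them open: Egger
re-orients instruments to β̂ₓ ≥ 0 (standard practice; estimates are
equivariant to allele flips, which a property test asserts);
the weighted-median SE uses a seeded parametric bootstrap (default 1000
draws; the seed is a required argument, making results reproducible by
contract); the contamination mixture defaults ψ to the empirical s.d. of
the ratio estimates and uses a 1001-point grid spanning the ratio range
extended by twice its width, CI = {θ : 2(ℓmax−ℓ(θ)) < 3.84} reported as a
union of intervals with all interior modes. Single-sample overlap bias
(both association sets from one cohort, as in the pipeline demo) is not
corrected — a documented limitation of applying two-sample machinery
within one sample.

## Observational analysis

Trait preparation winsorizes at the 0.5/99.5 percentiles, applies a
natural log when |skewness| of the winsorized values exceeds 1 (a concrete
criterion standing in for "where appropriate"; configurable) and all
values are positive, then Z-standardizes. Dilution correction divides
estimates (and SEs) by λ on the beta / log-OR / log-HR scale. Partial R²
is the full-minus-reduced model R² (McFadden's pseudo-R² for logistic).
Nonlinearity: a quadratic Wald P, then fractional polynomials over powers
{−2,−1,−0.5,0,0.5,1,2,3} (power 0 = log; repeated powers add a log
factor), FP1 vs linear and FP2 vs FP1 each by 2-df deviance tests at
P < 0.05, with the exposure shifted positive for the fractional basis.
Cox models exclude prevalent cases, stratify by sex and ethnic group,
adjust for age and WBC, and check proportional hazards with an
LTL × time interaction fit on episode-split data (2-year grid by default;
`lifelines` time-varying fitter); when violated, HRs at baseline and 10
years come from the linear combination b + t·b_int. Decile curves use
equal-count bins by convention.

## Life-table projection

Annual ages 40–95; at age a the all-cause hazard for a group is
Σ_c rate(sex, band(a), c)·HR(group, sex, band(a), c) with 5-year bands and
q = 1 − exp(−h) (exact under piecewise-constant hazards). Expected years
lived integrate the survival curve by trapezoid (deaths mid-year); years
beyond 95 are ignored. YLL is relative to group 4 (longest telomeres).
The cause partition substitutes each cause's HRs to the reference value in
every one of the 3! orderings and averages the attributed gains — a
Shapley decomposition, order-invariant by construction, summing to the
total YLL exactly; the underlying source reports only resulting
percentages, so averaged substitution is this package's declared
decomposition. Group HRs are estimated per cause by sex-stratified Cox
fits on the *age* time-scale with left truncation at baseline age
(age-at-risk specificity via the risk sets), censoring other causes; the
estimate is constant across bands, though the hazard table supports
band-varying values. `synthetic_population_rates()` is a synthetic
stand-in shaped like a national rate table (Gompertz-like, ~9%/yr
increase, male excess, age-varying cause shares); real rate CSVs drop in
via the same schema.

## Burden testing

Variant scores default to 1 for high-confidence LoF and ultra-rare
missense and 0 otherwise (the source's per-category weights live in
supplementary material; scores are configuration). Allele count
multiplies the score before the cap at one, so the default is carrier
status per gene. Association is per-gene least squares adjusted for age
and sex, Bonferroni at 0.05/genes-tested.

## Problem sizes and experiment design

Simulation sizes are chosen so each check estimates its quantity with
Monte-Carlo error several-fold below its tolerance: 500 replicates for
IVW calibration (bias tolerance 0.005 ≈ 30× the MC s.e. of the mean);
n = 10⁴ repeat pairs for the dilution ratio (±0.02 ≈ 3 s.d.);
n = 10⁵ and β = 0.3 for the single-variant ΔR² closed form (10% ≈ 3 s.d.;
at β = 0.1 the same band is ~1 s.d. and the check would be noise).
The pleiotropy-robustness experiment runs in the *strong-instrument
regime* (outcome SE 5 × 10⁻⁴): the weighted median carries an intrinsic
contamination bias ≈ z₅⸝₆ × (typical ratio SE) when 40% of instruments are
one-sidedly invalid, so instrument precision is set high enough that the
experiment measures contamination behaviour (median robust, IVW pulled by
f·α·E[wβ̂ₓ]/E[wβ̂ₓ²], Egger intercept → f·α, contamination-mixture mode on
θ) rather than GWAS sampling noise. The end-to-end demo uses n = 2×10⁴
and 120 variants; at that n genome-wide stringency admits ~12 equally
sized causal loci, not the hundreds a full biobank yields — headline
real-data quantities (locus counts, ΔR², life-expectancy gaps) are
functions of the configured generator, not reproductions.

## Known limitations

Single-sample MR without overlap correction; exchangeable-block LD only;
the joint conditional model assumes individual-level data are available
(no summary-statistic approximation of the two-stage procedure it
replaces); fractional-polynomial search refits each candidate fully
(no caching) and can be slow for Cox outcomes at large n; the
contamination-mixture CI is grid-resolution-limited; group hazard
estimation returns band-constant HRs.
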