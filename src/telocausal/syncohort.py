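"""Synthetic cohort generator.

Emulates the statistical structure of a biobank-scale leukocyte telomere
length (LTL) study: biallelic imputed variants with block linkage
disequilibrium, an additive polygenic LTL signal, noisy LTL measurement
calibrated to a chosen regression-dilution ratio, continuous/binary traits
and time-to-event diseases with configurable causal effects of true LTL,
optional instrument pleiotropy, and competing-risk cause-specific mortality
(vascular / cancer / other) with LTL-group-dependent hazards.

Everything is driven by a single integer seed; identical seeds yield
bit-identical cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger("telocausal.syncohort")

CAUSES = ("vascular", "cancer", "other")

#: Z-score cut points for the four LTL groups; group 4 (longest) is the
#: downstream reference group.
LTL_GROUP_CUTS = (-1.0, 0.0, 1.0)


def assign_ltl_groups(z: np.ndarray) -> np.ndarray:
    """Map standardized LTL to groups 1..4.

    Group 1: more than 1 s.d. below the mean; group 2: within 1 s.d. below;
    group 3: within 1 s.d. above (inclusive of the mean); group 4: at least
    1 s.d. above the mean.
    """
    z = np.asarray(z, dtype=float)
    return (1 + np.searchsorted(np.array(LTL_GROUP_CUTS), z, side="right")).astype(int)


@dataclass
class TraitSpec:
    """Generative recipe for one biomedical trait.

    theta is the causal effect of true LTL: s.d. of the trait per s.d. true
    LTL for continuous traits, log-odds per s.d. for binary ones.
    """

    theta: float = 0.0
    kind: str = "continuous"  # or "binary"
    confounding: float = 0.0  # effect of the shared confounder U
    base_rate: float = 0.1  # binary only: marginal-ish prevalence at U=LTL=0
    pleiotropic: bool = False  # receives direct effects from invalid instruments


@dataclass
class DiseaseSpec:
    """Generative recipe for one time-to-event disease.

    log_hr is the cause-log-hazard-ratio per s.d. true LTL; base_hazard an
    annual incidence rate; prevalence the baseline-prevalent probability at
    the linear-predictor origin (0 disables prevalent cases).
    """

    log_hr: float = 0.0
    base_hazard: float = 0.01
    prevalence: float = 0.0
    confounding: float = 0.0
    pleiotropic: bool = False


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with biobank-like defaults."""

    n_participants: int = 10_000
    n_variants: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    n_chrx_variants: int = 0
    # None => effects drawn (normal, scaled) so instruments explain var_explained
    instrument_effects: np.ndarray | None = None
    var_explained: float = 0.05
    # None => every variant carries an effect; else effects concentrate in a
    # random subset of this many variants (detectable sentinels at modest n)
    n_causal_variants: int | None = None
    dilution_ratio_target: float = 0.68
    n_repeat: int | None = None  # participants with a repeat LTL measure
    repeat_fraction: float = 0.05
    confounder_to_ltl: float = 0.0
    traits: dict[str, TraitSpec] = field(default_factory=dict)
    diseases: dict[str, DiseaseSpec] = field(default_factory=dict)
    invalid_fraction: float = 0.0
    pleiotropy_alpha: float = 0.0
    cause_hazards: dict[str, float] = field(
        default_factory=lambda: {"vascular": 0.002, "cancer": 0.004, "other": 0.003}
    )
    # HRs per cause for LTL groups (1, 2, 3, 4); group 4 is the reference.
    cause_group_hr: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "vascular": (1.4, 1.2, 1.1, 1.0),
            "cancer": (1.15, 1.1, 1.05, 1.0),
            "other": (1.25, 1.15, 1.05, 1.0),
        }
    )
    age_range: tuple[float, float] = (40.0, 70.0)
    followup_years: float = 12.0
    n_ethnic_groups: int = 4
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 < self.dilution_ratio_target <= 1.0):
            raise ConfigurationError(
                f"dilution_ratio_target must lie in (0, 1], got {self.dilution_ratio_target}"
            )
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ConfigurationError("invalid_fraction must lie in [0, 1]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        for name in ("n_participants", "n_variants", "ld_block_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.n_chrx_variants < 0 or self.n_chrx_variants > self.n_variants:
            raise ConfigurationError("n_chrx_variants must lie in [0, n_variants]")
        if self.instrument_effects is not None and len(self.instrument_effects) != self.n_variants:
            raise ConfigurationError("instrument_effects length must equal n_variants")
        for cause in self.cause_hazards:
            if cause not in CAUSES:
                raise ConfigurationError(f"unknown cause {cause!r}; expected one of {CAUSES}")
            if self.cause_hazards[cause] < 0:
                raise ConfigurationError("cause hazards must be non-negative")
        for cause, hrs in self.cause_group_hr.items():
            if len(hrs) != 4 or any(h <= 0 for h in hrs):
                raise ConfigurationError(f"cause_group_hr[{cause!r}] needs 4 positive HRs")


@dataclass
class DosageMatrix:
    """Participants x variants additive dosages plus per-variant metadata.

    ``variants`` columns: variant_id, chrom, pos (1-based), effect_allele,
    other_allele, eaf, info.  On chromosome X male dosages are coded {0, 2}.
    ``sex`` is carried so downstream stages reuse the same assignment.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sex: np.ndarray  # "male" / "female" per participant

    @property
    def n_participants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return self.dosages[:, idx[0]]


def _draw_block_latents(rng: np.random.Generator, n: int, size: int, rho: float) -> np.ndarray:
    """AR(1) Gaussian latents within one LD block: corr(i, j) = rho^|i-j|."""
    z = np.empty((n, size))
    z[:, 0] = rng.standard_normal(n)
    if size > 1:
        innov = rng.standard_normal((n, size - 1))
        c = np.sqrt(1.0 - rho * rho)
        for k in range(1, size):
            z[:, k] = rho * z[:, k - 1] + c * innov[:, k - 1]
    return z


def simulate_genotypes(cfg: SimulationConfig) -> DosageMatrix:
    """Draw a Hardy-Weinberg dosage matrix with block LD.

    Alleles are thresholded Gaussian latents (Gaussian copula); within a
    block adjacent variants share latent correlation ``ld_rho`` (AR(1)),
    blocks are independent, and the two haplotypes of a participant are
    independent. Autosomal variants sit on chromosome 1 spaced 10 kb apart;
    the last ``n_chrx_variants`` variants sit on X, where males carry a
    single haplotype coded 0/2.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 101]))
    n, m = cfg.n_participants, cfg.n_variants
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    mafs = np.maximum(mafs, 0.001)
    thresholds = norm.ppf(mafs)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    is_male = sex == "male"

    n_auto = m - cfg.n_chrx_variants
    chrom = np.array(["1"] * n_auto + ["X"] * cfg.n_chrx_variants)
    pos = np.concatenate(
        [1 + 10_000 * np.arange(n_auto), 1 + 10_000 * np.arange(cfg.n_chrx_variants)]
    ).astype(int)

    dosages = np.zeros((n, m))
    for start in range(0, m, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, m)
        size = stop - start
        hap1 = _draw_block_latents(rng, n, size, cfg.ld_rho) < thresholds[start:stop]
        hap2 = _draw_block_latents(rng, n, size, cfg.ld_rho) < thresholds[start:stop]
        block = hap1.astype(float) + hap2.astype(float)
        x_cols = np.nonzero(chrom[start:stop] == "X")[0]
        if len(x_cols):
            # males are hemizygous: one haplotype, coded 0/2
            block[np.ix_(is_male, x_cols)] = 2.0 * hap1[np.ix_(is_male, x_cols)]
        dosages[:, start:stop] = block

    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": dosages.mean(axis=0) / 2.0,
            "info": 1.0,
        }
    )
    return DosageMatrix(dosages=dosages, variants=variants, sex=sex)


def _draw_effects(cfg: SimulationConfig, mafs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-allele effects scaled so instruments explain ``var_explained``."""
    raw = rng.standard_normal(cfg.n_variants)
    het = 2.0 * mafs * (1.0 - mafs)
    if cfg.n_causal_variants is not None and cfg.n_causal_variants < cfg.n_variants:
        # concentrated architecture: random-sign effects scaled so every
        # causal variant contributes equal variance (equally detectable)
        mask = np.zeros(cfg.n_variants, dtype=bool)
        mask[rng.choice(cfg.n_variants, size=cfg.n_causal_variants, replace=False)] = True
        sign = np.sign(raw) + (raw == 0)
        raw = np.where(mask, sign / np.sqrt(np.maximum(het, 1e-6)), 0.0)
    current = float(np.sum(het * raw**2))
    if current <= 0:
        return np.zeros(cfg.n_variants)
    return raw * np.sqrt(cfg.var_explained / current)


def simulate_ltl(genotypes: DosageMatrix, cfg: SimulationConfig) -> pd.DataFrame:
    """Build the cohort table with true, measured and repeat LTL.

    ltl_true is the standardized sum of per-allele effects, a configurable
    confounder contribution, and polygenic noise. Measurement error uses a
    shared technical component calibrated so that, with target ratio λ,
    corr(measured, true) = λ and the slope of a standardized repeat measure
    on the first equals λ — making downstream division of effect estimates
    by the repeat-estimated regression-dilution ratio exactly consistent.
    """
    cfg.validate()
    if cfg.instrument_effects is not None and len(cfg.instrument_effects) != genotypes.n_variants:
        raise ConfigurationError("instrument_effects length must equal n_variants")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 202]))
    n = genotypes.n_participants
    mafs = np.minimum(genotypes.variants["eaf"].to_numpy(), 1 - genotypes.variants["eaf"].to_numpy())
    beta = (
        np.asarray(cfg.instrument_effects, dtype=float)
        if cfg.instrument_effects is not None
        else _draw_effects(cfg, mafs, rng)
    )
    genetic = genotypes.dosages @ beta
    confounder = rng.standard_normal(n)
    g_var = max(float(np.var(genetic)), 0.0)
    resid_var = max(1.0 - g_var - cfg.confounder_to_ltl**2, 0.05)
    ltl_raw = genetic + cfg.confounder_to_ltl * confounder + rng.standard_normal(n) * np.sqrt(resid_var)
    ltl_true = (ltl_raw - ltl_raw.mean()) / ltl_raw.std()

    lam = cfg.dilution_ratio_target
    shared_frac = lam / (1.0 + lam)  # shared technical error fraction of the error variance
    err_sd = np.sqrt(max(1.0 - lam * lam, 0.0))
    shared = rng.standard_normal(n)

    def measure() -> np.ndarray:
        e = np.sqrt(shared_frac) * shared + np.sqrt(1.0 - shared_frac) * rng.standard_normal(n)
        raw = lam * ltl_true + err_sd * e
        return (raw - raw.mean()) / max(raw.std(), 1e-12)

    ltl_measured = measure()
    n_repeat = cfg.n_repeat if cfg.n_repeat is not None else int(round(cfg.repeat_fraction * n))
    n_repeat = min(n_repeat, n)
    repeat_full = measure()
    ltl_repeat = np.full(n, np.nan)
    if n_repeat > 0:
        idx = rng.choice(n, size=n_repeat, replace=False)
        ltl_repeat[idx] = repeat_full[idx]

    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:07d}" for i in range(n)],
            "age": np.round(ages, 1),
            "sex": genotypes.sex,
            "array": rng.integers(0, 2, size=n),
            "ethnic_group": rng.integers(0, cfg.n_ethnic_groups, size=n).astype(str),
            "wbc": np.exp(rng.normal(np.log(6.8), 0.25, size=n)),
            "confounder": confounder,
            "ltl_true": ltl_true,
            "ltl_measured": ltl_measured,
            "ltl_repeat": ltl_repeat,
        }
    )
    for k in range(1, 11):
        cohort[f"pc{k}"] = rng.standard_normal(n)
    cohort.attrs["instrument_effects"] = beta
    return cohort


def simulate_outcomes(
    cohort: pd.DataFrame, cfg: SimulationConfig, genotypes: DosageMatrix | None = None
) -> pd.DataFrame:
    """Append traits, disease histories and cause-specific deaths.

    Continuous traits: theta·ltl_true + confounding·U + noise (unit total
    variance when feasible). Binary traits/prevalent disease: logistic on the
    same linear predictor. Disease incidence and death: exponential times
    from cause-specific hazards; an LTL group multiplies each death cause's
    baseline rate by its hazard ratio; the observed death is the earliest
    latent cause (competing risks), administratively censored at
    ``followup_years``. A seeded fraction ``invalid_fraction`` of instruments
    contributes a direct ``pleiotropy_alpha`` effect to outcomes marked
    pleiotropic.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 303]))
    n = len(cohort)
    out = cohort.copy()
    ltl = out["ltl_true"].to_numpy()
    conf = out["confounder"].to_numpy() if "confounder" in out else np.zeros(n)

    pleio = np.zeros(n)
    invalid_ids: list[str] = []
    if cfg.invalid_fraction > 0 and cfg.pleiotropy_alpha != 0 and genotypes is not None:
        m = genotypes.n_variants
        n_invalid = int(round(cfg.invalid_fraction * m))
        chosen = rng.choice(m, size=n_invalid, replace=False)
        centered = genotypes.dosages[:, chosen] - genotypes.dosages[:, chosen].mean(axis=0)
        pleio = cfg.pleiotropy_alpha * centered.sum(axis=1)
        invalid_ids = genotypes.variants["variant_id"].iloc[chosen].tolist()
    out.attrs["invalid_instruments"] = invalid_ids

    for name, spec in cfg.traits.items():
        lp = spec.theta * ltl + spec.confounding * conf + (pleio if spec.pleiotropic else 0.0)
        if spec.kind == "continuous":
            noise_var = max(1.0 - spec.theta**2 - spec.confounding**2, 0.1)
            out[name] = lp + rng.standard_normal(n) * np.sqrt(noise_var)
        elif spec.kind == "binary":
            p = expit(logit(spec.base_rate) + lp)
            if np.any((p <= 0) | (p >= 1)):
                raise DataError(f"trait {name!r}: probabilities leave (0,1) after link")
            out[name] = (rng.random(n) < p).astype(int)
        else:
            raise ConfigurationError(f"trait {name!r}: unknown kind {spec.kind!r}")

    # deaths first: disease follow-up is truncated at death
    groups = assign_ltl_groups(out["ltl_measured"].to_numpy())
    out["ltl_group"] = groups
    death_time = np.full(n, np.inf)
    death_cause = np.array([""] * n, dtype=object)
    for cause in CAUSES:
        base = cfg.cause_hazards.get(cause, 0.0)
        if base <= 0:
            continue
        hrs = np.asarray(cfg.cause_group_hr[cause])[groups - 1]
        t = rng.exponential(1.0, size=n) / (base * hrs)
        take = t < death_time
        death_time[take] = t[take]
        death_cause[take] = cause
    observed = death_time < cfg.followup_years
    out["death_observed"] = observed.astype(int)
    out["death_time"] = np.where(observed, death_time, cfg.followup_years)
    out["death_cause"] = np.where(observed, death_cause, "")

    end_of_followup = out["death_time"].to_numpy()
    for name, spec in cfg.diseases.items():
        lp = spec.log_hr * ltl + spec.confounding * conf + (pleio if spec.pleiotropic else 0.0)
        prevalent = np.zeros(n, dtype=int)
        if spec.prevalence > 0:
            p = expit(logit(spec.prevalence) + lp)
            prevalent = (rng.random(n) < p).astype(int)
        t = rng.exponential(1.0, size=n) / (spec.base_hazard * np.exp(lp))
        incident = (t < end_of_followup) & (prevalent == 0)
        out[f"{name}_prevalent"] = prevalent
        out[f"{name}_incident"] = incident.astype(int)
        out[f"{name}_time"] = np.where(incident, t, end_of_followup)
    return out


def simulate_cohort(cfg: SimulationConfig) -> tuple[pd.DataFrame, DosageMatrix]:
    """Convenience wrapper: genotypes -> LTL -> outcomes."""
    genotypes = simulate_genotypes(cfg)
    cohort = simulate_ltl(genotypes, cfg)
    cohort = simulate_outcomes(cohort, cfg, genotypes)
    return cohort, genotypes


def simulate_rare_burden(
    cohort: pd.DataFrame,
    n_genes: int = 20,
    n_causal_genes: int = 4,
    variants_per_gene: int = 5,
    carrier_freq: float = 0.0005,
    carrier_effect: float = -0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Rare-variant carriage for gene burden testing.

    Each gene carries ``variants_per_gene`` ultra-rare variants (per-variant
    carrier frequency ``carrier_freq`` < 0.1%, heterozygous). The first
    ``n_causal_genes`` genes shift carriers' LTL by ``carrier_effect`` s.d.
    Returns (carriers allele-count frame, variant score table, ltl column
    including the carrier shifts) — the shifted LTL is returned separately
    so the common-variant analyses stay untouched.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 707]))
    n = len(cohort)
    carriers = {}
    var_rows = []
    shift = np.zeros(n)
    for g in range(n_genes):
        gene = f"GENE{g + 1}"
        causal = g < n_causal_genes
        gene_carrier = np.zeros(n, dtype=bool)
        for v in range(variants_per_gene):
            vid = f"rare_{gene}_{v + 1}"
            alleles = (rng.random(n) < carrier_freq).astype(int)
            carriers[vid] = alleles
            gene_carrier |= alleles > 0
            category = "hc_lof" if v % 2 == 0 else "ultrarare_missense"
            var_rows.append((vid, gene, category, carrier_freq / 2.0))
        if causal:
            shift += carrier_effect * gene_carrier
    carriers_df = pd.DataFrame(carriers, index=cohort.index)
    variants_df = pd.DataFrame(var_rows, columns=["variant_id", "gene", "category", "maf"])
    ltl_with_burden = cohort["ltl_measured"].to_numpy() + shift
    return carriers_df, variants_df, ltl_with_burden


def simulate_kinship(
    cohort: pd.DataFrame, n_pairs: int, k_values: list[float] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Attach kinship coefficients to random disjoint-ish participant pairs.

    Returns a frame (id_a, id_b, k). No self-pairs, no duplicate pairs;
    deterministic under the seed. If ``k_values`` is shorter than
    ``n_pairs`` it is cycled.
    """
    if n_pairs == 0:
        return pd.DataFrame(columns=["id_a", "id_b", "k"])
    ids = cohort["participant_id"].to_numpy()
    if 2 * n_pairs > len(ids):
        raise ConfigurationError("not enough participants for the requested pairs")
    if k_values is None:
        k_values = [0.25]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
    chosen = rng.choice(len(ids), size=2 * n_pairs, replace=False)
    rows = []
    seen = set()
    for i in range(n_pairs):
        a, b = ids[chosen[2 * i]], ids[chosen[2 * i + 1]]
        key = (min(a, b), max(a, b))
        if a == b or key in seen:
            raise DataError(f"duplicate or self pair {key}")
        seen.add(key)
        k = float(k_values[i % len(k_values)])
        if not (0.0 <= k <= 0.5):
            raise ConfigurationError(f"kinship coefficient {k} outside [0, 0.5]")
        rows.append((key[0], key[1], k))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "k"])
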