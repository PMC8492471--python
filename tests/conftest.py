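import numpy as np
import pandas as pd
import pytest

from telocausal import syncohort


@pytest.fixture(scope="session")
def demo_cohort():
    """Mid-size cohort with one causal trait and one protective disease."""
    cfg = syncohort.SimulationConfig(
        n_participants=8000,
        n_variants=40,
        ld_block_size=4,
        ld_rho=0.5,
        n_causal_variants=12,
        var_explained=0.06,
        dilution_ratio_target=0.68,
        n_repeat=2000,
        traits={"trait_a": syncohort.TraitSpec(theta=0.1)},
        diseases={"disease_a": syncohort.DiseaseSpec(log_hr=-0.3, base_hazard=0.02,
                                                     prevalence=0.02)},
        seed=11,
    )
    cohort, genotypes = syncohort.simulate_cohort(cfg)
    return cfg, cohort, genotypes


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def binomial_dosages(rng, n, mafs):
    """Independent Hardy-Weinberg dosages with given MAFs as a DosageMatrix."""
    mafs = np.asarray(mafs, dtype=float)
    dos = rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)
    variants = pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(len(mafs))],
        "chrom": "1",
        "pos": 1 + 10_000 * np.arange(len(mafs)),
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": mafs,
        "info": 1.0,
    })
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    return syncohort.DosageMatrix(dosages=dos, variants=variants, sex=sex)
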