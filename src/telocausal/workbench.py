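"""File formats, configuration, and the end-to-end pipeline driver.

Readers/writers for the plain-text interchange formats (summary-statistics
TSV, instrument TSV, harmonized MR TSV, phenotype CSV, dosage TSV, optional
VCF with a DS dosage field, rate/hazard CSVs, flat key=value config), plus
``run_pipeline`` which chains simulate -> scan -> cojo -> clump -> mr ->
observe -> yll -> burden and writes a checksummed manifest. Coordinates are
1-based inclusive; probability thresholds use strict inequality.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, burden as burden_mod, instruments, lifeexp, mr, obsassoc, syncohort
from .exceptions import DataError, DependencyError, ParseError

logger = logging.getLogger("telocausal.workbench")

ALL_STAGES = ("simulate", "scan", "cojo", "clump", "mr", "observe", "yll", "burden")

SUMMARY_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "INFO", "BETA", "SE", "P"]
_INTERNAL = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
             "eaf", "info", "beta", "se", "p"]


# ---------------------------------------------------------------- formats

def write_summary_stats(table: pd.DataFrame, path) -> None:
    out = table[_INTERNAL].copy()
    out.columns = SUMMARY_COLUMNS
    out.to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header != SUMMARY_COLUMNS:
        raise ParseError(f"summary-stats header must be {SUMMARY_COLUMNS}, got {header}", line=1)
    tab = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    tab.columns = _INTERNAL
    return tab


def write_mr_input(data: mr.MRInput, path, ea="A", oa="G") -> None:
    ids = data.ids or [f"snp{i + 1}" for i in range(len(data))]
    pd.DataFrame({"SNP": ids, "EA": ea, "OA": oa, "BX": data.bx, "SX": data.sx,
                  "BY": data.by, "SY": data.sy}).to_csv(path, sep="\t", index=False)


def read_mr_input(path) -> mr.MRInput:
    tab = pd.read_csv(path, sep="\t")
    expected = ["SNP", "EA", "OA", "BX", "SX", "BY", "SY"]
    if list(tab.columns) != expected:
        raise ParseError(f"harmonized MR header must be {expected}", line=1)
    return mr.MRInput(bx=tab["BX"].to_numpy(), sx=tab["SX"].to_numpy(),
                      by=tab["BY"].to_numpy(), sy=tab["SY"].to_numpy(),
                      ids=tab["SNP"].tolist())


def write_rates(rates: pd.DataFrame, path) -> None:
    rates.to_csv(path, index=False)


def read_rates(path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    try:
        lifeexp.validate_rates(tab)
    except DataError as exc:
        raise ParseError(str(exc)) from exc
    return tab


def write_hazards(hazards: pd.DataFrame, path) -> None:
    hazards.to_csv(path, index=False)


def read_hazards(path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    required = ["group", "sex", "age_lo", "age_hi", "cause", "hr"]
    if list(tab.columns) != required:
        raise ParseError(f"hazards header must be {required}", line=1)
    return tab


def write_dosages(dosages: syncohort.DosageMatrix, dosage_path, variant_path) -> None:
    """Participant-major dosage TSV plus a variant metadata TSV."""
    dosages.variants.to_csv(variant_path, sep="\t", index=False)
    frame = pd.DataFrame(dosages.dosages, columns=dosages.variants["variant_id"])
    frame.insert(0, "sex", dosages.sex)
    frame.to_csv(dosage_path, sep="\t", index=False, float_format="%.6g")


def read_dosages(dosage_path, variant_path) -> syncohort.DosageMatrix:
    variants = pd.read_csv(variant_path, sep="\t", dtype={"chrom": str})
    frame = pd.read_csv(dosage_path, sep="\t")
    sex = frame.pop("sex").to_numpy()
    if list(frame.columns) != variants["variant_id"].tolist():
        raise ParseError("dosage columns do not match variant metadata", line=1)
    return syncohort.DosageMatrix(dosages=frame.to_numpy(dtype=float),
                                  variants=variants, sex=sex)


def write_vcf_dosages(dosages: syncohort.DosageMatrix, path) -> None:
    """Minimal VCF 4.2 with a DS (dosage) FORMAT field, one sample per
    participant."""
    samples = [f"S{i + 1}" for i in range(dosages.n_participants)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in dict.fromkeys(dosages.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, row in enumerate(dosages.variants.itertuples(index=False)):
            ds = "\t".join(f"{d:.4g}" for d in dosages.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.variant_id}\t"
                     f"{row.other_allele}\t{row.effect_allele}\t.\t.\t.\tDS\t{ds}\n")


def read_vcf_dosages(path) -> syncohort.DosageMatrix:
    """Ingest a VCF with DS dosage FORMAT (requires cyvcf2); the ALT allele
    is the effect allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, cols = [], []
    for v in vcf:
        ds = np.asarray(v.format("DS"), dtype=float).reshape(-1)
        cols.append(ds)
        rows.append((v.ID, str(v.CHROM), int(v.POS), v.ALT[0], v.REF))
    dos = np.column_stack(cols)
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos",
                                           "effect_allele", "other_allele"])
    variants["eaf"] = dos.mean(axis=0) / 2.0
    variants["info"] = 1.0
    sex = np.array(["female"] * dos.shape[0])
    return syncohort.DosageMatrix(dosages=dos, variants=variants, sex=sex)


def read_config(path) -> dict:
    """Flat ``key = value`` text config; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"expected 'key = value', got {line!r}", line=lineno)
            key, value = (s.strip() for s in line.split("=", 1))
            out[key] = value
    return out


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k} = {v}\n")


# ---------------------------------------------------------------- pipeline

@dataclass
class PipelineConfig:
    """Stage toggles, seeds and the parameters of the demo cohort."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    n_participants: int = 20_000
    n_variants: int = 120
    ld_block_size: int = 4
    ld_rho: float = 0.4
    n_causal_variants: int = 12
    var_explained: float = 0.08
    dilution_ratio: float = obsassoc.DILUTION_RATIO
    causal_theta: float = 0.1
    gw_threshold: float = assoc.GENOME_WIDE_P
    stage1_threshold: float = assoc.STAGE_ONE_P
    clump_r2: float = instruments.CLUMP_R2
    max_domains: int = instruments.MAX_PLEIOTROPY_DOMAINS
    k_threshold: float = assoc.KINSHIP_THRESHOLD
    params: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path, out_dir=None, seed=None) -> "PipelineConfig":
        raw = read_config(path)
        kwargs: dict = {}
        casts = {"seed": int, "n_participants": int, "n_variants": int,
                 "ld_block_size": int, "max_domains": int, "n_causal_variants": int,
                 "ld_rho": float, "var_explained": float, "dilution_ratio": float,
                 "causal_theta": float, "gw_threshold": float,
                 "stage1_threshold": float, "clump_r2": float, "k_threshold": float}
        for key, value in raw.items():
            if key == "stages":
                kwargs["stages"] = tuple(s.strip() for s in value.split(","))
            elif key == "out_dir":
                kwargs["out_dir"] = Path(value)
            elif key in casts:
                kwargs[key] = casts[key](value)
            else:
                kwargs.setdefault("params", {})[key] = value
        if out_dir is not None:
            kwargs["out_dir"] = Path(out_dir)
        if seed is not None:
            kwargs["seed"] = int(seed)
        if "out_dir" not in kwargs:
            raise ParseError("config must set out_dir (or pass --out)")
        return cls(**kwargs)


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic 31-bit per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise DependencyError(produced_by, f"output {path.name} needed by '{stage}' is missing; "
                                           f"run stage '{produced_by}' first")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write a manifest.

    The manifest records inputs, parameters, per-stage seeds and sha256
    checksums of every output file; identical configs and seeds produce
    byte-identical manifests. Any stage failure propagates as a typed error
    naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "telocausal",
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "n_participants": config.n_participants,
            "n_variants": config.n_variants,
            "ld_block_size": config.ld_block_size,
            "ld_rho": config.ld_rho,
            "n_causal_variants": config.n_causal_variants,
            "var_explained": config.var_explained,
            "dilution_ratio": config.dilution_ratio,
            "causal_theta": config.causal_theta,
            "gw_threshold": config.gw_threshold,
            "stage1_threshold": config.stage1_threshold,
            "clump_r2": config.clump_r2,
            "max_domains": config.max_domains,
            "k_threshold": config.k_threshold,
        },
        "stage_seeds": {},
        "outputs": {},
    }
    logger.info(
        "thresholds: genome-wide P < %g, stage-one P < %g, clump r^2 > %g, K > %g, "
        "pleiotropy domains >= %d, dilution ratio %g, winsorization %.1f/%.1f",
        config.gw_threshold, config.stage1_threshold, config.clump_r2, config.k_threshold,
        config.max_domains, config.dilution_ratio,
        obsassoc.WINSOR_LOWER_PCT, obsassoc.WINSOR_UPPER_PCT,
    )

    def record(stage: str, *paths: Path):
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)

    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise DataError(f"unknown stage {stage!r}")
        seed = _stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        logger.info("pipeline stage %s (seed %d)", stage, seed)

        if stage == "simulate":
            sim = syncohort.SimulationConfig(
                n_participants=config.n_participants,
                n_variants=config.n_variants,
                ld_block_size=config.ld_block_size,
                ld_rho=config.ld_rho,
                n_causal_variants=config.n_causal_variants,
                var_explained=config.var_explained,
                dilution_ratio_target=config.dilution_ratio,
                traits={"trait_a": syncohort.TraitSpec(theta=config.causal_theta)},
                diseases={"disease_a": syncohort.DiseaseSpec(
                    log_hr=-config.causal_theta, base_hazard=0.01)},
                seed=seed,
            )
            cohort, genotypes = syncohort.simulate_cohort(sim)
            carriers, rare_variants, ltl_burden = syncohort.simulate_rare_burden(
                cohort, seed=seed)
            cohort["ltl_burden"] = ltl_burden
            kin = syncohort.simulate_kinship(
                cohort, n_pairs=max(1, config.n_participants // 200),
                k_values=[0.25, 0.05, 0.125], seed=seed)
            cohort.to_csv(out / "cohort.csv", index=False, float_format="%.6g")
            write_dosages(genotypes, out / "dosages.tsv", out / "variants.tsv")
            carriers.to_csv(out / "rare_carriers.tsv", sep="\t", index=False)
            rare_variants.to_csv(out / "rare_variants.tsv", sep="\t", index=False)
            kin.to_csv(out / "kinship.csv", index=False)
            record(stage, out / "cohort.csv", out / "dosages.tsv", out / "variants.tsv",
                   out / "rare_carriers.tsv", out / "rare_variants.tsv", out / "kinship.csv")

        elif stage == "scan":
            _require(out / "cohort.csv", stage, "simulate")
            cohort = pd.read_csv(out / "cohort.csv")
            genotypes = read_dosages(out / "dosages.tsv", out / "variants.tsv")
            cov = _scan_covariates(cohort)
            scan = assoc.variant_scan(genotypes, cohort["ltl_measured"], cov)
            write_summary_stats(scan, out / "gwas.tsv")
            record(stage, out / "gwas.tsv")

        elif stage == "cojo":
            _require(out / "gwas.tsv", stage, "scan")
            cohort = pd.read_csv(out / "cohort.csv")
            genotypes = read_dosages(out / "dosages.tsv", out / "variants.tsv")
            scan = read_summary_stats(out / "gwas.tsv")
            candidates = scan.loc[scan["p"] < config.stage1_threshold, "variant_id"].tolist()
            joint = assoc.joint_conditional(
                genotypes, candidates, cohort["ltl_measured"],
                _scan_covariates(cohort), threshold=config.gw_threshold)
            sentinels = scan[scan["variant_id"].isin(joint.table["variant_id"])].copy()
            cond = joint.table.set_index("variant_id")
            sentinels["beta"] = sentinels["variant_id"].map(cond["beta"])
            sentinels["se"] = sentinels["variant_id"].map(cond["se"])
            sentinels["p"] = sentinels["variant_id"].map(cond["p"])
            write_summary_stats(sentinels, out / "sentinels.tsv")
            record(stage, out / "sentinels.tsv")

        elif stage == "clump":
            _require(out / "sentinels.tsv", stage, "cojo")
            genotypes = read_dosages(out / "dosages.tsv", out / "variants.tsv")
            sentinels = read_summary_stats(out / "sentinels.tsv")
            ld = instruments.compute_ld(genotypes)
            rng = np.random.default_rng(seed)
            domains = {v: int(rng.integers(0, 5)) for v in sentinels["variant_id"]}
            kept = instruments.select_instruments(
                sentinels, ld, domains, r2_threshold=config.clump_r2,
                max_domains=config.max_domains)
            inst = pd.DataFrame({
                "SNP": kept["variant_id"], "EA": kept["effect_allele"],
                "OA": kept["other_allele"], "BETA_EXP": kept["beta"],
                "SE_EXP": kept["se"], "DOMAINS": kept["pleiotropy_domains"],
                "KEPT": True,
            })
            inst.to_csv(out / "instruments.tsv", sep="\t", index=False)
            record(stage, out / "instruments.tsv")

        elif stage == "mr":
            _require(out / "instruments.tsv", stage, "clump")
            cohort = pd.read_csv(out / "cohort.csv")
            genotypes = read_dosages(out / "dosages.tsv", out / "variants.tsv")
            inst = pd.read_csv(out / "instruments.tsv", sep="\t")
            if inst.empty:
                raise DataError("mr stage: no instruments retained by clump; "
                                "lower thresholds or raise the simulated signal")
            keep_idx = genotypes.variants["variant_id"].isin(inst["SNP"]).to_numpy()
            sub = syncohort.DosageMatrix(
                dosages=genotypes.dosages[:, keep_idx],
                variants=genotypes.variants[keep_idx].reset_index(drop=True),
                sex=genotypes.sex)
            cov5 = _outcome_covariates(cohort)
            results = []
            harmonized = None
            for outcome in ("trait_a",):
                oscan = assoc.variant_scan(sub, cohort[outcome], cov5)
                merged = inst.merge(oscan[["variant_id", "beta", "se"]],
                                    left_on="SNP", right_on="variant_id")
                data = mr.MRInput(bx=merged["BETA_EXP"].to_numpy(),
                                  sx=merged["SE_EXP"].to_numpy(),
                                  by=merged["beta"].to_numpy(),
                                  sy=merged["se"].to_numpy(),
                                  ids=merged["SNP"].tolist())
                harmonized = data
                for est in mr.run_all(data, seed=seed):
                    results.append({
                        "OUTCOME": outcome, "METHOD": est.method, "THETA": est.theta,
                        "SE": est.se, "L95": est.ci95[0] if est.ci95 else np.nan,
                        "U95": est.ci95[1] if est.ci95 else np.nan,
                        "P": est.p, "Q": est.Q, "I2": est.i2,
                        "N_SNP": est.n_instruments,
                    })
            write_mr_input(harmonized, out / "harmonized.tsv")
            pd.DataFrame(results).to_csv(out / "mr_results.tsv", sep="\t",
                                         index=False, float_format="%.8g")
            record(stage, out / "harmonized.tsv", out / "mr_results.tsv")

        elif stage == "observe":
            _require(out / "cohort.csv", stage, "simulate")
            cohort = pd.read_csv(out / "cohort.csv")
            rep = cohort.dropna(subset=["ltl_repeat"])
            ratio = obsassoc.estimate_dilution_ratio(rep["ltl_measured"], rep["ltl_repeat"])
            kin = pd.read_csv(out / "kinship.csv")
            drop = assoc.unrelated_subset(kin, config.k_threshold, seed=seed)
            unrelated = cohort[~cohort["participant_id"].isin(drop)].copy()
            rows = []
            tr = obsassoc.associate(unrelated, "trait_a", "continuous",
                                    dilution_ratio=ratio)
            rows.append({"OUTCOME": "trait_a", "KIND": "continuous", "EST": tr.beta,
                         "EST_USUAL": tr.beta_usual, "SE": tr.se, "P": tr.p,
                         "PARTIAL_R2": tr.partial_r2, "N": tr.n})
            cx = obsassoc.cox_incident(unrelated, "disease_a", dilution_ratio=ratio)
            rows.append({"OUTCOME": "disease_a", "KIND": "cox",
                         "EST": cx.log_hr_measured,
                         "EST_USUAL": np.log(cx.hr), "SE": cx.se_measured,
                         "P": cx.p, "PARTIAL_R2": np.nan, "N": cx.n_at_risk})
            res = pd.DataFrame(rows)
            res.insert(0, "DILUTION_RATIO", ratio)
            res.to_csv(out / "observational.tsv", sep="\t", index=False,
                       float_format="%.8g")
            record(stage, out / "observational.tsv")

        elif stage == "yll":
            _require(out / "cohort.csv", stage, "simulate")
            cohort = pd.read_csv(out / "cohort.csv")
            hazards = lifeexp.estimate_group_hazards(cohort)
            rates = synthetic_rates_cached(out)
            projection = lifeexp.project_survival(rates, hazards)
            yll = lifeexp.years_of_life_lost(projection)
            write_hazards(hazards, out / "group_hazards.csv")
            yll.to_csv(out / "yll.csv", index=False, float_format="%.8g")
            surv_rows = []
            for (g, sex), s in projection.survival.items():
                for age, val in zip(projection.ages(), s):
                    surv_rows.append((g, sex, age, val))
            pd.DataFrame(surv_rows, columns=["group", "sex", "age", "survival"]).to_csv(
                out / "survival.csv", index=False, float_format="%.8g")
            record(stage, out / "group_hazards.csv", out / "yll.csv", out / "survival.csv")

        elif stage == "burden":
            _require(out / "rare_carriers.tsv", stage, "simulate")
            cohort = pd.read_csv(out / "cohort.csv")
            carriers = pd.read_csv(out / "rare_carriers.tsv", sep="\t")
            rare = pd.read_csv(out / "rare_variants.tsv", sep="\t")
            scored = burden_mod.score_variants(rare)
            gene_scores = burden_mod.build_gene_scores(carriers, scored)
            covs = np.column_stack([cohort["age"].to_numpy(),
                                    (cohort["sex"] == "male").astype(float).to_numpy()])
            res = burden_mod.burden_test(gene_scores, cohort["ltl_burden"], covs)
            res.to_csv(out / "burden.tsv", sep="\t", index=False, float_format="%.8g")
            record(stage, out / "burden.tsv")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def synthetic_rates_cached(out: Path) -> pd.DataFrame:
    path = out / "population_rates.csv"
    if path.exists():
        return read_rates(path)
    rates = lifeexp.synthetic_population_rates()
    write_rates(rates, path)
    return rates


def _scan_covariates(cohort: pd.DataFrame) -> np.ndarray:
    """Age, sex, array and the first ten principal components."""
    return np.column_stack(
        [cohort["age"], (cohort["sex"] == "male").astype(float), cohort["array"]]
        + [cohort[f"pc{k}"] for k in range(1, 11)]
    )


def _outcome_covariates(cohort: pd.DataFrame) -> np.ndarray:
    """Age, sex, array and the first five principal components (outcome scans)."""
    return np.column_stack(
        [cohort["age"], (cohort["sex"] == "male").astype(float), cohort["array"]]
        + [cohort[f"pc{k}"] for k in range(1, 6)]
    )
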