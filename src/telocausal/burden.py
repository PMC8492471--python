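"""Gene-based rare-variant burden scoring and association with LTL.

Rare and ultra-rare variants (MAF < 0.1%) within a gene's exons are scored
per category (high-confidence loss-of-function and ultra-rare missense both
default to 1, i.e. carrier indicators); a participant's gene score sums
carried-allele x variant-score contributions and is capped at one. Gene
scores are tested against LTL by linear regression adjusted for age and
sex, with a Bonferroni flag at 0.05 / (genes tested).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError

logger = logging.getLogger("telocausal.burden")

RARE_MAF = 0.001
DEFAULT_CATEGORY_SCORES = {"hc_lof": 1.0, "ultrarare_missense": 1.0, "other": 0.0}
BONFERRONI_ALPHA = 0.05


def score_variants(
    variants: pd.DataFrame, category_scores: dict[str, float] | None = None
) -> pd.DataFrame:
    """Attach per-variant scores from their functional category.

    ``variants`` needs columns variant_id, gene, category, maf. Variants
    with MAF >= 0.1% are excluded (not rare); unknown categories score 0.
    """
    scores = dict(DEFAULT_CATEGORY_SCORES)
    if category_scores:
        scores.update(category_scores)
    required = {"variant_id", "gene", "category", "maf"}
    if not required.issubset(variants.columns):
        raise DataError(f"variant table needs columns {sorted(required)}")
    out = variants[variants["maf"] < RARE_MAF].copy()
    dropped = len(variants) - len(out)
    if dropped:
        logger.info("score_variants: %d variants with MAF >= %g excluded", dropped, RARE_MAF)
    out["score"] = out["category"].map(scores).fillna(0.0)
    return out.reset_index(drop=True)


def build_gene_scores(carriers: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Participant x gene score matrix, capped at one.

    ``carriers``: participants x variants allele counts (0/1/2), columns
    named by variant_id. Each participant's gene score is
    min(1, Σ alleles_v · score_v) over that gene's scored variants.
    Variants without a gene assignment are skipped with a log message.
    """
    unassigned = scores["gene"].isna() | (scores["gene"] == "")
    if unassigned.any():
        logger.warning(
            "build_gene_scores: %d variants without gene assignment skipped",
            int(unassigned.sum()),
        )
        scores = scores[~unassigned]
    genes = sorted(scores["gene"].unique())
    out = pd.DataFrame(0.0, index=carriers.index, columns=genes)
    for gene, grp in scores.groupby("gene"):
        vids = [v for v in grp["variant_id"] if v in carriers.columns]
        if not vids:
            continue
        weights = grp.set_index("variant_id").loc[vids, "score"].to_numpy()
        raw = carriers[vids].to_numpy(dtype=float) @ weights
        out[gene] = np.minimum(raw, 1.0)
    return out


def burden_test(
    gene_scores: pd.DataFrame,
    ltl: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene linear regression of LTL on the gene score.

    Covariates default to none but the pipeline passes age and sex. Genes
    with zero score variance are skipped. Returns GENE, BETA, SE, P,
    N_CARRIERS and a BONF flag at 0.05 / (genes tested).
    """
    y = np.asarray(ltl, dtype=float)
    n = len(y)
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    X0 = np.column_stack([np.ones(n), C])
    rows = []
    for gene in gene_scores.columns:
        g = gene_scores[gene].to_numpy(dtype=float)
        if g.std() == 0:
            logger.warning("burden_test: gene %s has zero score variance; skipped", gene)
            continue
        X = np.column_stack([X0, g])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        df = n - X.shape[1]
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * np.linalg.inv(X.T @ X)
        beta = float(coef[-1])
        se = float(np.sqrt(cov[-1, -1]))
        p = 2.0 * stats.t.sf(abs(beta / se), df) if se > 0 else 0.0
        rows.append((gene, beta, se, p, int((g > 0).sum())))
    res = pd.DataFrame(rows, columns=["GENE", "BETA", "SE", "P", "N_CARRIERS"])
    m = len(res)
    if m:
        threshold = BONFERRONI_ALPHA / m
        res["BONF"] = res["P"] < threshold
        logger.info("burden_test: Bonferroni threshold %.3g over %d genes", threshold, m)
    else:
        res["BONF"] = pd.Series(dtype=bool)
    return res
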