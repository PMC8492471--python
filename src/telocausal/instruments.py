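"""Instrument selection: LD clumping and pleiotropy filtering.

Reduces conditionally independent sentinel variants to a set that is
mutually uncorrelated (pairwise r² below a clump threshold within a physical
window) and non-pleiotropic (associated with fewer than a cutoff number of
distinct biological domains). The pipeline applies clumping first, then the
pleiotropy filter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import DataError
from .syncohort import DosageMatrix

logger = logging.getLogger("telocausal.instruments")

CLUMP_R2 = 0.01
CLUMP_WINDOW_BP = 1_000_000
MAX_PLEIOTROPY_DOMAINS = 3


def compute_ld(dosages: DosageMatrix) -> pd.DataFrame:
    """Pairwise dosage r² between all variants, indexed by variant id."""
    g = dosages.dosages
    sd = g.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(g)
    z[:, ok] = (g[:, ok] - g[:, ok].mean(axis=0)) / sd[ok]
    r = (z.T @ z) / g.shape[0]
    ids = dosages.variants["variant_id"].tolist()
    return pd.DataFrame(r**2, index=ids, columns=ids)


def _pair_r2(ld: pd.DataFrame, a: str, b: str) -> float:
    try:
        return float(ld.loc[a, b])
    except KeyError:
        logger.warning("LD entry missing for (%s, %s) within window; treated as 0", a, b)
        return 0.0


def ld_clump(
    variants: pd.DataFrame,
    ld: pd.DataFrame,
    r2_threshold: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
) -> pd.DataFrame:
    """Greedy P-value-ranked clumping.

    Variants are sorted by ascending P (ties by smaller SE, then position);
    the best is retained and every variant within ``window_bp`` on the same
    chromosome with r² > ``r2_threshold`` to a retained variant is discarded.
    Cross-window r² is treated as 0. Requires columns variant_id, chrom,
    pos, p and (for ties) se. Output order follows the ranking; a boolean
    column ``kept`` is NOT added — only retained rows are returned.
    """
    required = {"variant_id", "chrom", "pos", "p"}
    if not required.issubset(variants.columns):
        raise DataError(f"clump input needs columns {sorted(required)}")
    logger.info("ld_clump: removing variants with r^2 > %g within %d bp", r2_threshold, window_bp)
    se = variants["se"] if "se" in variants.columns else pd.Series(0.0, index=variants.index)
    ranked = variants.assign(_se=se).sort_values(
        by=["p", "_se", "pos", "variant_id"], kind="mergesort"
    )
    if ranked.empty:
        return variants.iloc[0:0].copy()
    kept_rows = []
    for _, row in ranked.iterrows():
        ok = True
        for kept in kept_rows:
            same_chrom = str(kept["chrom"]) == str(row["chrom"])
            in_window = same_chrom and abs(int(kept["pos"]) - int(row["pos"])) <= window_bp
            if in_window and _pair_r2(ld, kept["variant_id"], row["variant_id"]) > r2_threshold:
                ok = False
                break
        if ok:
            kept_rows.append(row)
    return pd.DataFrame(kept_rows).drop(columns=["_se"]).reset_index(drop=True)


def pleiotropy_filter(
    variants: pd.DataFrame,
    domain_counts: dict[str, int] | pd.Series,
    max_domains: int = MAX_PLEIOTROPY_DOMAINS,
) -> pd.DataFrame:
    """Drop variants associated with at least ``max_domains`` biological domains.

    ``domain_counts`` maps variant_id to the number of distinct domains with
    reported associations; missing variants count 0. Removed ids are logged.
    """
    counts = pd.Series(domain_counts)
    if (counts < 0).any():
        raise DataError("domain counts must be non-negative")
    n_domains = variants["variant_id"].map(counts).fillna(0).astype(int)
    removed = variants.loc[n_domains >= max_domains, "variant_id"].tolist()
    if removed:
        logger.info(
            "pleiotropy_filter: removed %d variants with >= %d domains: %s",
            len(removed), max_domains, ", ".join(removed),
        )
    out = variants.loc[n_domains < max_domains].reset_index(drop=True)
    out = out.assign(pleiotropy_domains=n_domains[n_domains < max_domains].to_numpy())
    return out


def select_instruments(
    variants: pd.DataFrame,
    ld: pd.DataFrame,
    domain_counts: dict[str, int] | pd.Series,
    *,
    r2_threshold: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
    max_domains: int = MAX_PLEIOTROPY_DOMAINS,
    blacklist: set[str] | None = None,
) -> pd.DataFrame:
    """Clump, then filter pleiotropic variants; optional artifact blacklist first."""
    work = variants
    if blacklist:
        work = work[~work["variant_id"].isin(blacklist)].reset_index(drop=True)
        logger.info("select_instruments: blacklist removed %d variants", len(variants) - len(work))
    clumped = ld_clump(work, ld, r2_threshold=r2_threshold, window_bp=window_bp)
    return pleiotropy_filter(clumped, domain_counts, max_domains=max_domains)
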