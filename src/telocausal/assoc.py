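"""Single-variant and joint conditional association of LTL on dosages.

Covers the GWAS-style scan (covariate-adjusted least squares or logistic
regression with MAF/INFO pre-filters), exact joint modelling with backward
elimination at a genome-wide threshold, the Benjamini-Hochberg-derived P
threshold, variance explained by a variant set (ΔR²), and the relatedness
exclusion that removes one member of every pair closer than a kinship cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DataError, ModelError
from .syncohort import DosageMatrix

logger = logging.getLogger("telocausal.assoc")

#: Genome-wide significance for scans including low-frequency variants.
GENOME_WIDE_P = 8.31e-9
#: Stage-one screening threshold feeding the joint conditional model.
STAGE_ONE_P = 1e-6
#: Kinship coefficient above which a pair counts as related (~2nd degree).
KINSHIP_THRESHOLD = 0.088
MIN_MAF = 0.001
MIN_INFO = 0.3


def _design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    """Intercept + covariates as a dense float design matrix."""
    if covariates is None:
        return np.ones((n, 1))
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return np.column_stack([np.ones(n), arr])


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def variant_scan(
    dosages: DosageMatrix,
    phenotype: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    *,
    binary: bool = False,
    min_maf: float = MIN_MAF,
    min_info: float = MIN_INFO,
) -> pd.DataFrame:
    """Marginal per-variant association scan.

    Continuous phenotypes use covariate-adjusted least squares via
    Frisch-Waugh partialling (numerically identical to the joint OLS
    coefficient); binary phenotypes use per-variant logistic regression.
    Variants failing the MAF/INFO pre-filter are excluded; zero-variance
    dosages are skipped with a warning. Returns one row per retained
    variant: variant_id, chrom, pos, effect_allele, other_allele, eaf,
    info, maf, beta, se, p, n.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if dosages.n_participants != n:
        raise DataError("phenotype length does not match dosage matrix")
    meta = dosages.variants
    maf = np.minimum(meta["eaf"].to_numpy(), 1.0 - meta["eaf"].to_numpy())
    keep = (maf >= min_maf) & (meta["info"].to_numpy() >= min_info)
    logger.info(
        "variant_scan: MAF >= %g and INFO >= %g retain %d/%d variants",
        min_maf, min_info, int(keep.sum()), len(meta),
    )
    X = _design(covariates, n)
    p_cov = X.shape[1]

    rows = []
    if binary:
        import statsmodels.api as sm

        for j in np.nonzero(keep)[0]:
            g = dosages.dosages[:, j]
            if g.std() == 0:
                logger.warning("variant %s monomorphic; skipped", meta["variant_id"].iloc[j])
                continue
            try:
                fit = sm.Logit(y, np.column_stack([X, g])).fit(disp=0, maxiter=200)
                beta, se = fit.params[-1], fit.bse[-1]
                p = fit.pvalues[-1]
                if not np.isfinite(se) or se > 100:
                    raise np.linalg.LinAlgError
            except Exception:
                logger.warning(
                    "variant %s: logistic separation/non-convergence; P set missing",
                    meta["variant_id"].iloc[j],
                )
                beta, se, p = np.nan, np.nan, np.nan
            rows.append((j, beta, se, p))
    else:
        y_r = _residualize(y, X)
        df = n - p_cov - 1
        for j in np.nonzero(keep)[0]:
            g = dosages.dosages[:, j]
            if g.std() == 0:
                logger.warning("variant %s monomorphic; skipped", meta["variant_id"].iloc[j])
                continue
            g_r = _residualize(g, X)
            gg = float(g_r @ g_r)
            if gg <= 1e-12:
                logger.warning(
                    "variant %s has zero residual variance; skipped", meta["variant_id"].iloc[j]
                )
                continue
            beta = float(g_r @ y_r) / gg
            rss = float(y_r @ y_r) - beta * beta * gg
            sigma2 = max(rss, 0.0) / df
            se = np.sqrt(sigma2 / gg)
            t = beta / se if se > 0 else np.inf
            p = 2.0 * stats.t.sf(abs(t), df)
            rows.append((j, beta, se, max(p, np.nextafter(0, 1))))

    idx = [r[0] for r in rows]
    res = meta.iloc[idx][
        ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf", "info"]
    ].reset_index(drop=True)
    res["maf"] = np.minimum(res["eaf"], 1 - res["eaf"])
    res["beta"] = [r[1] for r in rows]
    res["se"] = [r[2] for r in rows]
    res["p"] = [r[3] for r in rows]
    res["n"] = n
    return res


@dataclass
class JointModelResult:
    """Survivors of backward elimination with their conditional statistics."""

    table: pd.DataFrame  # variant_id, beta, se, p (conditional)
    r_squared: float
    dropped: list[str]


def joint_conditional(
    dosages: DosageMatrix,
    candidates: list[str],
    phenotype: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    threshold: float = GENOME_WIDE_P,
) -> JointModelResult:
    """Exact joint modelling with backward elimination.

    All candidates are fit jointly with the covariates; the variant with the
    weakest conditional evidence (highest P, ties by larger SE then by
    position) is dropped and the model refit until every retained variant has
    conditional P < threshold. Perfectly collinear candidates are resolved
    first by dropping the later variant (by position, then id).
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    meta = dosages.variants.set_index("variant_id")
    missing = [c for c in candidates if c not in meta.index]
    if missing:
        raise DataError(f"unknown candidate variants: {missing}")
    X = _design(covariates, n)
    if not candidates:
        return JointModelResult(
            table=pd.DataFrame(columns=["variant_id", "beta", "se", "p"]),
            r_squared=0.0, dropped=[])

    order = {v: i for i, v in enumerate(dosages.variants["variant_id"])}
    current = sorted(candidates, key=lambda v: (str(meta.loc[v, "chrom"]), int(meta.loc[v, "pos"]), v))
    dropped: list[str] = []

    # resolve exact collinearity up front: later (position, id) goes first
    while True:
        G = np.column_stack([dosages.dosages[:, order[v]] for v in current])
        M = np.column_stack([X, G])
        if np.linalg.matrix_rank(M) == M.shape[1]:
            break
        for k in range(len(current) - 1, -1, -1):
            sub = current[:k] + current[k + 1:]
            Gs = np.column_stack([dosages.dosages[:, order[v]] for v in sub]) if sub else np.empty((n, 0))
            if np.linalg.matrix_rank(np.column_stack([X, Gs])) == X.shape[1] + len(sub):
                victim = current[k]
                logger.warning("joint_conditional: dropping collinear variant %s", victim)
                dropped.append(victim)
                current = sub
                break
        else:  # pragma: no cover - cannot happen once X is full rank
            raise ModelError("could not resolve collinearity")
        if not current:
            break

    def fit(variant_ids: list[str]):
        G = np.column_stack([dosages.dosages[:, order[v]] for v in variant_ids])
        M = np.column_stack([X, G])
        coef, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ coef
        df = n - M.shape[1]
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * np.linalg.inv(M.T @ M)
        k0 = X.shape[1]
        betas = coef[k0:]
        ses = np.sqrt(np.diag(cov)[k0:])
        ps = 2.0 * stats.t.sf(np.abs(betas / ses), df)
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
        return betas, ses, ps, r2

    betas = ses = ps = np.array([])
    r2 = 0.0
    while current:
        betas, ses, ps, r2 = fit(current)
        if np.all(ps < threshold):
            break
        worst = max(
            range(len(current)),
            key=lambda i: (ps[i], ses[i], int(meta.loc[current[i], "pos"])),
        )
        victim = current[worst]
        logger.info("joint_conditional: dropping %s (conditional P=%.3g)", victim, ps[worst])
        dropped.append(victim)
        current = current[:worst] + current[worst + 1:]

    table = pd.DataFrame({"variant_id": current, "beta": betas[: len(current)],
                          "se": ses[: len(current)], "p": ps[: len(current)]})
    return JointModelResult(table=table, r_squared=r2, dropped=dropped)


def derive_fdr_threshold(p_values, q: float) -> float:
    """Benjamini-Hochberg step-up: largest P declared significant at level q.

    Returns 0.0 when nothing passes.
    """
    if not (0.0 < q < 1.0):
        raise ConfigurationError(f"q must lie in (0, 1), got {q}")
    p = np.sort(np.asarray(list(p_values), dtype=float))
    if p.size == 0:
        raise DataError("p_values must be nonempty")
    m = p.size
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(p <= crit)[0]
    return float(p[passing[-1]]) if passing.size else 0.0


def variance_explained(
    dosages: DosageMatrix,
    variant_ids: list[str],
    phenotype: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> float:
    """ΔR²: R²(covariates + variants) − R²(covariates)."""
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    order = {v: i for i, v in enumerate(dosages.variants["variant_id"])}
    missing = [v for v in variant_ids if v not in order]
    if missing:
        raise DataError(f"unknown variants: {missing}")
    if len(variant_ids) >= n:
        raise ModelError("more variants than observations")
    X = _design(covariates, n)

    def r2(M: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ coef
        tss = float(((y - y.mean()) ** 2).sum())
        return 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0

    base = r2(X)
    G = np.column_stack([dosages.dosages[:, order[v]] for v in variant_ids]) if variant_ids else None
    full = r2(np.column_stack([X, G])) if G is not None else base
    return max(full - base, 0.0)


def _max_independent_set(adj: dict[str, set[str]], order_hint: list[str]) -> set[str]:
    """Exact maximum independent set by branch and bound on one component."""
    nodes = order_hint
    best: set[str] = set()

    def search(candidates: list[str], chosen: set[str]):
        nonlocal best
        if len(chosen) + len(candidates) <= len(best):
            return
        if not candidates:
            if len(chosen) > len(best):
                best = set(chosen)
            return
        # branch on the highest-degree remaining node
        v = max(candidates, key=lambda u: len(adj[u] & set(candidates)))
        rest = [u for u in candidates if u != v]
        search([u for u in rest if u not in adj[v]], chosen | {v})
        search(rest, chosen)

    search(nodes, set())
    return best


def unrelated_subset(
    pairs: pd.DataFrame, k_threshold: float = KINSHIP_THRESHOLD, seed: int = 0
) -> set[str]:
    """Participants to drop so no remaining pair exceeds the kinship cutoff.

    Pairs with K > k_threshold define a relatedness graph; the removal set is
    the complement of a maximum independent set, computed exactly per
    connected component (branch and bound) for components up to 30 nodes and
    by greedy highest-degree removal beyond that. Node order is shuffled
    under the seed, so ties among equally valid removals resolve randomly
    but reproducibly.
    """
    if k_threshold < 0:
        raise ConfigurationError("k_threshold must be non-negative")
    logger.info("unrelated_subset: excluding one of each pair with K > %g", k_threshold)
    related = pairs[pairs["k"] > k_threshold]
    if related.empty:
        return set()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 505]))
    adj: dict[str, set[str]] = {}
    for a, b in zip(related["id_a"], related["id_b"]):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    # connected components
    drop: set[str] = set()
    unvisited = set(adj)
    while unvisited:
        start = next(iter(unvisited))
        comp = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            for u in adj[v]:
                if u not in comp:
                    comp.add(u)
                    frontier.append(u)
        unvisited -= comp
        comp_nodes = sorted(comp)
        rng.shuffle(comp_nodes)
        if len(comp_nodes) <= 30:
            keep = _max_independent_set({v: adj[v] & comp for v in comp}, comp_nodes)
            drop |= comp - keep
        else:  # greedy: repeatedly remove the highest-degree node
            local = {v: set(adj[v] & comp) for v in comp}
            while any(local[v] for v in local):
                v = max(local, key=lambda u: (len(local[u]), u))
                for u in local[v]:
                    local[u].discard(v)
                del local[v]
                drop.add(v)
    return drop
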