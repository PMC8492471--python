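"""Observational trait and disease analysis.

Trait preparation (winsorization, optional log transform, Z-standardization),
regression-dilution estimation from repeat measurements, covariate-adjusted
linear/logistic association with correction to "usual" LTL, nonlinearity
assessment (quadratic term and fractional polynomials), and Cox models for
incident disease with a proportional-hazards time-interaction check.

Effect estimates on measured LTL are attenuated by within-person variability;
dividing by the regression-dilution ratio (slope of a repeat measurement on
the first) re-expresses them per s.d. usual LTL.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ModelError

logger = logging.getLogger("telocausal.obsassoc")

DILUTION_RATIO = 0.68
WINSOR_LOWER_PCT = 0.5
WINSOR_UPPER_PCT = 99.5
LOG_SKEW_THRESHOLD = 1.0
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)
DEFAULT_COVARIATES = ("age", "sex", "ethnic_group", "wbc")


def prepare_trait(values, *, skew_threshold: float = LOG_SKEW_THRESHOLD) -> np.ndarray:
    """Winsorize at the 0.5/99.5 percentiles, log-transform when skewed,
    Z-standardize.

    The natural-log branch triggers when |skewness| of the winsorized values
    exceeds ``skew_threshold`` and all values are positive; otherwise the
    transform is skipped with a warning.
    """
    x = np.asarray(values, dtype=float)
    if np.nanstd(x) == 0:
        raise DataError("constant trait cannot be prepared")
    lo, hi = np.nanpercentile(x, [WINSOR_LOWER_PCT, WINSOR_UPPER_PCT])
    x = np.clip(x, lo, hi)
    logger.info("prepare_trait: winsorized at %.1f/%.1f percentiles", WINSOR_LOWER_PCT, WINSOR_UPPER_PCT)
    skew = float(stats.skew(x, nan_policy="omit"))
    if abs(skew) > skew_threshold:
        if np.nanmin(x) > 0:
            x = np.log(x)
            logger.info("prepare_trait: log transform applied (skew %.2f)", skew)
        else:
            logger.warning("prepare_trait: skew %.2f but non-positive values; log skipped", skew)
    return (x - np.nanmean(x)) / np.nanstd(x)


def estimate_dilution_ratio(first, second) -> float:
    """Regression-dilution ratio: slope of the standardized repeat
    measurement on the standardized first measurement."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        raise DataError("need at least 2 paired measurements")
    if len(a) < 10:
        warnings.warn("fewer than 10 repeat pairs: dilution ratio is unstable", stacklevel=2)
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    return float((a * b).sum() / (a * a).sum())


def _covariate_matrix(cohort: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for c in covariates:
        v = cohort[c]
        if v.dtype == object or str(v.dtype) == "category":
            dummies = pd.get_dummies(v, drop_first=True, dtype=float)
            cols.append(dummies.to_numpy())
        else:
            cols.append(v.to_numpy(dtype=float)[:, None])
    return np.hstack(cols) if cols else np.empty((len(cohort), 0))


@dataclass
class TraitResult:
    trait: str
    kind: str
    beta: float  # per s.d. measured LTL (log-odds for binary)
    se: float
    p: float
    beta_usual: float  # corrected to per s.d. usual LTL
    se_usual: float
    partial_r2: float
    n: int
    quad_p: float | None = None
    fp_powers: tuple[float, ...] | None = None


def associate(
    cohort: pd.DataFrame,
    trait: str,
    kind: str = "continuous",
    *,
    exposure: str = "ltl_measured",
    covariates=DEFAULT_COVARIATES,
    dilution_ratio: float = DILUTION_RATIO,
) -> TraitResult:
    """Covariate-adjusted association of a prepared trait with measured LTL.

    Linear regression for continuous traits, logistic for binary. The
    "usual LTL" estimate divides beta (and its SE) by the regression-
    dilution ratio. partial_r2 is R²(full) − R²(without LTL); for binary
    traits McFadden's pseudo-R² difference is used.
    """
    import statsmodels.api as sm

    y = cohort[trait].to_numpy(dtype=float)
    z = cohort[exposure].to_numpy(dtype=float)
    C = _covariate_matrix(cohort, covariates)
    X_full = np.column_stack([np.ones(len(y)), z, C])
    X_red = np.column_stack([np.ones(len(y)), C])

    if kind == "continuous":
        full = sm.OLS(y, X_full).fit()
        red = sm.OLS(y, X_red).fit()
        beta, se, p = full.params[1], full.bse[1], full.pvalues[1]
        partial = max(full.rsquared - red.rsquared, 0.0)
    elif kind == "binary":
        try:
            full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
            red = sm.Logit(y, X_red).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise ModelError(f"logistic fit failed for {trait!r} (separation?): {exc}") from exc
        beta, se, p = full.params[1], full.bse[1], full.pvalues[1]
        partial = max(full.prsquared - red.prsquared, 0.0)
    else:
        raise DataError(f"unknown trait kind {kind!r}")
    return TraitResult(
        trait=trait, kind=kind, beta=float(beta), se=float(se), p=float(p),
        beta_usual=float(beta) / dilution_ratio, se_usual=float(se) / dilution_ratio,
        partial_r2=float(partial), n=len(y),
    )


def _fp_terms(x: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """Fractional-polynomial basis; power 0 is ln x, repeated powers add a
    log factor (Royston-Altman convention). Requires positive x."""
    cols = []
    prev = None
    for p in powers:
        t = np.log(x) if p == 0 else x**p
        if prev is not None and p == prev:
            t = t * np.log(x)
        cols.append(t)
        prev = p
    return np.column_stack(cols)


def nonlinearity(
    cohort: pd.DataFrame,
    outcome: str,
    *,
    kind: str = "continuous",
    exposure: str = "ltl_measured",
    covariates=(),
    alpha: float = 0.05,
) -> tuple[float, tuple[float, ...]]:
    """Quadratic-term P value and fractional-polynomial model selection.

    The exposure is shifted to be strictly positive for the FP basis.
    FP1 searches powers {-2,-1,-0.5,0,0.5,1,2,3}; FP2 searches unordered
    pairs. The more complex model is selected only when the 2-df deviance
    improvement has P < ``alpha`` (FP1 vs linear, then FP2 vs FP1).
    Returns (quad_p, selected_powers); (1.0,) denotes the linear model.

    ``kind``: "continuous" (least squares) or one of the cohort's disease
    prefixes with kind="survival" (Cox partial likelihood on incident
    events, prevalent excluded).
    """
    z = cohort[exposure].to_numpy(dtype=float)
    x = z - z.min() + 0.1  # positive shift for fractional powers
    C = _covariate_matrix(cohort, covariates)

    if kind == "continuous":
        y = cohort[outcome].to_numpy(dtype=float)

        def loglik(terms: np.ndarray) -> float:
            X = np.column_stack([np.ones(len(y)), terms, C])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ coef) ** 2).sum())
            return -0.5 * len(y) * np.log(rss / len(y))

        import statsmodels.api as sm

        quad = sm.OLS(y, np.column_stack([np.ones(len(y)), z, z**2, C])).fit()
        quad_p = float(quad.pvalues[2])
    elif kind == "survival":
        from lifelines import CoxPHFitter

        mask = cohort[f"{outcome}_prevalent"] == 0
        sub = cohort.loc[mask]
        x = x[mask.to_numpy()]
        z_s = z[mask.to_numpy()]
        C = C[mask.to_numpy()] if C.size else np.empty((mask.sum(), 0))

        def loglik(terms: np.ndarray) -> float:
            df = pd.DataFrame(terms, index=sub.index).add_prefix("fp")
            for i in range(C.shape[1]):
                df[f"c{i}"] = C[:, i]
            df["T"] = sub[f"{outcome}_time"].to_numpy()
            df["E"] = sub[f"{outcome}_incident"].to_numpy()
            f = CoxPHFitter()
            f.fit(df, duration_col="T", event_col="E")
            return float(f.log_likelihood_)

        ll_lin = loglik(z_s[:, None])
        ll_quad = loglik(np.column_stack([z_s, z_s**2]))
        quad_p = float(stats.chi2.sf(2 * (ll_quad - ll_lin), 1))
    else:
        raise DataError(f"unknown outcome kind {kind!r}")

    ll_linear = loglik(x[:, None])
    best1, ll1 = None, -np.inf
    for p in FP_POWERS:
        try:
            ll = loglik(_fp_terms(x, (p,)))
        except Exception:
            logger.warning("FP1 power %s did not converge; skipped", p)
            continue
        if ll > ll1:
            best1, ll1 = (p,), ll
    selected, ll_sel = (1.0,), ll_linear
    if best1 is not None and stats.chi2.sf(2 * (ll1 - ll_linear), 2) < alpha:
        selected, ll_sel = best1, ll1
        best2, ll2 = None, -np.inf
        for pair in itertools.combinations_with_replacement(FP_POWERS, 2):
            try:
                ll = loglik(_fp_terms(x, pair))
            except Exception:
                logger.warning("FP2 powers %s did not converge; skipped", (pair,))
                continue
            if ll > ll2:
                best2, ll2 = pair, ll
        if best2 is not None and stats.chi2.sf(2 * (ll2 - ll_sel), 2) < alpha:
            selected = best2
    return quad_p, selected


@dataclass
class CoxResult:
    disease: str
    hr: float  # per s.d. usual LTL
    ci: tuple[float, float]
    p: float
    log_hr_measured: float  # naive, per s.d. measured LTL
    se_measured: float
    ph_interaction_p: float | None
    hr_baseline: float | None
    hr_10y: float | None
    n_incident: int
    n_at_risk: int


def _episode_split(df: pd.DataFrame, duration: str, event: str, step: float = 1.0) -> pd.DataFrame:
    """Split follow-up into intervals on a regular grid for time-varying fits."""
    t_end = df[duration].to_numpy(dtype=float)
    ev = df[event].to_numpy(dtype=int)
    n_int = np.maximum(np.ceil(t_end / step).astype(int), 1)
    pid = np.repeat(df.index.to_numpy(), n_int)
    interval = np.concatenate([np.arange(k) for k in n_int])
    start = interval * step
    stop = np.minimum(start + step, np.repeat(t_end, n_int))
    last = np.concatenate([np.arange(k) == k - 1 for k in n_int])
    return pd.DataFrame({"pid": pid, "start": start, "stop": stop,
                         "event": np.where(last, np.repeat(ev, n_int), 0)})


def cox_incident(
    cohort: pd.DataFrame,
    disease: str,
    *,
    exposure: str = "ltl_measured",
    strata=("sex", "ethnic_group"),
    covariates=("age", "wbc"),
    dilution_ratio: float = DILUTION_RATIO,
    ph_alpha: float = 0.05,
    ph_check: bool = True,
    ph_step: float = 2.0,
) -> CoxResult:
    """Cox model for incident disease, stratified by sex and ethnicity and
    adjusted for age and WBC count; prevalent cases are excluded.

    The proportional-hazards assumption is checked with an LTL-by-time
    interaction (episode-split time-varying fit); when its P < ``ph_alpha``
    the HRs at baseline and at 10 years are reported via the linear
    combination b_ltl + t·b_interaction. The headline HR is expressed per
    s.d. usual LTL by dividing the log-HR by the dilution ratio.
    """
    from lifelines import CoxPHFitter, CoxTimeVaryingFitter

    sub = cohort[cohort[f"{disease}_prevalent"] == 0].copy()
    if (sub[f"{disease}_time"] <= 0).any():
        sub = sub[sub[f"{disease}_time"] > 0]
    n_inc = int(sub[f"{disease}_incident"].sum())
    if n_inc == 0:
        raise ModelError(f"no incident {disease!r} events")
    for s in strata:
        counts = sub.groupby(s, observed=True)[f"{disease}_incident"].sum()
        empty = counts[counts == 0].index.tolist()
        if empty:
            logger.warning("cox_incident: dropping %s strata with no events: %s", s, empty)
            sub = sub[~sub[s].isin(empty)]

    df = pd.DataFrame({
        "T": sub[f"{disease}_time"].to_numpy(),
        "E": sub[f"{disease}_incident"].to_numpy(),
        "ltl": sub[exposure].to_numpy(),
    })
    for c in covariates:
        df[c] = sub[c].to_numpy(dtype=float) if sub[c].dtype != object else sub[c].to_numpy()
    for s in strata:
        df[s] = sub[s].to_numpy()
    fitter = CoxPHFitter()
    fitter.fit(df, duration_col="T", event_col="E", strata=list(strata))
    b = float(fitter.params_["ltl"])
    se = float(fitter.standard_errors_["ltl"])
    p = float(fitter.summary.loc["ltl", "p"])
    b_usual = b / dilution_ratio
    se_usual = se / dilution_ratio
    ci = (np.exp(b_usual - 1.96 * se_usual), np.exp(b_usual + 1.96 * se_usual))

    # PH check: interaction of LTL with time on an episode-split data set
    p_int = hr0 = hr10 = None
    if ph_check:
        episodes = _episode_split(df, "T", "E", step=ph_step)
        tv = episodes.merge(
            df.drop(columns=["T", "E"]), left_on="pid", right_index=True, how="left"
        )
        tmid = (tv["start"] + tv["stop"]) / 2.0
        tv["ltl_x_t"] = tv["ltl"] * tmid
        ctv = CoxTimeVaryingFitter()
        ctv.fit(tv, id_col="pid", start_col="start", stop_col="stop", event_col="event",
                strata=list(strata))
        b_int = float(ctv.params_["ltl_x_t"])
        p_int = float(ctv.summary.loc["ltl_x_t", "p"])
        if p_int < ph_alpha:
            b0 = float(ctv.params_["ltl"])
            hr0 = float(np.exp(b0 / dilution_ratio))
            hr10 = float(np.exp((b0 + 10.0 * b_int) / dilution_ratio))
            logger.info("cox_incident: PH violated for %s (P=%.3g); HRs at 0 and 10y reported",
                        disease, p_int)
    return CoxResult(
        disease=disease, hr=float(np.exp(b_usual)), ci=ci, p=p,
        log_hr_measured=b, se_measured=se, ph_interaction_p=p_int,
        hr_baseline=hr0, hr_10y=hr10, n_incident=n_inc, n_at_risk=len(df),
    )
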