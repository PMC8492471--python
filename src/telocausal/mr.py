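"""Mendelian-randomization estimator suite.

Four estimators over per-instrument summary associations (SNP-exposure
beta/SE, SNP-outcome beta/SE): inverse-variance weighted with multiplicative
random effects, MR-Egger regression, the weighted median, and a
contamination-mixture profile likelihood admitting multimodal confidence
sets. Heterogeneity is quantified with Cochran's Q and the I² statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, ModelError

logger = logging.getLogger("telocausal.mr")

Z95 = 1.959963984540054


@dataclass
class MRInput:
    """Harmonized per-instrument associations.

    bx/sx: effect and SE on the exposure (s.d. LTL per effect allele);
    by/sy: effect and SE on the outcome, for the same effect allele.
    """

    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    ids: list[str] | None = None

    def __post_init__(self):
        self.bx = np.asarray(self.bx, dtype=float)
        self.sx = np.asarray(self.sx, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        if not (len(self.bx) == len(self.sx) == len(self.by) == len(self.sy)):
            raise ConfigurationError("bx, sx, by, sy must share a length")
        if len(self.bx) < 1:
            raise ConfigurationError("at least one instrument required")
        if np.any(self.sx <= 0) or np.any(self.sy <= 0):
            raise ConfigurationError("all standard errors must be positive")

    def __len__(self) -> int:
        return len(self.bx)

    def oriented(self) -> "MRInput":
        """Flip instruments so every exposure beta is non-negative."""
        sign = np.where(self.bx < 0, -1.0, 1.0)
        return MRInput(self.bx * sign, self.sx, self.by * sign, self.sy, self.ids)


@dataclass
class MREstimate:
    """One estimator's causal effect per s.d. genetically determined LTL."""

    method: str
    theta: float
    se: float | None
    ci95: tuple[float, float] | None
    p: float | None
    n_instruments: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    Q: float | None = None
    i2: float | None = None
    ci_set: list[tuple[float, float]] | None = None  # contamination mixture only
    modes: list[float] = field(default_factory=list)


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> tuple[float, float]:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if bx == 0:
        raise ModelError("Wald ratio undefined for bx = 0")
    return by / bx, abs(sy / bx)


def heterogeneity(data: MRInput, theta: float) -> tuple[float, float]:
    """Cochran's Q about ``theta`` and I² (percent), as used by IVW."""
    if len(data) < 2:
        raise ModelError("heterogeneity needs at least 2 instruments")
    q = float(np.sum((data.by - theta * data.bx) ** 2 / data.sy**2))
    dof = len(data) - 1
    i2 = max(0.0, (q - dof) / q) * 100.0 if q > 0 else 0.0
    return q, i2


def ivw(data: MRInput) -> MREstimate:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    Weighted least squares of by on bx through the origin with weights
    1/sy²; the fixed-effect SE is inflated by sqrt(max(1, Q/(J-1))).
    A single instrument degenerates to the Wald ratio (Q, I² missing).
    """
    w = 1.0 / data.sy**2
    denom = float(np.sum(w * data.bx**2))
    if denom <= 0:
        raise ModelError("IVW undefined: all exposure betas are zero")
    theta = float(np.sum(w * data.bx * data.by)) / denom
    se_fe = float(np.sqrt(1.0 / denom))
    if len(data) == 1:
        theta_w, se_w = wald_ratio(data.bx[0], data.sx[0], data.by[0], data.sy[0])
        p = 2.0 * stats.norm.sf(abs(theta_w / se_w))
        return MREstimate("ivw", theta_w, se_w, (theta_w - Z95 * se_w, theta_w + Z95 * se_w),
                          p, 1, Q=None, i2=None)
    q, i2 = heterogeneity(data, theta)
    scale = float(np.sqrt(max(1.0, q / (len(data) - 1))))
    se = se_fe * scale
    p = 2.0 * stats.norm.sf(abs(theta / se))
    return MREstimate("ivw", theta, se, (theta - Z95 * se, theta + Z95 * se), p,
                      len(data), Q=q, i2=i2)


def mr_egger(data: MRInput) -> MREstimate:
    """MR-Egger regression: intercept estimates average directional pleiotropy.

    Instruments are re-orientated so bx >= 0; weighted (1/sy²) regression of
    by on bx with an intercept; multiplicative random-effects scaling uses
    the regression's Q on J-2 degrees of freedom.
    """
    if len(data) < 3:
        raise ModelError("MR-Egger needs at least 3 instruments")
    d = data.oriented()
    w = 1.0 / d.sy**2
    X = np.column_stack([np.ones(len(d)), d.bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ d.by)
    resid = d.by - X @ coef
    q = float(np.sum(w * resid**2))
    dof = len(d) - 2
    scale = max(1.0, q / dof)
    cov = np.linalg.inv(xtwx) * scale
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    i2 = max(0.0, (q - dof) / q) * 100.0 if q > 0 else 0.0
    p_slope = 2.0 * stats.norm.sf(abs(slope / se_slope)) if se_slope > 0 else 0.0
    p_int = 2.0 * stats.norm.sf(abs(intercept / se_int)) if se_int > 0 else 0.0
    return MREstimate(
        "egger", float(slope), float(se_slope),
        (slope - Z95 * se_slope, slope + Z95 * se_slope), p_slope, len(d),
        egger_intercept=float(intercept), egger_intercept_se=float(se_int),
        egger_intercept_p=p_int, Q=q, i2=i2,
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - w / 2.0  # centred cumulative weight
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(cum, 0.5))
    frac = (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1])
    return float(r[k - 1] + frac * (r[k] - r[k - 1]))


def weighted_median(data: MRInput, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of Wald ratios; consistent when valid instruments
    carry at least half the weight.

    Weights are inverse variances of the ratio estimates (bx²/sy² to first
    order); the estimate interpolates where centred cumulative weight
    crosses 0.5. SE by seeded parametric bootstrap.
    """
    if len(data) < 3:
        raise ModelError("weighted median needs at least 3 instruments")
    if np.any(data.bx == 0):
        raise ModelError("weighted median undefined with bx = 0 instruments")
    ratios = data.by / data.bx
    weights = data.bx**2 / data.sy**2
    theta = _weighted_median(ratios, weights)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 606]))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = data.bx + rng.standard_normal(len(data)) * data.sx
        by = data.by + rng.standard_normal(len(data)) * data.sy
        bad = bx == 0
        bx[bad] = data.bx[bad]
        boots[b] = _weighted_median(by / bx, bx**2 / data.sy**2)
    se = float(np.std(boots, ddof=1))
    p = 2.0 * stats.norm.sf(abs(theta / se)) if se > 0 else 0.0
    return MREstimate("weighted_median", theta, se,
                      (theta - Z95 * se, theta + Z95 * se), p, len(data))


def contamination_mixture(
    data: MRInput, psi: float | None = None, grid: np.ndarray | None = None
) -> MREstimate:
    """Contamination-mixture profile likelihood over candidate effects.

    At each grid value θ every instrument's Wald ratio is classed as valid
    (Normal(θ, se_j²)) or invalid (Normal(0, se_j² + psi²)), whichever is
    more likely; the profile log-likelihood is maximized over the grid. The
    95% confidence set is {θ : 2(ℓmax − ℓ(θ)) < 3.84} and may be a union of
    intervals; all local modes inside it are reported. Defaults: psi is the
    empirical s.d. of the ratio estimates; the grid has 1001 points spanning
    the ratio range extended by twice its width on both sides.
    """
    if len(data) < 1:
        raise ModelError("contamination mixture needs at least 1 instrument")
    if np.any(data.bx == 0):
        raise ModelError("contamination mixture undefined with bx = 0 instruments")
    ratios = data.by / data.bx
    ses = data.sy / np.abs(data.bx)
    if psi is None:
        psi = float(np.std(ratios, ddof=1)) if len(data) > 1 else float(2 * ses[0])
        psi = max(psi, 1e-8)
        logger.info("contamination_mixture: default psi = %.4g (sd of ratios)", psi)
    if psi <= 0:
        raise ConfigurationError("psi must be positive")
    if grid is None:
        lo, hi = float(ratios.min()), float(ratios.max())
        span = max(hi - lo, 4 * float(ses.min()))
        grid = np.linspace(lo - 2 * span, hi + 2 * span, 1001)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigurationError("theta grid must be nonempty")

    ll_valid = stats.norm.logpdf(ratios[None, :], loc=grid[:, None], scale=ses[None, :])
    ll_invalid = stats.norm.logpdf(ratios, loc=0.0, scale=np.sqrt(ses**2 + psi**2))
    ll = np.maximum(ll_valid, ll_invalid[None, :]).sum(axis=1)

    best = int(np.argmax(ll))
    theta = float(grid[best])
    inside = 2.0 * (ll[best] - ll) < stats.chi2.ppf(0.95, 1)
    # contiguous runs of grid points inside the confidence set
    ci_set: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            ci_set.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        ci_set.append((float(grid[start]), float(grid[-1])))
    # local maxima of the profile inside the confidence set
    modes = []
    for i in np.nonzero(inside)[0]:
        left = ll[i - 1] if i > 0 else -np.inf
        right = ll[i + 1] if i < len(ll) - 1 else -np.inf
        if ll[i] >= left and ll[i] >= right and (ll[i] > left or ll[i] > right):
            modes.append(float(grid[i]))
    main = ci_set[0] if len(ci_set) == 1 else None
    se = (main[1] - main[0]) / (2 * Z95) if main else None
    return MREstimate("contamination_mixture", theta, se, main, None, len(data),
                      ci_set=ci_set, modes=modes)


def run_all(
    data: MRInput, *, n_boot: int = 1000, seed: int = 0,
    psi: float | None = None, grid: np.ndarray | None = None,
) -> list[MREstimate]:
    """IVW, MR-Egger, weighted median and contamination mixture where the
    instrument count permits each."""
    out = [ivw(data)]
    if len(data) >= 3:
        out.append(mr_egger(data))
        out.append(weighted_median(data, n_boot=n_boot, seed=seed))
    if len(data) >= 2:
        out.append(contamination_mixture(data, psi=psi, grid=grid))
    return out
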