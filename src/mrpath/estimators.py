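"""Univariable two-sample MR estimators.

All estimators regress harmonized outcome effects on exposure effects, weight
by inverse outcome variance, and report the causal effect on the log-odds
scale alongside its exponentiated (odds-ratio) counterpart.

* IVW: weighted regression through the origin; the default multiplicative
  random-effects model inflates the SE by sqrt(Q/(k-1)) when the Cochran Q
  exceeds its degrees of freedom, leaving the point estimate unchanged.
* MR-Egger: the same regression with a free intercept; the intercept absorbs
  directional pleiotropy and the slope is a pleiotropy-adjusted effect.
* Weighted median: the weighted 50th percentile of per-variant Wald ratios;
  consistent when at least half the weight comes from valid instruments; SE
  by parametric bootstrap.

A result is declared significant by the triangulation rule: IVW p below alpha
AND the weighted-median and Egger slopes pointing in the IVW direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, UndefinedRatioError
from .summary_stats import HarmonizedDataset

Z975 = stats.norm.ppf(0.975)


@dataclass
class MrEstimate:
    """A causal-effect estimate with normal/t-based uncertainty.

    ``beta`` is on the log-odds scale; ``or_value`` = exp(beta).
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    or_value: float
    or_low: float
    or_high: float
    pvalue: float
    n_snps: int

    @classmethod
    def from_beta_se(
        cls, method: str, beta: float, se: float, n_snps: int, df: int | None = None
    ) -> "MrEstimate":
        """Wrap a point estimate; normal inference, or t with ``df`` if given."""
        if df is not None:
            crit = stats.t.ppf(0.975, df)
            p = 2.0 * stats.t.sf(abs(beta) / se, df) if se > 0 else (1.0 if beta == 0 else 0.0)
        else:
            crit = Z975
            p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
        lo, hi = beta - crit * se, beta + crit * se
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        return cls(
            method, float(beta), float(se), float(lo), float(hi),
            float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi)),
            float(p), int(n_snps),
        )


@dataclass
class EggerFit:
    """MR-Egger slope plus the pleiotropy intercept test."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


@dataclass
class TriangulationVerdict:
    """Which of the three significance conditions held, and the overall call."""

    significant: bool
    ivw_significant: bool
    wm_direction_consistent: bool
    egger_direction_consistent: bool
    alpha: float


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MrEstimate:
    """Single-instrument causal estimate beta_y / beta_x with first-order SE."""
    if beta_x == 0:
        raise UndefinedRatioError("wald ratio undefined for beta_x = 0")
    beta = beta_y / beta_x
    se = abs(se_y / beta_x)
    return MrEstimate.from_beta_se("wald", beta, se, 1)


def _ivw_core(bx: np.ndarray, by: np.ndarray, se_y: np.ndarray):
    """Closed-form weighted slope through the origin and its fixed-effect SE."""
    w = 1.0 / se_y**2
    sxx = np.sum(w * bx * bx)
    beta = np.sum(w * bx * by) / sxx
    se_fixed = np.sqrt(1.0 / sxx)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return float(beta), float(se_fixed), q


def ivw(data: HarmonizedDataset, model: str = "multiplicative_random") -> MrEstimate:
    """Inverse-variance-weighted estimate.

    ``model``: 'fixed' uses the analytic SE; 'multiplicative_random' (default)
    inflates it by sqrt(Q/(k-1)) when the heterogeneity ratio exceeds 1.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = data.n_snps
    if k < 2:
        raise InsufficientInstrumentsError(
            f"IVW needs >= 2 instruments, got {k}; use wald_ratio"
        )
    bx, _, by, se_y = data.arrays()
    beta, se, q = _ivw_core(bx, by, se_y)
    method = "ivw_fixed"
    if model == "multiplicative_random":
        method = "ivw_mre"
        infl = np.sqrt(max(1.0, q / (k - 1)))
        se *= infl
    return MrEstimate.from_beta_se(method, beta, se, k)


def mr_egger(data: HarmonizedDataset) -> EggerFit:
    """Weighted regression with intercept after orienting exposure betas >= 0.

    Slope/intercept inference uses t with k-2 df; the SE carries multiplicative
    random-effects inflation when the residual variance exceeds 1.
    """
    k = data.n_snps
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {k}")
    bx, _, by, se_y = data.arrays()
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = 1.0 / se_y**2

    # weighted least squares, closed form for the 2-parameter fit
    sw, swx = np.sum(w), np.sum(w * bx)
    swxx, swy, swxy = np.sum(w * bx * bx), np.sum(w * by), np.sum(w * bx * by)
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    infl2 = max(1.0, sigma2)
    se_slope = np.sqrt(infl2 * sw / det)
    se_int = np.sqrt(infl2 * swxx / det)

    slope_est = MrEstimate.from_beta_se("egger_slope", slope, se_slope, k, df=k - 2)
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_int, k - 2))
    return EggerFit(slope_est, float(intercept), float(se_int), p_int)


def weighted_median_point(bx: np.ndarray, by: np.ndarray, se_y: np.ndarray) -> float:
    """Interpolated weighted median of Wald ratios, weights (bx/se_y)^2."""
    ratios = by / bx
    weights = (bx / se_y) ** 2
    weights = weights / weights.sum()
    order = np.argsort(ratios, kind="mergesort")
    r, w = ratios[order], weights[order]
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(
    data: HarmonizedDataset, n_boot: int = 1000, seed: int | None = None
) -> MrEstimate:
    """Weighted-median estimate; SE from a seeded parametric bootstrap.

    Each bootstrap draw resamples per-variant (bx, by) from normal
    distributions centred at the observed values with the reported SEs.
    """
    k = data.n_snps
    if k < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= 3 instruments, got {k}"
        )
    bx, se_x, by, se_y = data.arrays()
    point = weighted_median_point(bx, by, se_y)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, se_x, size=(n_boot, k))
    by_star = rng.normal(by, se_y, size=(n_boot, k))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = weighted_median_point(bx_star[i], by_star[i], se_y)
    se = float(np.std(boots, ddof=1))
    return MrEstimate.from_beta_se("weighted_median", point, se, k)


def triangulate(
    ivw_est: MrEstimate,
    wm_est: MrEstimate,
    egger_fit: EggerFit,
    alpha: float = 0.05,
) -> TriangulationVerdict:
    """Significance rule: IVW p < alpha and both other estimators agree in sign."""
    ivw_sig = ivw_est.pvalue < alpha
    wm_ok = np.sign(wm_est.beta) == np.sign(ivw_est.beta)
    egger_ok = np.sign(egger_fit.slope.beta) == np.sign(ivw_est.beta)
    return TriangulationVerdict(
        bool(ivw_sig and wm_ok and egger_ok), bool(ivw_sig), bool(wm_ok),
        bool(egger_ok), alpha,
    )
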