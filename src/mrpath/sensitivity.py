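"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q measures excess dispersion of per-variant causal estimates around
the fixed-effect IVW slope; the Egger intercept tests for directional
pleiotropy; MR-PRESSO detects global pleiotropy and individual outlier
variants by comparing observed leave-one-out residual sums of squares against
a parametric simulation under the no-pleiotropy model, re-running the global
test after outlier removal; leave-one-out re-estimates IVW with each variant
omitted in turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError
from .estimators import MrEstimate, EggerFit, ivw, _ivw_core
from .summary_stats import HarmonizedDataset


@dataclass
class PressoResult:
    global_rss: float
    global_pvalue: float
    outliers: list[str]
    outlier_pvalues: dict[str, float]
    rerun_pvalue: float | None = None
    corrected_estimate: MrEstimate | None = None


@dataclass
class PleiotropyVerdict:
    directional_pleiotropy: bool
    intercept: float
    intercept_pvalue: float
    alpha: float


@dataclass
class SensitivityReport:
    q_statistic: float
    q_df: int
    q_pvalue: float
    egger_intercept: float
    egger_intercept_pvalue: float
    presso: PressoResult | None = None
    loo_estimates: list[tuple[str, MrEstimate]] = field(default_factory=list)


def cochran_q(data: HarmonizedDataset) -> tuple[float, int, float]:
    """Q = sum w_j (by_j - beta_ivw bx_j)^2 at the fixed-effect IVW slope.

    df = k - 1; p from the chi-square upper tail. p > 0.05 is read as no
    significant heterogeneity.
    """
    k = data.n_snps
    if k < 2:
        raise InsufficientInstrumentsError(f"Cochran Q needs >= 2 instruments, got {k}")
    bx, _, by, se_y = data.arrays()
    _, _, q = _ivw_core(bx, by, se_y)
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return float(q), df, max(p, np.nextafter(0, 1))


def egger_intercept_test(fit: EggerFit, alpha: float = 0.05) -> PleiotropyVerdict:
    """Flag directional pleiotropy when the Egger intercept p-value < alpha."""
    return PleiotropyVerdict(
        bool(fit.intercept_pvalue < alpha), fit.intercept, fit.intercept_pvalue, alpha
    )


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, computed analytically.

    Broadcasts over leading dimensions, so simulated (n_sim, k) arrays get
    per-simulation leave-one-out slopes in one pass.
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    data: HarmonizedDataset,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global and outlier tests with post-removal re-test.

    The observed statistic is the weighted residual sum of squares of each
    variant against the IVW slope fitted without it. The null distribution
    simulates, ``n_sim`` times, exposure betas around their observed values
    and outcome betas around the leave-one-out predictions, recomputing the
    statistic each time. Empirical p-values use add-one smoothing so they are
    never exactly zero; per-variant outlier p-values are Bonferroni-adjusted
    across the k variants. When outliers are found they are removed, the
    global test re-run, and the post-removal IVW estimate returned.
    """
    k = data.n_snps
    if k < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments, got {k}")
    bx, se_x, by, se_y = data.arrays()
    w = 1.0 / se_y**2
    rng = np.random.default_rng(seed)

    beta_loo = _loo_slopes(bx, by, w)
    obs_res2 = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(obs_res2))

    bx_star = rng.normal(bx, se_x, size=(n_sim, k))
    by_star = rng.normal(beta_loo * bx, se_y, size=(n_sim, k))
    beta_loo_star = _loo_slopes(bx_star, by_star, w)
    sim_res2 = w * (by_star - beta_loo_star * bx_star) ** 2
    rss_sim = np.sum(sim_res2, axis=1)

    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))

    per_p = (np.sum(sim_res2 >= obs_res2, axis=0) + 1) / (n_sim + 1)
    adj = np.minimum(1.0, per_p * k)
    ids = data.rows["variant_id"].tolist()
    outlier_p = dict(zip(ids, adj.astype(float)))
    outliers = [v for v, p in outlier_p.items() if p < outlier_alpha]

    result = PressoResult(rss_obs, global_p, outliers, outlier_p)
    if outliers:
        reduced = data.drop_variants(outliers)
        if reduced.n_snps >= 4:
            rerun = mr_presso(
                reduced, n_sim=n_sim, seed=int(rng.integers(2**31)), outlier_alpha=0.0
            )
            result.rerun_pvalue = rerun.global_pvalue
        if reduced.n_snps >= 2:
            result.corrected_estimate = ivw(reduced)
    return result


def leave_one_out(data: HarmonizedDataset, model: str = "multiplicative_random"):
    """One IVW estimate per omitted variant, plus the all-variant estimate.

    Returns a list of (label, MrEstimate); the final entry is labelled "All"
    and carries the total effect.
    """
    k = data.n_snps
    if k < 3:
        raise InsufficientInstrumentsError(
            f"leave-one-out needs >= 3 instruments, got {k}"
        )
    results: list[tuple[str, MrEstimate]] = []
    for i, vid in enumerate(data.rows["variant_id"]):
        reduced = HarmonizedDataset(
            data.exposure_id,
            data.outcome_id,
            data.rows.drop(index=data.rows.index[i]).reset_index(drop=True),
            data.exclusions,
        )
        results.append((vid, ivw(reduced, model=model)))
    results.append(("All", ivw(data, model=model)))
    return results


def sensitivity_battery(
    data: HarmonizedDataset,
    egger_fit: EggerFit,
    n_sim: int = 1000,
    seed: int | None = None,
    run_presso: bool = True,
) -> SensitivityReport:
    """Full diagnostic suite for one harmonized exposure/outcome pair."""
    q, df, qp = cochran_q(data)
    report = SensitivityReport(q, df, qp, egger_fit.intercept, egger_fit.intercept_pvalue)
    if run_presso and data.n_snps >= 4:
        report.presso = mr_presso(data, n_sim=n_sim, seed=seed)
    if data.n_snps >= 3:
        report.loo_estimates = leave_one_out(data)
    return report
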