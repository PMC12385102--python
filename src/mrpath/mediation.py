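"""Two-step mediation MR with product-of-coefficients decomposition.

Step 1 screens candidate mediators: the exposure's instruments estimate the
exposure -> mediator effect (beta_XY) for each trait, retained when the
triangulation rule holds (no multiple-testing correction by design — this is
an exploratory screen; a Benjamini-Hochberg option exists but is off by
default). Step 2 estimates the mediator -> outcome effect conditional on the
exposure (beta_YZ) by multivariable MR. The indirect (mediating) effect is
beta_XY * beta_YZ; the mediated proportion is 100 * indirect / total. SEs use
the delta method, documented in the result metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientInstrumentsError, UndefinedProportionError
from .estimators import (
    MrEstimate,
    TriangulationVerdict,
    ivw,
    mr_egger,
    triangulate,
    weighted_median,
)
from .instruments import LdMatrix
from .mvmr import assemble_mv_dataset, mvmr_ivw
from .summary_stats import GwasTable, harmonize

logger = logging.getLogger(__name__)


@dataclass
class ScreenHit:
    """A mediator that passed the step-1 screen, with its beta_XY estimate."""

    mediator_id: str
    estimate: MrEstimate
    verdict: TriangulationVerdict
    n_snps: int


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition for one mediator.

    Invariants: ``indirect_effect == step1 * step2`` and
    ``mediated_proportion_pct == 100 * indirect / total`` exactly at the
    point-estimate level. ``ci_method`` records the uncertainty propagation
    used (delta method throughout).
    """

    mediator_id: str
    total_effect: float
    total_se: float
    step1_beta_xy: float
    step1_se: float
    step2_beta_yz: float
    step2_se: float
    indirect_effect: float
    indirect_se: float
    indirect_ci_low: float
    indirect_ci_high: float
    mediated_proportion_pct: float
    proportion_se_pct: float
    proportion_ci_low: float
    proportion_ci_high: float
    pvalue: float
    ci_method: str = "delta"


def screen_mediators(
    exposure: GwasTable,
    mediators: dict[str, GwasTable],
    instruments: list[str],
    alpha: float = 0.05,
    n_boot: int = 200,
    seed: int | None = None,
    rule: str = "triangulate",
    bh_correct: bool = False,
) -> list[ScreenHit]:
    """Step-1 screen of candidate mediators against the exposure instruments.

    For each mediator: harmonize the exposure instruments onto the mediator
    table, fit IVW + weighted median + MR-Egger, and keep the trait when the
    significance rule holds. ``rule`` is 'triangulate' (default: IVW p < alpha
    and direction-consistent weighted median and Egger) or 'ivw_only'.
    Mediators with fewer than 3 overlapping instruments are skipped and
    logged, not errors. ``bh_correct`` applies Benjamini-Hochberg to the IVW
    p-values before the rule (off by default).
    """
    rng = np.random.default_rng(seed)
    evaluated: list[tuple[str, MrEstimate, TriangulationVerdict]] = []
    skipped: list[str] = []
    for mid, table in mediators.items():
        data = harmonize(exposure, table, instruments)
        if data.n_snps < 3:
            skipped.append(mid)
            continue
        ivw_est = ivw(data)
        wm_est = weighted_median(data, n_boot=n_boot, seed=int(rng.integers(2**31)))
        egger_fit = mr_egger(data)
        verdict = triangulate(ivw_est, wm_est, egger_fit, alpha=alpha)
        evaluated.append((mid, ivw_est, verdict))
    if skipped:
        logger.info("screen_mediators: skipped %d mediators with <3 instruments", len(skipped))

    pvals = np.array([e.pvalue for _, e, _ in evaluated])
    if bh_correct and len(pvals):
        sig_mask = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        sig_mask = pvals < alpha

    hits = []
    for (mid, est, verdict), ivw_sig in zip(evaluated, sig_mask):
        passed = (
            bool(ivw_sig)
            and (rule == "ivw_only" or (verdict.wm_direction_consistent and verdict.egger_direction_consistent))
        )
        if passed:
            hits.append(ScreenHit(mid, est, verdict, est.n_snps))
    return hits


def mediator_to_outcome(
    mediator: GwasTable,
    exposure: GwasTable,
    outcome: GwasTable,
    ld: LdMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> MrEstimate:
    """Step-2 effect of the mediator on the outcome conditional on the exposure.

    Multivariable IVW over the jointly clumped instruments of (mediator,
    exposure); the mediator's coefficient is returned.
    """
    data = assemble_mv_dataset(
        [mediator, exposure], outcome, ld, p_threshold, r2_threshold, window_kb
    )
    result = mvmr_ivw(data)
    return result.estimates[mediator.trait_id]


def mediation_effect(
    total: tuple[float, float],
    step1: tuple[float, float],
    step2: tuple[float, float],
    mediator_id: str = "",
) -> MediationResult:
    """Product-of-coefficients mediation from three (estimate, SE) pairs.

    indirect = beta_XY * beta_YZ with delta-method SE
    sqrt(beta_YZ^2 SE_XY^2 + beta_XY^2 SE_YZ^2); two-sided normal p.
    mediated proportion (%) = 100 * indirect / total, with a delta-method CI
    treating the total as independent of the product.
    """
    t, se_t = total
    a, se_a = step1
    b, se_b = step2
    if t == 0:
        raise UndefinedProportionError("mediated proportion undefined for total = 0")
    indirect = a * b
    se_ind = float(np.sqrt(b**2 * se_a**2 + a**2 * se_b**2))
    if se_ind > 0:
        p = float(2.0 * stats.norm.sf(abs(indirect) / se_ind))
    else:
        p = 1.0 if indirect == 0 else float(np.nextafter(0, 1))
    z = stats.norm.ppf(0.975)

    prop = 100.0 * indirect / t
    # ratio delta method, product and total treated as independent
    se_prop = 100.0 * float(
        np.sqrt(se_ind**2 / t**2 + indirect**2 * se_t**2 / t**4)
    )
    return MediationResult(
        mediator_id=mediator_id,
        total_effect=t,
        total_se=se_t,
        step1_beta_xy=a,
        step1_se=se_a,
        step2_beta_yz=b,
        step2_se=se_b,
        indirect_effect=indirect,
        indirect_se=se_ind,
        indirect_ci_low=indirect - z * se_ind,
        indirect_ci_high=indirect + z * se_ind,
        mediated_proportion_pct=prop,
        proportion_se_pct=se_prop,
        proportion_ci_low=prop - z * se_prop,
        proportion_ci_high=prop + z * se_prop,
        pvalue=p,
    )
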