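"""Multivariable MR: direct effects of several exposures, jointly instrumented.

The exposure-association matrix of all jointly clumped instruments is
regressed against outcome associations (weights 1/se_outcome^2) without an
intercept (multivariable IVW) or with one (multivariable Egger, which absorbs
shared directional pleiotropy). Each coefficient is the direct effect of that
exposure conditional on the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, InsufficientInstrumentsError, NoInstrumentsError
from .estimators import MrEstimate
from .instruments import LdMatrix, ld_clump, select_significant
from .summary_stats import GwasTable, align_alleles

logger = logging.getLogger(__name__)


@dataclass
class MvDataset:
    """Joint instrument associations across m exposures and one outcome.

    ``beta_exposures`` / ``se_exposures`` have shape (k, m) aligned to
    ``exposure_ids``; ``provenance`` maps variant -> exposures it was
    genome-wide significant for.
    """

    exposure_ids: list[str]
    outcome_id: str
    variant_ids: list[str]
    beta_exposures: np.ndarray
    se_exposures: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.exposure_ids)

    @property
    def k(self) -> int:
        return len(self.variant_ids)


@dataclass
class MvmrResult:
    method: str
    estimates: dict[str, MrEstimate]
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None


def assemble_mv_dataset(
    exposures: list[GwasTable],
    outcome: GwasTable,
    ld: LdMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> MvDataset:
    """Union of per-exposure significant variants, jointly clumped by the
    minimum p-value across exposures, then extracted from every table and
    harmonized to the first exposure's effect alleles.

    Variants absent from any exposure or the outcome, or with unresolvable
    alleles, are dropped and logged.
    """
    if len(exposures) < 2:
        raise InsufficientInstrumentsError("multivariable MR needs >= 2 exposures")
    m = len(exposures)
    indexed = [e.indexed() for e in exposures]
    out_idx = outcome.indexed()

    # candidate pool: significant anywhere, keyed by min p across exposures
    provenance: dict[str, list[str]] = {}
    min_p: dict[str, float] = {}
    meta: dict[str, tuple] = {}
    for e, idx in zip(exposures, indexed):
        try:
            sig = select_significant(e, p_threshold)
        except NoInstrumentsError:
            # an exposure may contribute no instruments of its own as long as
            # the joint pool stays large enough
            logger.info("assemble_mv_dataset: no significant variants for %s", e.trait_id)
            continue
        for _, row in sig.records.iterrows():
            vid = row["variant_id"]
            provenance.setdefault(vid, []).append(e.trait_id)
            if row["pvalue"] < min_p.get(vid, np.inf):
                min_p[vid] = row["pvalue"]
                meta[vid] = (row["chromosome"], row["position"])

    pool = pd.DataFrame(
        {
            "variant_id": list(min_p),
            "chromosome": [meta[v][0] for v in min_p],
            "position": [meta[v][1] for v in min_p],
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": np.nan,
            "beta": np.nan,
            "se": 1.0,
            "pvalue": [min_p[v] for v in min_p],
            "n": np.nan,
        }
    )
    kept = ld_clump(GwasTable("mv_pool", pool), ld, r2_threshold, window_kb)

    rows = []
    dropped = []
    ref = indexed[0]
    for vid in kept:
        if any(vid not in idx.index for idx in indexed) or vid not in out_idx.index:
            dropped.append(vid)
            continue
        ea, oa = ref.loc[vid, "effect_allele"], ref.loc[vid, "other_allele"]
        betas, ses, ok = [], [], True
        for idx in indexed:
            r = idx.loc[vid]
            sign = align_alleles(ea, oa, r["effect_allele"], r["other_allele"])
            if sign is None:
                ok = False
                break
            betas.append(sign * r["beta"])
            ses.append(r["se"])
        if not ok:
            dropped.append(vid)
            continue
        r = out_idx.loc[vid]
        sign = align_alleles(ea, oa, r["effect_allele"], r["other_allele"])
        if sign is None:
            dropped.append(vid)
            continue
        rows.append((vid, betas, ses, sign * r["beta"], r["se"]))
    if dropped:
        logger.info("assemble_mv_dataset: dropped %d variants (%s...)", len(dropped), dropped[:5])

    if len(rows) < m + 2:
        raise InsufficientInstrumentsError(
            f"only {len(rows)} joint instruments for {m} exposures (need >= {m + 2})"
        )
    vids = [r[0] for r in rows]
    return MvDataset(
        [e.trait_id for e in exposures],
        outcome.trait_id,
        vids,
        np.array([r[1] for r in rows], dtype=float),
        np.array([r[2] for r in rows], dtype=float),
        np.array([r[3] for r in rows], dtype=float),
        np.array([r[4] for r in rows], dtype=float),
        {v: provenance.get(v, []) for v in vids},
    )


def _check_rank(X: np.ndarray, exposure_ids: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify exposures whose column is in the span of the others
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                bad.append(exposure_ids[min(j, len(exposure_ids) - 1)])
        raise CollinearityError(f"collinear exposure columns: {bad or exposure_ids}")


def _mv_wls(
    data: MvDataset, with_intercept: bool, orientation_exposure: int = 0
) -> tuple[MvmrResult, object]:
    m, k = data.m, data.k
    X = data.beta_exposures.copy()
    y = data.beta_outcome.copy()
    w = 1.0 / data.se_outcome**2

    if with_intercept:
        flip = np.where(X[:, orientation_exposure] < 0, -1.0, 1.0)
        X = X * flip[:, None]
        y = y * flip
        design = sm.add_constant(X)
        df_resid = k - m - 1
        method = "egger_mv"
    else:
        design = X
        df_resid = k - m
        method = "ivw_mv"
    if k < m + (2 if with_intercept else 1):
        raise InsufficientInstrumentsError(
            f"{method} needs >= {m + (2 if with_intercept else 1)} instruments, got {k}"
        )
    _check_rank(np.sqrt(w)[:, None] * design, data.exposure_ids)

    fit = sm.WLS(y, design, weights=w).fit()
    sigma2 = float(fit.scale)  # weighted residual variance
    infl = np.sqrt(max(1.0, sigma2))
    params = np.asarray(fit.params, dtype=float)
    # fixed-effect covariance (unit residual variance), then multiplicative inflation
    cov_fixed = np.linalg.inv(design.T @ (w[:, None] * design))
    bses = np.sqrt(np.diag(cov_fixed)) * infl

    offset = 1 if with_intercept else 0
    estimates = {}
    for j, eid in enumerate(data.exposure_ids):
        b, s = params[offset + j], bses[offset + j]
        df = df_resid if with_intercept else None
        estimates[eid] = MrEstimate.from_beta_se(method, b, s, k, df=df)
    result = MvmrResult(method, estimates)
    if with_intercept:
        result.intercept = float(params[0])
        result.intercept_se = float(bses[0])
        if bses[0] > 0:
            result.intercept_pvalue = float(
                2.0 * stats.t.sf(abs(params[0]) / bses[0], df_resid)
            )
        else:
            result.intercept_pvalue = 1.0 if params[0] == 0 else np.nextafter(0, 1)
    return result, fit


def mvmr_ivw(data: MvDataset) -> MvmrResult:
    """Multivariable IVW: no-intercept WLS of outcome betas on the exposure
    beta matrix; SEs carry multiplicative overdispersion inflation when the
    weighted residual variance exceeds 1; normal p-values."""
    result, _ = _mv_wls(data, with_intercept=False)
    return result


def mvmr_egger(data: MvDataset, orientation_exposure: int = 0) -> MvmrResult:
    """Multivariable Egger: intercept column added after orienting every row
    so the orientation exposure's beta is non-negative; t inference with
    k - m - 1 df; the intercept tests shared directional pleiotropy."""
    result, _ = _mv_wls(data, with_intercept=True, orientation_exposure=orientation_exposure)
    return result


def conditional_f_statistics(data: MvDataset) -> dict[str, float]:
    """Approximate conditional instrument strength per exposure.

    Regresses each exposure's betas (precision-weighted by its own SEs) on the
    other exposures' betas and reports the F of the residual signal. Reported
    as a diagnostic only.
    """
    out: dict[str, float] = {}
    k, m = data.k, data.m
    for j, eid in enumerate(data.exposure_ids):
        y = data.beta_exposures[:, j]
        X = np.delete(data.beta_exposures, j, axis=1)
        w = 1.0 / data.se_exposures[:, j] ** 2
        fit = sm.WLS(y, sm.add_constant(X), weights=w).fit()
        resid_ss = float(np.sum(w * fit.resid**2))
        out[eid] = resid_ss / max(k - m, 1)
    return out
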