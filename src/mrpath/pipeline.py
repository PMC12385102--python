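"""Three-step study orchestration: univariable MR, multivariable MR, mediation.

Each ``run_*_study`` function is deterministic given (inputs, config, seed)
and returns a report object that serializes to forest-plot-shaped TSVs plus a
JSON metadata block (config echo, seeds, exclusion tallies). Nothing is
dropped silently: every excluded variant or skipped mediator is tallied.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InsufficientInstrumentsError, MrPathError
from .estimators import (
    EggerFit,
    MrEstimate,
    TriangulationVerdict,
    ivw,
    mr_egger,
    triangulate,
    weighted_median,
)
from .instruments import LdMatrix, build_instrument_set, substitute_proxies
from .mediation import MediationResult, ScreenHit, mediation_effect, mediator_to_outcome, screen_mediators
from .mvmr import MvmrResult, assemble_mv_dataset, conditional_f_statistics, mvmr_egger, mvmr_ivw
from .sensitivity import SensitivityReport, sensitivity_battery
from .summary_stats import GwasTable, HarmonizedDataset, harmonize

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and seeds for a full study run; echoed into every report."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    window_kb: float = 10_000.0
    proxy_r2: float = 0.8
    palindrome_maf: float = 0.42
    alpha: float = 0.05
    n_boot: int = 1000
    n_presso_sim: int = 1000
    ivw_model: str = "multiplicative_random"
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 < self.p_threshold <= 1, "p_threshold in (0, 1]"),
            (0 <= self.clump_r2 <= 1, "clump_r2 in [0, 1]"),
            (self.window_kb > 0, "window_kb > 0"),
            (0 <= self.proxy_r2 <= 1, "proxy_r2 in [0, 1]"),
            (0 <= self.palindrome_maf <= 0.5, "palindrome_maf in [0, 0.5]"),
            (0 < self.alpha < 1, "alpha in (0, 1)"),
            (self.n_boot >= 2 and self.n_presso_sim >= 2, "simulation counts >= 2"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise MrPathError("invalid config: " + "; ".join(bad))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _estimate_row(label: str, est: MrEstimate, q_pvalue: float | None = None) -> dict:
    return {
        "method": label,
        "nsnp": est.n_snps,
        "beta": est.beta,
        "se": est.se,
        "or": est.or_value,
        "or_low": est.or_low,
        "or_high": est.or_high,
        "pvalue": est.pvalue,
        "q_pvalue": q_pvalue,
    }


@dataclass
class UvmrReport:
    exposure_id: str
    outcome_id: str
    harmonized: HarmonizedDataset
    ivw: MrEstimate
    weighted_median: MrEstimate
    egger: EggerFit
    verdict: TriangulationVerdict
    sensitivity: SensitivityReport
    instrument_diag: dict
    tallies: dict
    config: PipelineConfig

    def forest_table(self) -> pd.DataFrame:
        """Forest-plot table: one row per method with OR, CI, p, Q p-value."""
        qp = self.sensitivity.q_pvalue
        return pd.DataFrame(
            [
                _estimate_row("IVW", self.ivw, qp),
                _estimate_row("Weighted median", self.weighted_median),
                _estimate_row("MR-Egger", self.egger.slope),
            ]
        )

    def loo_table(self) -> pd.DataFrame:
        rows = [
            {"left_out": vid, "beta": est.beta, "se": est.se,
             "ci_low": est.ci_low, "ci_high": est.ci_high}
            for vid, est in self.sensitivity.loo_estimates
        ]
        return pd.DataFrame(rows)

    def metadata(self) -> dict:
        s = self.sensitivity
        return {
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "config": self.config.to_dict(),
            "instruments": self.instrument_diag,
            "tallies": self.tallies,
            "verdict": dataclasses.asdict(self.verdict),
            "sensitivity": {
                "q": s.q_statistic, "q_df": s.q_df, "q_pvalue": s.q_pvalue,
                "egger_intercept": s.egger_intercept,
                "egger_intercept_pvalue": s.egger_intercept_pvalue,
                "presso_global_pvalue": s.presso.global_pvalue if s.presso else None,
                "presso_outliers": s.presso.outliers if s.presso else None,
                "presso_rerun_pvalue": s.presso.rerun_pvalue if s.presso else None,
            },
        }

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.forest_table().to_csv(d / "uvmr_forest.tsv", sep="\t", index=False)
        self.loo_table().to_csv(d / "uvmr_leave_one_out.tsv", sep="\t", index=False)
        self.harmonized.write(d / "harmonized.tsv", d / "harmonized_exclusions.tsv")
        with open(d / "uvmr_metadata.json", "w") as fh:
            json.dump(self.metadata(), fh, indent=2, sort_keys=True, default=str)


def run_uvmr_study(
    exposure: GwasTable,
    outcome: GwasTable,
    ld: LdMatrix,
    config: PipelineConfig | None = None,
) -> UvmrReport:
    """Instrument selection -> harmonization -> estimators -> sensitivity."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)

    iset = build_instrument_set(
        exposure, ld, config.p_threshold, config.clump_r2, config.window_kb
    )
    usable, proxies, dropped = substitute_proxies(
        iset.variants, outcome, ld, config.proxy_r2
    )
    # a proxy is only usable if the exposure reports it too
    exp_ids = set(exposure.variant_ids())
    usable = [v for v in usable if v in exp_ids]

    data = harmonize(exposure, outcome, usable, config.palindrome_maf)
    if data.n_snps < 3:
        raise InsufficientInstrumentsError(
            f"UVMR needs >= 3 harmonized instruments, got {data.n_snps}"
        )
    ivw_est = ivw(data, model=config.ivw_model)
    wm_est = weighted_median(data, n_boot=config.n_boot, seed=int(rng.integers(2**31)))
    egger_fit = mr_egger(data)
    verdict = triangulate(ivw_est, wm_est, egger_fit, alpha=config.alpha)
    sens = sensitivity_battery(
        data, egger_fit, n_sim=config.n_presso_sim, seed=int(rng.integers(2**31))
    )
    tallies = {
        "instruments_selected": iset.k,
        "proxied": len(proxies),
        "dropped_no_proxy": len(dropped),
        "harmonized": data.n_snps,
        "exclusions": data.exclusions["reason"].value_counts().to_dict(),
    }
    diag = {
        "k": iset.k,
        "total_r2": iset.total_r2,
        "f_statistic": iset.f_statistic,
        "weak": bool(iset.weak) if np.isfinite(iset.f_statistic) else None,
        "proxies": {k: list(v) for k, v in proxies.items()},
    }
    return UvmrReport(
        exposure.trait_id, outcome.trait_id, data, ivw_est, wm_est, egger_fit,
        verdict, sens, diag, tallies, config,
    )


@dataclass
class MvmrReport:
    exposure_ids: list[str]
    outcome_id: str
    ivw: MvmrResult
    egger: MvmrResult
    conditional_f: dict
    n_snps: int
    config: PipelineConfig

    def table(self) -> pd.DataFrame:
        """Direct-effect table: per method x exposure, plus the Egger intercept row."""
        rows = []
        for label, res in (("Multivariable IVW", self.ivw), ("Multivariable MR-Egger", self.egger)):
            for eid in self.exposure_ids:
                rows.append({**_estimate_row(label, res.estimates[eid]), "exposure": eid})
        rows.append(
            {
                "method": "Intercept",
                "exposure": "-",
                "nsnp": self.n_snps,
                "beta": self.egger.intercept,
                "se": self.egger.intercept_se,
                "or": None, "or_low": None, "or_high": None,
                "pvalue": self.egger.intercept_pvalue,
                "q_pvalue": None,
            }
        )
        return pd.DataFrame(rows)

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.table().to_csv(d / "mvmr_table.tsv", sep="\t", index=False)
        with open(d / "mvmr_metadata.json", "w") as fh:
            json.dump(
                {
                    "exposures": self.exposure_ids,
                    "outcome": self.outcome_id,
                    "n_snps": self.n_snps,
                    "conditional_f": self.conditional_f,
                    "config": self.config.to_dict(),
                },
                fh, indent=2, sort_keys=True, default=str,
            )


def run_mvmr_study(
    exposures: list[GwasTable],
    outcome: GwasTable,
    ld: LdMatrix,
    config: PipelineConfig | None = None,
) -> MvmrReport:
    """Joint clumping and multivariable IVW + Egger over >= 2 exposures."""
    config = config or PipelineConfig()
    if len(exposures) < 2:
        raise InsufficientInstrumentsError(
            "multivariable MR needs >= 2 exposures; use run_uvmr_study for one"
        )
    data = assemble_mv_dataset(
        exposures, outcome, ld, config.p_threshold, config.clump_r2, config.window_kb
    )
    # orientation axis for multivariable Egger is chosen by trait ID, not list
    # position, so permuting the exposure list permutes labels only
    orientation = int(np.argmin(np.array(data.exposure_ids, dtype=object)))
    return MvmrReport(
        data.exposure_ids, data.outcome_id,
        mvmr_ivw(data), mvmr_egger(data, orientation_exposure=orientation),
        conditional_f_statistics(data), data.k, config,
    )


@dataclass
class MediationReport:
    exposure_id: str
    outcome_id: str
    total_effect: MrEstimate
    screen_hits: list[ScreenHit]
    step2_estimates: dict[str, MrEstimate]
    results: list[MediationResult]
    tallies: dict
    config: PipelineConfig

    def table(self) -> pd.DataFrame:
        """Decomposition table: total, step 1, step 2, mediated proportion, p."""
        rows = []
        for r in self.results:
            rows.append(
                {
                    "mediator": r.mediator_id,
                    "total_beta": r.total_effect, "total_se": r.total_se,
                    "step1_beta": r.step1_beta_xy, "step1_se": r.step1_se,
                    "step2_beta": r.step2_beta_yz, "step2_se": r.step2_se,
                    "indirect": r.indirect_effect,
                    "proportion_pct": r.mediated_proportion_pct,
                    "proportion_ci_low": r.proportion_ci_low,
                    "proportion_ci_high": r.proportion_ci_high,
                    "pvalue": r.pvalue,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "mediator", "total_beta", "total_se", "step1_beta", "step1_se",
                "step2_beta", "step2_se", "indirect", "proportion_pct",
                "proportion_ci_low", "proportion_ci_high", "pvalue",
            ],
        )

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.table().to_csv(d / "mediation_table.tsv", sep="\t", index=False)
        with open(d / "mediation_metadata.json", "w") as fh:
            json.dump(
                {
                    "exposure": self.exposure_id,
                    "outcome": self.outcome_id,
                    "tallies": self.tallies,
                    "screen_hits": [
                        {"mediator": h.mediator_id, "beta": h.estimate.beta,
                         "se": h.estimate.se, "pvalue": h.estimate.pvalue}
                        for h in self.screen_hits
                    ],
                    "config": self.config.to_dict(),
                    "ci_method": "delta",
                },
                fh, indent=2, sort_keys=True, default=str,
            )


def run_mediation_study(
    exposure: GwasTable,
    outcome: GwasTable,
    mediators: dict[str, GwasTable],
    ld: LdMatrix,
    config: PipelineConfig | None = None,
    total_effect: MrEstimate | None = None,
) -> MediationReport:
    """Two-step mediation: screen mediators, estimate conditional effects,
    decompose. A mediator contributes a decomposition row when its step-2
    coefficient is significant and the implied indirect effect shares the
    total effect's sign."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)

    if total_effect is None:
        total_effect = run_uvmr_study(exposure, outcome, ld, config).ivw

    iset = build_instrument_set(
        exposure, ld, config.p_threshold, config.clump_r2, config.window_kb
    )
    hits = screen_mediators(
        exposure, mediators, iset.variants,
        alpha=config.alpha, n_boot=max(100, config.n_boot // 5),
        seed=int(rng.integers(2**31)),
    )
    logger.info("mediation: %d/%d mediators passed screening", len(hits), len(mediators))

    step2: dict[str, MrEstimate] = {}
    results: list[MediationResult] = []
    step2_failed: list[str] = []
    for hit in hits:
        try:
            est = mediator_to_outcome(
                mediators[hit.mediator_id], exposure, outcome, ld,
                config.p_threshold, config.clump_r2, config.window_kb,
            )
        except MrPathError:
            step2_failed.append(hit.mediator_id)
            continue
        step2[hit.mediator_id] = est
        indirect_sign = np.sign(hit.estimate.beta * est.beta)
        if est.pvalue < config.alpha and indirect_sign == np.sign(total_effect.beta):
            results.append(
                mediation_effect(
                    (total_effect.beta, total_effect.se),
                    (hit.estimate.beta, hit.estimate.se),
                    (est.beta, est.se),
                    mediator_id=hit.mediator_id,
                )
            )
    if not results:
        logger.info("mediation: no mediator passed both steps")
    tallies = {
        "mediators_in": len(mediators),
        "screen_hits": len(hits),
        "step2_insufficient": len(step2_failed),
        "decomposed": len(results),
    }
    return MediationReport(
        exposure.trait_id, outcome.trait_id, total_effect, hits, step2,
        results, tallies, config,
    )
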