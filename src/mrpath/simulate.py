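"""Synthetic GWAS summary statistics with known causal structure.

The generator draws per-variant true exposure effects from a normal
distribution truncated to genome-wide detectability, adds optional
(directional or balanced) horizontal pleiotropy, links an outcome by a causal
slope, and observes everything through independent two-sample noise. A
mediation variant builds an exposure -> mediator -> outcome triangle whose
implied total effect equals direct + phi * psi by construction, plus a panel
of decoy mediators for screening calibration. Block LD matrices support
clumping and proxy tests.

Default effect scales follow the study the package models: a causal slope of
0.11 on the log-odds scale (odds ratio 1.12), 67 instruments, an
exposure -> mediator effect of -0.13 and conditional mediator -> outcome
effect of -0.09 (mediated proportion 10.64%). Summary statistics are
simulated directly — the log-odds scale is treated as linear, the standard
two-sample MR approximation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .instruments import LdMatrix
from .summary_stats import GWAS_COLUMNS, GwasTable, write_gwas_table

#: two-sided detectability threshold |z| for P < 5e-8
Z_GENOME_WIDE = float(stats.norm.isf(2.5e-8))

_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]


@dataclass
class SimTruth:
    """Generating parameters of a synthetic two-sample / mediation dataset.

    theta: true exposure -> outcome causal effect (log-OR per unit exposure).
    step1_phi / step2_psi: exposure -> mediator and conditional mediator ->
    outcome effects; direct_effect defaults to theta - phi * psi so the
    decomposition identity holds by construction.
    """

    theta: float = 0.11
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 0.0
    step1_phi: float = -0.13
    step2_psi: float = -0.09
    direct_effect: float | None = None
    n_snps: int = 67
    n_mediator_snps: int = 67
    se_x_scale: float = 0.01
    se_y_scale: float = 0.05
    se_m_scale: float = 0.03
    sigma_gamma: float = 0.15
    sigma_delta: float = 0.25
    n_exposure: int = 218_792
    n_outcome: int = 473_500
    n_decoys: int = 730
    n_nonnull_decoys: int = 0
    decoy_phi_range: tuple[float, float] = (0.08, 0.16)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direct_effect is None:
            self.direct_effect = self.theta - self.step1_phi * self.step2_psi
        self.validate()

    def validate(self) -> None:
        problems = []
        if self.n_snps < 2:
            problems.append("n_snps must be >= 2")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            problems.append("pleiotropy_fraction must lie in [0, 1]")
        if self.pleiotropy_sd < 0:
            problems.append("pleiotropy_sd must be >= 0")
        for name in ("se_x_scale", "se_y_scale", "se_m_scale", "sigma_gamma", "sigma_delta"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if abs(self.direct_effect + self.step1_phi * self.step2_psi - self.theta) > 1e-12:
            problems.append("theta must equal direct_effect + step1_phi * step2_psi")
        if problems:
            raise ConfigurationError("invalid SimTruth: " + "; ".join(problems))


@dataclass
class SimBundle:
    """A generated study: tables, LD, and the truth that produced them."""

    exposure: GwasTable
    outcome: GwasTable
    ld: LdMatrix
    truth: SimTruth
    mediators: dict[str, GwasTable] = field(default_factory=dict)
    mediator_phis: dict[str, float] = field(default_factory=dict)


def _truncated_effects(rng, n, sigma, threshold):
    """|effect| > threshold, effect ~ N(0, sigma^2) conditioned on detectability."""
    p_tail = stats.norm.sf(threshold / sigma)
    u = rng.uniform(size=n)
    mags = sigma * stats.norm.isf(u * p_tail)
    signs = rng.choice([-1.0, 1.0], size=n)
    return mags * signs


def _pleiotropy(rng, truth: SimTruth, n: int, orient: np.ndarray) -> np.ndarray:
    """Pleiotropic outcome offsets aligned to the instrument-raising allele.

    ``orient`` carries the sign of each variant's true instrument effect:
    a directional (nonzero-mean) pleiotropy is defined relative to the allele
    that raises the exposure, the convention under which the Egger intercept
    estimates the mean pleiotropic effect.
    """
    alpha = np.zeros(n)
    if truth.pleiotropy_fraction > 0:
        mask = rng.uniform(size=n) < truth.pleiotropy_fraction
        alpha[mask] = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, mask.sum())
    return alpha * orient


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def _make_table(trait_id, vids, chroms, positions, eas, oas, eafs, beta, se, n) -> GwasTable:
    df = pd.DataFrame(
        {
            "variant_id": vids,
            "chromosome": chroms,
            "position": positions,
            "effect_allele": eas,
            "other_allele": oas,
            "eaf": eafs,
            "beta": beta,
            "se": se,
            "pvalue": _wald_p(np.asarray(beta), np.asarray(se)),
            "n": n,
        }
    )
    return GwasTable(trait_id, df[GWAS_COLUMNS])


def _variant_frame(rng, n, prefix="rs", spacing_kb=20_000, start=1):
    """Shared variant metadata: IDs, coordinates far enough apart to be
    clump-independent, random non-palindromic alleles, uniform EAFs."""
    vids = [f"{prefix}{i}" for i in range(start, start + n)]
    positions = (np.arange(n) + start) * int(spacing_kb * 1000)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), n)]
    eas = [p[0] for p in pairs]
    oas = [p[1] for p in pairs]
    eafs = rng.uniform(0.05, 0.95, n)
    return vids, ["1"] * n, positions, eas, oas, eafs


def identity_ld(variant_ids, positions) -> LdMatrix:
    return LdMatrix(list(variant_ids), np.eye(len(variant_ids)), np.asarray(positions))


def simulate_two_sample(truth: SimTruth) -> SimBundle:
    """Exposure and outcome summary statistics from two non-overlapping samples.

    Per variant j: gamma_j ~ truncated-detectable N(0, sigma_gamma^2);
    pleiotropic offset alpha_j with probability pleiotropy_fraction;
    bx_j ~ N(gamma_j, se_x^2), by_j ~ N(theta * gamma_j + alpha_j, se_y^2).
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_snps
    vids, chroms, positions, eas, oas, eafs = _variant_frame(rng, n)

    se_x = truth.se_x_scale * rng.uniform(0.8, 1.2, n)
    se_y = truth.se_y_scale * rng.uniform(0.8, 1.2, n)
    gamma = _truncated_effects(rng, n, truth.sigma_gamma, Z_GENOME_WIDE * truth.se_x_scale)
    alpha = _pleiotropy(rng, truth, n, np.sign(gamma))

    bx = rng.normal(gamma, se_x)
    by = rng.normal(truth.theta * gamma + alpha, se_y)

    exposure = _make_table("sim_exposure", vids, chroms, positions, eas, oas, eafs, bx, se_x, truth.n_exposure)
    outcome = _make_table("sim_outcome", vids, chroms, positions, eas, oas, eafs, by, se_y, truth.n_outcome)
    return SimBundle(exposure, outcome, identity_ld(vids, positions), truth)


def simulate_mediation_triangle(truth: SimTruth) -> SimBundle:
    """Exposure -> mediator -> outcome triangle plus a decoy-mediator panel.

    Exposure instruments (gamma) act on the mediator with slope phi and on
    the outcome with slope theta = direct + phi * psi. The target mediator
    additionally has its own genome-wide-significant instruments (delta),
    which reach the outcome only through psi — these identify the conditional
    mediator -> outcome effect in multivariable MR. Decoy mediators (default
    730, of which ``n_nonnull_decoys`` get real effects drawn from
    ``decoy_phi_range``) share the exposure instruments.
    """
    rng = np.random.default_rng(truth.seed)
    n, nm = truth.n_snps, truth.n_mediator_snps
    total = n + nm
    vids, chroms, positions, eas, oas, eafs = _variant_frame(rng, total)

    se_x = truth.se_x_scale * rng.uniform(0.8, 1.2, total)
    se_y = truth.se_y_scale * rng.uniform(0.8, 1.2, total)
    se_m = truth.se_m_scale * rng.uniform(0.8, 1.2, total)

    gamma = np.zeros(total)
    gamma[:n] = _truncated_effects(rng, n, truth.sigma_gamma, Z_GENOME_WIDE * truth.se_x_scale)
    delta = np.zeros(total)
    delta[n:] = _truncated_effects(rng, nm, truth.sigma_delta, Z_GENOME_WIDE * truth.se_m_scale)
    alpha = _pleiotropy(rng, truth, total, np.sign(gamma + delta))

    true_m = truth.step1_phi * gamma + delta
    true_y = truth.direct_effect * gamma + truth.step2_psi * true_m + alpha
    # on exposure instruments this collapses to theta * gamma by the identity
    # theta = direct + phi * psi (asserted in SimTruth.validate)

    bx = rng.normal(gamma, se_x)
    by = rng.normal(true_y, se_y)
    bm = rng.normal(true_m, se_m)

    exposure = _make_table("sim_exposure", vids, chroms, positions, eas, oas, eafs, bx, se_x, truth.n_exposure)
    outcome = _make_table("sim_outcome", vids, chroms, positions, eas, oas, eafs, by, se_y, truth.n_outcome)
    mediators = {
        "mediator_target": _make_table(
            "mediator_target", vids, chroms, positions, eas, oas, eafs, bm, se_m, 3_757
        )
    }
    phis = {"mediator_target": truth.step1_phi}

    nonnull_phis = rng.uniform(*truth.decoy_phi_range, truth.n_decoys) * rng.choice(
        [-1.0, 1.0], truth.n_decoys
    )
    for d in range(truth.n_decoys):
        phi_d = float(nonnull_phis[d]) if d < truth.n_nonnull_decoys else 0.0
        se_d = truth.se_m_scale * rng.uniform(0.8, 1.2, total)
        bm_d = rng.normal(phi_d * gamma, se_d)
        did = f"decoy_{d + 1:03d}"
        mediators[did] = _make_table(did, vids, chroms, positions, eas, oas, eafs, bm_d, se_d, 3_757)
        phis[did] = phi_d

    return SimBundle(
        exposure, outcome, identity_ld(vids, positions), truth, mediators, phis
    )


def simulate_planted_outlier(
    seed: int, n_clean: int = 30, offset_se_multiple: float = 10.0, theta: float = 0.11
) -> tuple[SimBundle, str]:
    """A clean two-sample bundle plus one variant with a large pleiotropic
    offset (``offset_se_multiple`` times its outcome SE) for outlier tests."""
    truth = SimTruth(theta=theta, n_snps=n_clean + 1, seed=seed)
    bundle = simulate_two_sample(truth)
    rec = bundle.outcome.records
    vid = rec.loc[0, "variant_id"]
    rec.loc[0, "beta"] += offset_se_multiple * rec.loc[0, "se"]
    rec.loc[0, "pvalue"] = float(_wald_p(rec.loc[[0], "beta"].to_numpy(), rec.loc[[0], "se"].to_numpy())[0])
    return bundle, vid


def simulate_ld_blocks(
    n_blocks: int,
    block_size: int,
    intra_r2: float,
    positions_spacing_kb: float = 100.0,
    seed: int | None = None,
    prefix: str = "rs",
) -> LdMatrix:
    """Block-diagonal LD: r^2 = ``intra_r2`` within a block, 0 between blocks."""
    if not (0.0 <= intra_r2 <= 1.0):
        raise ConfigurationError("intra_r2 must lie in [0, 1]")
    k = n_blocks * block_size
    vids = [f"{prefix}{i + 1}" for i in range(k)]
    r2 = np.zeros((k, k))
    for b in range(n_blocks):
        lo, hi = b * block_size, (b + 1) * block_size
        r2[lo:hi, lo:hi] = intra_r2
    np.fill_diagonal(r2, 1.0)
    positions = np.arange(1, k + 1) * int(positions_spacing_kb * 1000)
    return LdMatrix(vids, r2, positions)


def simulate_mv_exposures(
    n_snps: int = 67,
    direct_effects: tuple[float, ...] = (0.0, 0.17, 0.0),
    rho: float = 0.5,
    se_x_scale: float = 0.01,
    se_y_scale: float = 0.05,
    sigma_gamma: float = 0.15,
    seed: int = 0,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
):
    """Correlated multi-exposure summary statistics for multivariable MR.

    Each variant is a detectable instrument for one exposure (round-robin)
    with correlated spill-over effects (correlation ``rho``) on the others;
    the outcome's true effect is the direct-effect combination of the
    exposure effects plus optional constant/noisy pleiotropy. Returns
    (list of exposure GwasTables, outcome GwasTable, LdMatrix, truth arrays).
    """
    rng = np.random.default_rng(seed)
    m = len(direct_effects)
    vids, chroms, positions, eas, oas, eafs = _variant_frame(rng, n_snps)

    # effect vectors are equicorrelated MVN across exposures (pairwise rho),
    # conditioned on detectability for the variant's primary exposure
    G = np.empty((n_snps, m))
    primary = np.arange(n_snps) % m
    base = _truncated_effects(rng, n_snps, sigma_gamma, Z_GENOME_WIDE * se_x_scale)
    cond_sd = sigma_gamma * np.sqrt(1.0 - rho**2)
    for j in range(n_snps):
        for i in range(m):
            if i == primary[j]:
                G[j, i] = base[j]
            else:
                G[j, i] = rho * base[j] + rng.normal(0.0, cond_sd)

    # pleiotropy aligned to the first exposure's raising allele (the same
    # orientation axis multivariable Egger uses)
    alpha = np.full(n_snps, pleiotropy_mean) + (
        rng.normal(0, pleiotropy_sd, n_snps) if pleiotropy_sd > 0 else 0.0
    )
    alpha = alpha * np.sign(G[:, 0])
    true_y = G @ np.asarray(direct_effects) + alpha

    se_x = se_x_scale * rng.uniform(0.8, 1.2, (n_snps, m))
    se_y = se_y_scale * rng.uniform(0.8, 1.2, n_snps)
    bx = rng.normal(G, se_x)
    by = rng.normal(true_y, se_y)

    exposures = [
        _make_table(f"sim_exposure_{i + 1}", vids, chroms, positions, eas, oas, eafs,
                    bx[:, i], se_x[:, i], 218_792)
        for i in range(m)
    ]
    outcome = _make_table("sim_outcome", vids, chroms, positions, eas, oas, eafs, by, se_y, 473_500)
    truth = {"direct_effects": list(direct_effects), "G": G, "alpha": alpha}
    return exposures, outcome, identity_ld(vids, positions), truth


def toy_harmonization_tables() -> tuple[GwasTable, GwasTable, dict[str, str]]:
    """Hand-built exposure/outcome pair exercising every harmonization branch.

    Returns (exposure, outcome, expected) where expected maps variant_id to
    'retained' or its exclusion reason.
    """
    exp = pd.DataFrame(
        [
            ("rs1", "1", 1_000_000, "A", "G", 0.30, 0.10, 0.02, 5.7e-07, 10_000),
            ("rs2", "1", 2_000_000, "A", "T", 0.50, 0.12, 0.02, 2.0e-09, 10_000),
            ("rs3", "1", 3_000_000, "A", "T", 0.10, 0.15, 0.03, 5.7e-07, 10_000),
            ("rs4", "1", 4_000_000, "A", "G", 0.40, 0.09, 0.02, 6.7e-06, 10_000),
            ("rs5", "1", 5_000_000, "C", "T", 0.25, 0.11, 0.02, 3.8e-08, 10_000),
            ("rs6", "1", 6_000_000, "C", "T", 0.60, 0.20, 0.04, 5.7e-07, 10_000),
            ("rs7", "1", 7_000_000, "A", "G", 0.35, 0.08, 0.02, 6.3e-05, 10_000),
        ],
        columns=GWAS_COLUMNS,
    )
    out = pd.DataFrame(
        [
            ("rs1", "1", 1_000_000, "G", "A", 0.70, -0.05, 0.01, 5.7e-07, 20_000),
            ("rs2", "1", 2_000_000, "A", "T", 0.50, 0.04, 0.01, 6.3e-05, 20_000),
            ("rs3", "1", 3_000_000, "A", "T", 0.12, 0.03, 0.01, 2.7e-03, 20_000),
            ("rs4", "1", 4_000_000, "A", "C", 0.40, 0.02, 0.01, 4.6e-02, 20_000),
            ("rs6", "1", 6_000_000, "C", "T", 0.58, 0.10, 0.01, 1.5e-23, 20_000),
            ("rs7", "1", 7_000_000, "T", "C", 0.64, 0.07, 0.01, 2.6e-12, 20_000),
        ],
        columns=GWAS_COLUMNS,
    )
    expected = {
        "rs1": "retained",  # swapped alleles: beta flips to +0.05
        "rs2": "palindromic_intermediate",  # A/T at MAF 0.50 > 0.42
        "rs3": "retained",  # palindromic but MAF 0.10, frequencies concordant
        "rs4": "allele_mismatch",
        "rs5": "missing_in_outcome",
        "rs6": "retained",  # as-is
        "rs7": "retained",  # strand complement of (A,G) is (T,C)
    }
    return GwasTable("toy_exposure", exp), GwasTable("toy_outcome", out), expected


def write_fixture_suite(directory) -> dict:
    """Write the canonical small fixtures as TSVs plus a JSON manifest.

    Deterministic and idempotent: re-running with the same seeds restores
    byte-identical files.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"fixtures": {}}

    exp, out, expected = toy_harmonization_tables()
    write_gwas_table(exp, d / "toy_exposure.tsv")
    write_gwas_table(out, d / "toy_outcome.tsv")
    manifest["fixtures"]["toy_harmonization"] = {
        "files": ["toy_exposure.tsv", "toy_outcome.tsv"],
        "expected": expected,
    }

    ld = simulate_ld_blocks(4, 5, 0.9, seed=11)
    ld.write(d / "ld_blocks_pairs.tsv", d / "ld_blocks_positions.tsv")
    rng = np.random.default_rng(11)
    pv = rng.uniform(1e-12, 1e-9, 20)
    cand = _make_table(
        "ld_block_candidates",
        ld.variant_ids, ["1"] * 20, ld.positions,
        ["A"] * 20, ["G"] * 20, rng.uniform(0.1, 0.9, 20),
        stats.norm.isf(pv / 2) * 0.02, np.full(20, 0.02), 100_000,
    )
    write_gwas_table(cand, d / "ld_block_candidates.tsv")
    manifest["fixtures"]["ld_blocks"] = {
        "files": ["ld_blocks_pairs.tsv", "ld_blocks_positions.tsv", "ld_block_candidates.tsv"],
        "n_blocks": 4, "block_size": 5, "intra_r2": 0.9, "seed": 11,
        "expected_clumped": 4,
    }

    tri_truth = SimTruth(seed=7, n_snps=12, n_mediator_snps=12, n_decoys=3)
    tri = simulate_mediation_triangle(tri_truth)
    write_gwas_table(tri.exposure, d / "triangle_exposure.tsv")
    write_gwas_table(tri.outcome, d / "triangle_outcome.tsv")
    write_gwas_table(tri.mediators["mediator_target"], d / "triangle_mediator.tsv")
    truth_dict = asdict(tri_truth)
    manifest["fixtures"]["mediation_triangle"] = {
        "files": ["triangle_exposure.tsv", "triangle_outcome.tsv", "triangle_mediator.tsv"],
        "truth": truth_dict,
    }

    outlier_bundle, outlier_id = simulate_planted_outlier(seed=13)
    write_gwas_table(outlier_bundle.exposure, d / "outlier_exposure.tsv")
    write_gwas_table(outlier_bundle.outcome, d / "outlier_outcome.tsv")
    manifest["fixtures"]["planted_outlier"] = {
        "files": ["outlier_exposure.tsv", "outlier_outcome.tsv"],
        "seed": 13, "outlier": outlier_id, "offset_se_multiple": 10.0,
    }

    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
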