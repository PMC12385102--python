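"""Instrument selection and strength diagnostics.

Instruments are genome-wide significant variants (P < 5e-8) pruned to mutual
linkage-equilibrium by greedy clumping (keep the smallest p-value, drop
everything correlated with it within a genomic window), optionally proxied
into the outcome when absent there, and screened for weak-instrument bias via
the variance explained R^2 = beta^2 / (beta^2 + n * se^2) and the F statistic
F = R^2 (n - k - 1) / (k (1 - R^2)); F < 10 flags a weak instrument set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateFrequencyError,
    InsufficientSampleError,
    NoInstrumentsError,
)
from .summary_stats import GwasTable

WEAK_INSTRUMENT_F = 10.0


@dataclass
class LdMatrix:
    """Squared-correlation matrix over an ordered set of variants.

    ``r2`` is symmetric with unit diagonal and entries in [0, 1];
    ``positions`` are base-pair coordinates aligned to ``variant_ids``.
    """

    variant_ids: list[str]
    r2: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ConfigurationError("r2 shape does not match variant_ids")
        if self.positions.shape != (k,):
            raise ConfigurationError("positions length does not match variant_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ConfigurationError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ConfigurationError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ConfigurationError("r2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index_of(self, variant_id: str) -> int:
        return self._index[variant_id]

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def read(cls, pairs_path, positions_path) -> "LdMatrix":
        """Build from a long-format pairs TSV (id_a, id_b, r2) and a positions
        TSV (variant_id, position). Unlisted pairs default to r2 = 0."""
        pos = pd.read_csv(positions_path, sep="\t")
        ids = pos["variant_id"].astype(str).tolist()
        idx = {v: i for i, v in enumerate(ids)}
        mat = np.eye(len(ids))
        pairs = pd.read_csv(pairs_path, sep="\t")
        for a, b, r in zip(pairs["id_a"], pairs["id_b"], pairs["r2"]):
            i, j = idx[str(a)], idx[str(b)]
            mat[i, j] = mat[j, i] = float(r)
        return cls(ids, mat, pos["position"].to_numpy(np.int64))

    def write(self, pairs_path, positions_path) -> None:
        recs = [
            (self.variant_ids[i], self.variant_ids[j], self.r2[i, j])
            for i in range(len(self.variant_ids))
            for j in range(i + 1, len(self.variant_ids))
            if self.r2[i, j] != 0.0
        ]
        pd.DataFrame(recs, columns=["id_a", "id_b", "r2"]).to_csv(
            pairs_path, sep="\t", index=False
        )
        pd.DataFrame(
            {"variant_id": self.variant_ids, "position": self.positions}
        ).to_csv(positions_path, sep="\t", index=False)


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure with strength diagnostics."""

    exposure_id: str
    variants: list[str]
    per_variant_r2: dict[str, float] = field(default_factory=dict)
    total_r2: float = float("nan")
    f_statistic: float = float("nan")
    proxies: dict[str, tuple[str, float]] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.variants)

    @property
    def weak(self) -> bool:
        return self.f_statistic < WEAK_INSTRUMENT_F


def select_significant(gwas: GwasTable, p_threshold: float = 5e-8) -> GwasTable:
    """Rows with p-value strictly below the genome-wide threshold, in input order."""
    keep = gwas.records["pvalue"] < p_threshold
    if not keep.any():
        raise NoInstrumentsError(
            f"no variant of {gwas.trait_id!r} reaches P < {p_threshold:g}"
        )
    return GwasTable(gwas.trait_id, gwas.records.loc[keep].reset_index(drop=True))


def ld_clump(
    candidates: GwasTable,
    ld: LdMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> list[str]:
    """Greedy clumping: keep the most significant variant, drop neighbours in LD.

    Candidates are sorted by ascending p-value (ties broken by variant_id) and
    consumed greedily; a remaining candidate is dropped when it sits on the
    same chromosome within ``window_kb`` kilobases of a kept variant and its
    r^2 with it is >= ``r2_threshold``. The result is order-independent and
    mutually independent under the thresholds.
    """
    recs = candidates.records
    missing = [v for v in recs["variant_id"] if v not in ld]
    if missing:
        raise ConfigurationError(f"candidates missing from LD matrix: {missing[:10]}")

    order = recs.sort_values(
        ["pvalue", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = window_kb * 1000.0
    chrom = dict(zip(order["variant_id"], order["chromosome"]))
    pos = {v: float(ld.positions[ld.index_of(v)]) for v in order["variant_id"]}

    kept: list[str] = []
    alive = order["variant_id"].tolist()
    while alive:
        top = alive.pop(0)
        kept.append(top)
        survivors = []
        for v in alive:
            same_chrom = chrom[v] == chrom[top]
            within = abs(pos[v] - pos[top]) <= window_bp
            if same_chrom and within and ld.r2_between(v, top) >= r2_threshold:
                continue
            survivors.append(v)
        alive = survivors
    return kept


def find_proxy(
    variant: str,
    outcome: GwasTable,
    ld: LdMatrix,
    min_r2: float = 0.8,
) -> tuple[str, float] | None:
    """Best available LD proxy (r^2 strictly > ``min_r2``) present in the outcome.

    Returns (proxy_id, r2) with maximal r2 (lexicographic tie-break), or None —
    in which case the caller drops the instrument.
    """
    if variant not in ld:
        raise ConfigurationError(f"variant {variant!r} not in LD matrix")
    present = set(outcome.variant_ids())
    i = ld.index_of(variant)
    best: tuple[float, str] | None = None
    for j, cand in enumerate(ld.variant_ids):
        if cand not in present:
            continue
        r2 = float(ld.r2[i, j])
        if r2 > min_r2:
            key = (-r2, cand)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[1], -best[0]


def variance_explained(beta: float, se: float, eaf: float, n: float) -> float:
    """Per-variant phenotypic variance explained.

    2·EAF·(1−EAF)·β² / (2·EAF·(1−EAF)·β² + 2·EAF·(1−EAF)·N·SE²), which the
    common 2·EAF·(1−EAF) factor reduces to β² / (β² + N·SE²).
    """
    if not (0 < eaf < 1):
        raise DegenerateFrequencyError(f"eaf={eaf} is degenerate")
    if se <= 0 or n < 1:
        raise ConfigurationError("se must be > 0 and n >= 1")
    var = 2.0 * eaf * (1.0 - eaf)
    return (var * beta**2) / (var * beta**2 + var * n * se**2)


def f_statistic(total_r2: float, n: float, k: int) -> float:
    """Instrument-strength F = R²·(N − k − 1) / (k·(1 − R²))."""
    if not (0 <= total_r2 < 1):
        raise ConfigurationError(f"total_r2={total_r2} outside [0, 1)")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if n <= k + 1:
        raise InsufficientSampleError(f"n={n} <= k+1={k + 1}")
    return total_r2 * (n - k - 1) / (k * (1.0 - total_r2))


def build_instrument_set(
    exposure: GwasTable,
    ld: LdMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> InstrumentSet:
    """Select, clump, and score instruments for one exposure."""
    sig = select_significant(exposure, p_threshold)
    kept = ld_clump(sig, ld, r2_threshold, window_kb)
    recs = sig.indexed().loc[kept]
    per_r2: dict[str, float] = {}
    for vid, row in recs.iterrows():
        eaf, n = row["eaf"], row["n"]
        if np.isfinite(eaf) and 0 < eaf < 1 and np.isfinite(n):
            per_r2[vid] = variance_explained(row["beta"], row["se"], eaf, n)
    total = float(sum(per_r2.values()))
    f = float("nan")
    n_med = recs["n"].median()
    if per_r2 and np.isfinite(n_med) and n_med > len(kept) + 1:
        f = f_statistic(total, float(n_med), len(kept))
    return InstrumentSet(exposure.trait_id, kept, per_r2, total, f)


def substitute_proxies(
    instruments: list[str],
    outcome: GwasTable,
    ld: LdMatrix,
    min_r2: float = 0.8,
) -> tuple[list[str], dict[str, tuple[str, float]], list[str]]:
    """Replace instruments absent from the outcome with their best LD proxy.

    Returns (usable instrument list, proxy map original -> (proxy, r2),
    dropped instruments with no adequate proxy).
    """
    present = set(outcome.variant_ids())
    usable: list[str] = []
    proxies: dict[str, tuple[str, float]] = {}
    dropped: list[str] = []
    for v in instruments:
        if v in present:
            usable.append(v)
            continue
        hit = find_proxy(v, outcome, ld, min_r2) if v in ld else None
        if hit is None:
            dropped.append(v)
        else:
            proxies[v] = hit
            usable.append(hit[0])
    return usable, proxies, dropped
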