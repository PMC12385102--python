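"""GWAS summary-statistic tables and exposure/outcome harmonization.

A :class:`GwasTable` holds one trait's per-variant association statistics
(effect sizes on the log-odds scale, signed to an explicit effect allele).
:func:`harmonize` aligns an outcome table onto the exposure's effect alleles so
that downstream estimators regress outcome betas on exposure betas that refer
to the same allele. Palindromic (A/T, C/G) variants whose strand cannot be
resolved — minor-allele frequency above the intermediate-frequency threshold —
are excluded rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

#: Standard internal field -> common export column name.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP",
    "chromosome": "CHR",
    "position": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

#: Fields that must be mappable for a table to be usable at all.
MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se")

GWAS_COLUMNS = list(DEFAULT_COLUMN_MAP)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Exclusion reasons recorded by harmonize()
PALINDROMIC_INTERMEDIATE = "palindromic_intermediate"
ALLELE_MISMATCH = "allele_mismatch"
MISSING_IN_OUTCOME = "missing_in_outcome"


@dataclass
class GwasTable:
    """Per-variant summary associations for one trait.

    ``records`` is a DataFrame with columns ``variant_id, chromosome, position,
    effect_allele, other_allele, eaf, beta, se, pvalue, n``; ``variant_id`` is
    unique. ``eaf`` and ``n`` may contain NaN.
    """

    trait_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GWAS_COLUMNS if c not in self.records.columns]
        if missing:
            raise ConfigurationError(
                f"GwasTable {self.trait_id!r} missing columns: {missing}"
            )
        if self.records["variant_id"].duplicated().any():
            dups = self.records.loc[
                self.records["variant_id"].duplicated(), "variant_id"
            ].tolist()
            raise ConfigurationError(
                f"duplicate variant_id in {self.trait_id!r}: {dups[:5]}"
            )
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def variant_ids(self) -> list[str]:
        return self.records["variant_id"].tolist()

    def indexed(self) -> pd.DataFrame:
        return self.records.set_index("variant_id", drop=False)


@dataclass
class HarmonizedDataset:
    """Exposure and outcome effects signed to shared effect alleles.

    ``rows`` columns: variant_id, beta_exposure, se_exposure, beta_outcome,
    se_outcome, eaf_exposure. ``exclusions`` columns: variant_id, reason.
    Every input instrument appears exactly once across rows/exclusions.
    """

    exposure_id: str
    outcome_id: str
    rows: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_snps(self) -> int:
        return len(self.rows)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) as float arrays."""
        r = self.rows
        return (
            r["beta_exposure"].to_numpy(float),
            r["se_exposure"].to_numpy(float),
            r["beta_outcome"].to_numpy(float),
            r["se_outcome"].to_numpy(float),
        )

    def drop_variants(self, variant_ids: list[str]) -> "HarmonizedDataset":
        keep = ~self.rows["variant_id"].isin(variant_ids)
        return HarmonizedDataset(
            self.exposure_id,
            self.outcome_id,
            self.rows.loc[keep].reset_index(drop=True),
            self.exclusions,
        )

    def write(self, path, exclusions_path=None) -> None:
        self.rows.to_csv(path, sep="\t", index=False)
        if exclusions_path is not None:
            self.exclusions.to_csv(exclusions_path, sep="\t", index=False)


def read_gwas_table(
    path,
    column_map: dict[str, str] | None = None,
    trait_id: str | None = None,
) -> GwasTable:
    """Read a delimited summary-statistics file into a :class:`GwasTable`.

    The file must be tab- or comma-separated with a header. ``column_map``
    maps standard field names to source column names (defaults to
    :data:`DEFAULT_COLUMN_MAP`). Rows whose beta or SE do not parse as finite
    numbers are dropped and the count logged.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=None, engine="python")
    for fld in MANDATORY_FIELDS:
        if cmap[fld] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {cmap[fld]!r} (field {fld!r}) not found in {path}"
            )
    out = pd.DataFrame()
    for fld, col in cmap.items():
        out[fld] = df[col] if col in df.columns else np.nan
    for fld in ("beta", "se", "eaf", "pvalue", "position", "n"):
        out[fld] = pd.to_numeric(out[fld], errors="coerce")
    for fld in ("variant_id", "chromosome", "effect_allele", "other_allele"):
        out[fld] = out[fld].astype(str)
    out["effect_allele"] = out["effect_allele"].str.upper()
    out["other_allele"] = out["other_allele"].str.upper()

    ok = (
        np.isfinite(out["beta"])
        & np.isfinite(out["se"])
        & (out["se"] > 0)
        & (out["effect_allele"] != out["other_allele"])
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_gwas_table(%s): dropped %d unparsable rows", path, n_dropped)
    out = out.loc[ok].reset_index(drop=True)
    if out.empty:
        raise EmptyInputError(f"no usable rows in {path}")
    return GwasTable(trait_id or str(path), out[GWAS_COLUMNS])


def write_gwas_table(table: GwasTable, path, column_map: dict[str, str] | None = None) -> None:
    """Write a table in the same dialect :func:`read_gwas_table` accepts (TSV)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = table.records.rename(columns=cmap)
    df.to_csv(path, sep="\t", index=False)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G}; indels are never palindromic."""
    a, b = str(effect_allele).upper(), str(other_allele).upper()
    if len(a) != 1 or len(b) != 1:
        return False
    return {a, b} in ({"A", "T"}, {"C", "G"})


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[c] for c in allele)
    except KeyError:
        return None


def align_alleles(
    exp_ea: str, exp_oa: str, out_ea: str, out_oa: str
) -> int | None:
    """Orientation of an outcome record relative to exposure alleles.

    Returns +1 (same effect allele), -1 (effect/other swapped: negate the
    outcome beta and flip its EAF), or None when no orientation matches even
    after strand-complementing the outcome alleles.
    """
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return 1
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return -1
    cea, coa = _complement(out_ea), _complement(out_oa)
    if cea is None or coa is None:
        return None
    if (cea, coa) == (exp_ea, exp_oa):
        return 1
    if (cea, coa) == (exp_oa, exp_ea):
        return -1
    return None


def harmonize(
    exposure: GwasTable,
    outcome: GwasTable,
    instruments: list[str] | None = None,
    palindrome_maf_threshold: float = 0.42,
) -> HarmonizedDataset:
    """Align outcome effects to the exposure's effect alleles.

    For each instrument: a matching outcome orientation keeps the beta as-is;
    a swapped orientation negates the outcome beta; strand-complement matches
    are accepted for non-palindromic variants. Palindromic variants with
    exposure minor-allele frequency above ``palindrome_maf_threshold`` (or
    with missing frequency) are excluded as ``palindromic_intermediate``;
    retained palindromic variants are additionally frequency-aligned when the
    outcome reports an EAF. Instruments absent from the outcome are excluded
    as ``missing_in_outcome`` (proxy lookup happens upstream).

    The exposure EAF is authoritative for the palindrome decision; variants
    are matched by ID only.
    """
    exp = exposure.indexed()
    if instruments is None:
        instruments = exposure.variant_ids()
    unknown = [v for v in instruments if v not in exp.index]
    if unknown:
        raise ConfigurationError(
            f"instruments not in exposure table {exposure.trait_id!r}: {unknown[:5]}"
        )
    out = outcome.indexed()

    rows, excl = [], []
    for vid in instruments:
        e = exp.loc[vid]
        if vid not in out.index:
            excl.append((vid, MISSING_IN_OUTCOME))
            continue
        o = out.loc[vid]
        palindromic = is_palindromic(e["effect_allele"], e["other_allele"])
        if palindromic:
            eaf = e["eaf"]
            if not np.isfinite(eaf) or min(eaf, 1.0 - eaf) > palindrome_maf_threshold:
                excl.append((vid, PALINDROMIC_INTERMEDIATE))
                continue
        sign = align_alleles(
            e["effect_allele"], e["other_allele"], o["effect_allele"], o["other_allele"]
        )
        if sign is None:
            excl.append((vid, ALLELE_MISMATCH))
            continue
        beta_out = sign * o["beta"]
        if palindromic and np.isfinite(o["eaf"]):
            # strand is unresolvable from alleles; align by which allele is minor
            out_eaf = o["eaf"] if sign == 1 else 1.0 - o["eaf"]
            if (e["eaf"] < 0.5) != (out_eaf < 0.5):
                beta_out = -beta_out
        rows.append(
            (vid, e["beta"], e["se"], beta_out, o["se"], e["eaf"])
        )

    rows_df = pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "beta_exposure",
            "se_exposure",
            "beta_outcome",
            "se_outcome",
            "eaf_exposure",
        ],
    )
    excl_df = pd.DataFrame(excl, columns=["variant_id", "reason"])
    if len(excl_df):
        logger.info(
            "harmonize(%s -> %s): %d retained, %d excluded (%s)",
            exposure.trait_id,
            outcome.trait_id,
            len(rows_df),
            len(excl_df),
            excl_df["reason"].value_counts().to_dict(),
        )
    return HarmonizedDataset(exposure.trait_id, outcome.trait_id, rows_df, excl_df)
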