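import numpy as np
import pandas as pd
import pytest

from mrpath.summary_stats import GWAS_COLUMNS, GwasTable, HarmonizedDataset


def make_dataset(bx, by, se_y, se_x=None, exposure_id="exp", outcome_id="out"):
    """HarmonizedDataset straight from effect arrays (tests bypass harmonize)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    se_y = np.asarray(se_y, float)
    se_x = np.full_like(bx, 0.01) if se_x is None else np.asarray(se_x, float)
    rows = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(len(bx))],
            "beta_exposure": bx,
            "se_exposure": se_x,
            "beta_outcome": by,
            "se_outcome": se_y,
            "eaf_exposure": 0.3,
        }
    )
    return HarmonizedDataset(exposure_id, outcome_id, rows)


def make_gwas_table(trait_id, variant_ids, beta, se, pvalue=None, eaf=0.3,
                    ea="A", oa="G", chrom="1", positions=None, n=10_000):
    k = len(variant_ids)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if pvalue is None:
        from scipy import stats
        pvalue = 2 * stats.norm.sf(np.abs(beta) / se)
    df = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chromosome": chrom,
            "position": positions if positions is not None else np.arange(1, k + 1) * 10**6,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": pvalue,
            "n": n,
        }
    )
    return GwasTable(trait_id, df[GWAS_COLUMNS])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
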