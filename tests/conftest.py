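"""Shared builders for small hand-constructed MR fixtures."""

import numpy as np
import pandas as pd
import pytest

from netmr.gwas_io import HarmonizedSet, SummaryTable
from netmr.instruments import LDMatrix


def make_table(snp_ids, beta, se, pval=None, chrom=None, pos=None,
               ea=None, oa=None, eaf=None, n=None, label="trait",
               trait_type="quantitative") -> SummaryTable:
    """Build a SummaryTable from plain sequences with sensible defaults."""
    j = len(snp_ids)
    from scipy import stats
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if pval is None:
        pval = 2 * stats.norm.sf(np.abs(beta / se))
    df = pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": chrom if chrom is not None else ["1"] * j,
        "pos": pos if pos is not None else np.arange(j) * 1_000_000 + 1,
        "effect_allele": ea if ea is not None else ["A"] * j,
        "other_allele": oa if oa is not None else ["G"] * j,
        "eaf": eaf if eaf is not None else [0.3] * j,
        "beta": beta, "se": se, "pval": pval,
        "n": n if n is not None else [10_000] * j,
    })
    return SummaryTable(df, label, trait_type)


def make_hset(beta_exp, se_exp, beta_out, se_out, snp_ids=None) -> HarmonizedSet:
    j = len(beta_exp)
    ids = snp_ids or [f"rs{i}" for i in range(j)]
    return HarmonizedSet(ids, beta_exp, se_exp, beta_out, se_out)


def identity_ld(table: SummaryTable) -> LDMatrix:
    df = table.df
    return LDMatrix(df["snp_id"].tolist(), np.eye(len(df)),
                    df["pos"].to_numpy(), df["chrom"].to_numpy(dtype=object))


@pytest.fixture
def ten_snp_hset() -> HarmonizedSet:
    """A fixed 10-SNP harmonized set used by the oracle-equivalence tests."""
    rng = np.random.default_rng(42)
    bx = rng.normal(0.2, 0.05, 10)
    sx = np.full(10, 0.02)
    by = 0.3 * bx + rng.normal(0, 0.01, 10)
    sy = rng.uniform(0.01, 0.03, 10)
    return make_hset(bx, sx, by, sy)
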