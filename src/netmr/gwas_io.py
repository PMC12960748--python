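"""Reading, validation and harmonization of GWAS summary statistics.

A summary-statistics table holds one genome-wide association per SNP:
identifier, genomic location, the effect and other allele, the effect-allele
frequency (EAF), the per-allele effect estimate (log-odds units for binary
traits, trait-SD units otherwise), its standard error, p-value and study
sample size.  Two-sample Mendelian randomization needs the exposure and
outcome effects expressed for the *same* effect allele at every shared SNP;
:func:`harmonize` performs that alignment, resolving strand flips by allele
complementation and palindromic (A/T, C/G) variants by allele-frequency
concordance.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs whose strand cannot be resolved from the labels alone
PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

#: canonical column names; the first six are mandatory
CANONICAL_COLUMNS = (
    "snp_id", "effect_allele", "other_allele", "beta", "se", "pval",
    "chrom", "pos", "eaf", "n",
)
MANDATORY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")

TRAIT_TYPES = ("binary", "quantitative")


class ColumnMappingError(ValueError):
    """A mandatory summary-statistics column is missing from the file."""


class EmptyInputError(ValueError):
    """The input file or the exposure/outcome overlap contains no usable rows."""


class EmptyOverlapError(EmptyInputError):
    """No SNP survived harmonization; no MR analysis is possible."""


@dataclass
class SummaryTable:
    """A validated GWAS summary-statistics table for one trait.

    ``df`` carries the canonical columns of :data:`CANONICAL_COLUMNS`; optional
    fields (``chrom``, ``pos``, ``eaf``, ``n``) are present but may hold NaN.
    ``snp_id`` values are unique.
    """

    df: pd.DataFrame
    trait_label: str
    trait_type: str = "quantitative"

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}")
        if self.df["snp_id"].duplicated().any():
            dup = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id in table {self.trait_label!r}: {dup!r}")

    @property
    def n_snp(self) -> int:
        return len(self.df)

    def restrict(self, snp_ids) -> "SummaryTable":
        """Return a copy restricted to ``snp_ids``, preserving table order."""
        keep = self.df["snp_id"].isin(set(snp_ids))
        return SummaryTable(self.df.loc[keep].reset_index(drop=True),
                            self.trait_label, self.trait_type)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a shared effect-allele convention."""

    snp_ids: list
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    n_dropped_palindromic: int = 0
    n_dropped_incompatible: int = 0
    exposure_label: str = ""
    outcome_label: str = ""

    def __post_init__(self) -> None:
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.snp_ids)
        if n < 1:
            raise EmptyOverlapError("harmonized set is empty")
        for name in ("beta_exp", "se_exp", "beta_out", "se_out"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match snp_ids")
        if not (self.se_exp > 0).all() or not (self.se_out > 0).all():
            raise ValueError("standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def drop(self, snp_id: str) -> "HarmonizedSet":
        """Return a copy without ``snp_id`` (used by leave-one-out)."""
        keep = [i for i, s in enumerate(self.snp_ids) if s != snp_id]
        return self.subset(keep)

    def subset(self, idx) -> "HarmonizedSet":
        idx = list(idx)
        return HarmonizedSet(
            [self.snp_ids[i] for i in idx],
            self.beta_exp[idx], self.se_exp[idx],
            self.beta_out[idx], self.se_out[idx],
            self.n_dropped_palindromic, self.n_dropped_incompatible,
            self.exposure_label, self.outcome_label,
        )


def _validate_rows(df: pd.DataFrame, label: str) -> pd.DataFrame:
    """Drop rows that violate the per-record invariants, logging counts."""
    n0 = len(df)
    ok = pd.Series(True, index=df.index)
    ok &= df["effect_allele"].isin(VALID_ALLELES)
    ok &= df["other_allele"].isin(VALID_ALLELES)
    ok &= df["effect_allele"] != df["other_allele"]
    ok &= df["se"] > 0
    ok &= df["beta"].notna() & np.isfinite(df["beta"])
    # p = 0 is clamped below, not dropped
    ok &= df["pval"].notna() & (df["pval"] >= 0) & (df["pval"] <= 1)
    if "eaf" in df:
        ok &= df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))
    dropped = n0 - int(ok.sum())
    if dropped:
        logger.info("%s: dropped %d of %d rows violating record invariants", label, dropped, n0)
    df = df.loc[ok].copy()
    df["pval"] = df["pval"].astype(float)
    n_zero_p = int((df["pval"] == 0).sum())
    if n_zero_p:
        logger.info("%s: clamped %d zero p-values to float tiny", label, n_zero_p)
        df.loc[df["pval"] == 0, "pval"] = sys.float_info.min
    return df


def read_sumstats(path, column_map=None, trait_label: str = "",
                  trait_type: str = "quantitative") -> SummaryTable:
    """Read a delimited (TSV/CSV, optionally gzipped) summary-statistics file.

    ``column_map`` maps canonical names (``snp_id``, ``effect_allele``,
    ``other_allele``, ``beta``, ``se``, ``pval``, and optionally ``chrom``,
    ``pos``, ``eaf``, ``n``) to the header names used in the file.  Canonical
    headers need no mapping.  Rows violating the record invariants (bad
    alleles, non-positive SE, p outside [0, 1]) are dropped and counted in a
    log message; alleles are upper-cased; zero p-values are clamped to the
    smallest positive float.
    """
    import csv

    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        raise EmptyInputError(f"{path}: file is empty or unparseable") from None
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")

    column_map = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
    df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ColumnMappingError(
            f"{path}: missing mandatory column(s) {missing}; supply a column_map")

    for c in CANONICAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[list(CANONICAL_COLUMNS)]
    df["snp_id"] = df["snp_id"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["chrom"] = df["chrom"].astype(str)
    for c in ("beta", "se", "pval", "eaf"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = _validate_rows(df, trait_label or path.name)
    if df.empty:
        raise EmptyInputError(f"{path}: no rows survived validation")
    return SummaryTable(df.reset_index(drop=True), trait_label or path.stem, trait_type)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in PALINDROMIC_PAIRS


def _complement_pair(a1: str, a2: str) -> tuple[str, str]:
    return COMPLEMENT[a1], COMPLEMENT[a2]


def harmonize(exposure: SummaryTable, outcome: SummaryTable,
              palindrome_eaf_window: float = 0.08) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect-allele convention.

    For each SNP shared by both tables (matching on ``snp_id``):

    * same allele pair, same orientation — kept as-is;
    * same pair, swapped orientation — outcome beta sign-flipped and its EAF
      replaced by 1 − EAF;
    * strand flip — outcome alleles complemented first, then as above;
    * palindromic pair (A/T or C/G) — strand cannot be resolved from allele
      labels; kept only when both EAFs are present, both lie outside
      ``0.5 ± palindrome_eaf_window``, and both fall on the same side of 0.5
      (concordant), otherwise dropped and counted;
    * irreconcilable allele sets — dropped and counted.

    Output preserves exposure-table SNP order.  Raises
    :class:`EmptyOverlapError` when nothing survives.
    """
    if not (0 <= palindrome_eaf_window < 0.5):
        raise ValueError("palindrome_eaf_window must be in [0, 0.5)")
    out_idx = outcome.df.set_index("snp_id")
    lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window

    snp_ids, bx, sx, by, sy = [], [], [], [], []
    n_pal = n_inc = 0
    for row in exposure.df.itertuples(index=False):
        if row.snp_id not in out_idx.index:
            continue
        o = out_idx.loc[row.snp_id]
        e_ea, e_oa = row.effect_allele, row.other_allele
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        beta_out, eaf_out = float(o["beta"]), o["eaf"]

        if _is_palindromic(e_ea, e_oa):
            if {o_ea, o_oa} != {e_ea, e_oa}:
                n_inc += 1
                continue
            eaf_exp = row.eaf
            if (pd.isna(eaf_exp) or pd.isna(eaf_out)
                    or lo <= eaf_exp <= hi or lo <= eaf_out <= hi
                    or (eaf_exp < 0.5) != (eaf_out < 0.5)):
                n_pal += 1
                continue
            # concordant frequencies: same strand and orientation assumed
        else:
            if {o_ea, o_oa} != {e_ea, e_oa}:
                o_ea, o_oa = _complement_pair(o_ea, o_oa)
            if (o_ea, o_oa) == (e_ea, e_oa):
                pass
            elif (o_ea, o_oa) == (e_oa, e_ea):
                beta_out = -beta_out
                if not pd.isna(eaf_out):
                    eaf_out = 1.0 - eaf_out
            else:
                n_inc += 1
                continue

        snp_ids.append(row.snp_id)
        bx.append(float(row.beta))
        sx.append(float(row.se))
        by.append(beta_out)
        sy.append(float(o["se"]))

    if not snp_ids:
        raise EmptyOverlapError(
            f"no SNP shared by {exposure.trait_label!r} and {outcome.trait_label!r} "
            "survived harmonization; MR is not possible")
    return HarmonizedSet(snp_ids, bx, sx, by, sy, n_pal, n_inc,
                         exposure.trait_label, outcome.trait_label)


def write_harmonized(hset: HarmonizedSet, path) -> None:
    """Write a harmonized set as TSV (snp_id, beta_exp, se_exp, beta_out, se_out).

    Uses full float precision so a read-back reproduces the numeric fields
    bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "snp_id": hset.snp_ids,
        "beta_exp": hset.beta_exp, "se_exp": hset.se_exp,
        "beta_out": hset.beta_out, "se_out": hset.se_out,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_harmonized(path) -> HarmonizedSet:
    """Read back a file written by :func:`write_harmonized`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return HarmonizedSet(df["snp_id"].astype(str).tolist(),
                         df["beta_exp"].to_numpy(), df["se_exp"].to_numpy(),
                         df["beta_out"].to_numpy(), df["se_out"].to_numpy())
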