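"""Instrumental-variable selection for two-sample MR.

Instruments are SNPs robustly associated with the exposure.  Selection
composes three rules, in this fixed order:

1. genome-wide suggestive significance, ``pval < p_threshold`` (default 1e-5);
2. greedy LD clumping — repeatedly take the remaining SNP with the lowest
   p-value as an index SNP and discard every other remaining SNP on the same
   chromosome within ``window_kb`` whose r² with the index is at or above
   ``r2_threshold`` (defaults 0.001 and 10,000 kb);
3. weak-instrument filtering by the single-SNP Wald F statistic,
   ``F = (beta/se)² > f_min`` (default 10).

All inequalities are strict on the retained side.  The LD matrix is a
required input; real analyses derive it from a reference panel, tests use
the synthetic generator's block-diagonal matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas_io import SummaryTable

logger = logging.getLogger(__name__)


class NoInstrumentsError(ValueError):
    """No SNP survived instrument selection; the exposure is untestable."""


class LDLookupError(KeyError):
    """A summary-table SNP is absent from the LD matrix."""


@dataclass
class LDMatrix:
    """Pairwise r² between SNPs, with their genomic coordinates."""

    snp_ids: list
    r2: np.ndarray
    pos: np.ndarray
    chrom: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 matrix must have unit diagonal")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise LDLookupError(f"SNP {snp_id!r} absent from the LD matrix") from None


@dataclass
class InstrumentSet:
    """Selected instruments with their F statistics and a decision log."""

    records: SummaryTable
    f_stats: np.ndarray
    selection_log: list = field(default_factory=list)

    @property
    def snp_ids(self) -> list:
        return self.records.df["snp_id"].tolist()

    @property
    def n_snp(self) -> int:
        return self.records.n_snp


def threshold_filter(table: SummaryTable, p_threshold: float = 1e-5) -> SummaryTable:
    """Keep rows with ``pval < p_threshold`` (strict), preserving order."""
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    kept = table.df.loc[table.df["pval"] < p_threshold].reset_index(drop=True)
    if kept.empty:
        logger.info("%s: no SNP below p < %g", table.trait_label, p_threshold)
    return SummaryTable(kept, table.trait_label, table.trait_type)


def f_statistic(beta: float, se: float) -> float:
    """Single-SNP instrument-strength F, the squared Wald statistic (beta/se)²."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def clump(table: SummaryTable, ld: LDMatrix, r2_threshold: float = 0.001,
          window_kb: int = 10_000, selection_log: list | None = None) -> SummaryTable:
    """Greedy LD clumping keeping the lowest-p SNP of each LD neighbourhood.

    p-value ties are broken by (chrom, pos, snp_id) lexicographic order so the
    result is independent of input row order.  Distance is measured from the
    index SNP: a SNP is in the window when ``|pos − pos_index| ≤ window_kb·1000``.
    """
    df = table.df
    idx_in_ld = [ld.index_of(s) for s in df["snp_id"]]  # raises on missing SNP
    pos = ld.pos[idx_in_ld]
    chrom = ld.chrom[idx_in_ld]
    order = sorted(
        range(len(df)),
        key=lambda i: (df["pval"].iat[i], str(chrom[i]), int(pos[i]), df["snp_id"].iat[i]),
    )
    unclaimed = set(range(len(df)))
    kept_rows: list[int] = []
    for i in order:
        if i not in unclaimed:
            continue
        unclaimed.discard(i)
        kept_rows.append(i)
        index_snp = df["snp_id"].iat[i]
        for j in list(unclaimed):
            if (chrom[j] == chrom[i]
                    and abs(int(pos[j]) - int(pos[i])) <= window_kb * 1000
                    and ld.r2[idx_in_ld[i], idx_in_ld[j]] >= r2_threshold):
                unclaimed.discard(j)
                if selection_log is not None:
                    selection_log.append(
                        (df["snp_id"].iat[j], "clump_removed",
                         f"r2 >= {r2_threshold} with index {index_snp} within {window_kb} kb"))
        if selection_log is not None:
            selection_log.append((index_snp, "clump_index", "lowest p in its neighbourhood"))
    kept = df.iloc[kept_rows].reset_index(drop=True)
    return SummaryTable(kept, table.trait_label, table.trait_type)


@dataclass
class SelectionConfig:
    """Thresholds for instrument selection."""

    p_threshold: float = 1e-5
    r2_threshold: float = 0.001
    window_kb: int = 10_000
    f_min: float = 10.0


def select_instruments(table: SummaryTable, ld: LDMatrix,
                       config: SelectionConfig | None = None) -> InstrumentSet:
    """Compose threshold → clump → F filter; log every decision.

    Raises :class:`NoInstrumentsError` when nothing survives, so a screening
    driver can record the exposure as untestable and move on.
    """
    cfg = config or SelectionConfig()
    log: list = []

    sig = threshold_filter(table, cfg.p_threshold)
    for s in set(table.df["snp_id"]) - set(sig.df["snp_id"]):
        log.append((s, "threshold_removed", f"pval >= {cfg.p_threshold}"))
    if sig.n_snp == 0:
        raise NoInstrumentsError(
            f"{table.trait_label!r}: no SNP passes p < {cfg.p_threshold}")

    clumped = clump(sig, ld, cfg.r2_threshold, cfg.window_kb, selection_log=log)

    f = (clumped.df["beta"] / clumped.df["se"]) ** 2
    strong = f > cfg.f_min
    for s, fv in zip(clumped.df.loc[~strong, "snp_id"], f[~strong]):
        log.append((s, "f_removed", f"F = {fv:.3g} <= {cfg.f_min}"))
    kept = SummaryTable(clumped.df.loc[strong].reset_index(drop=True),
                        table.trait_label, table.trait_type)
    if kept.n_snp == 0:
        raise NoInstrumentsError(
            f"{table.trait_label!r}: no SNP passes F > {cfg.f_min}")
    for s in kept.df["snp_id"]:
        log.append((s, "retained", "passed threshold, clump and F filter"))
    return InstrumentSet(kept, f[strong].to_numpy(), log)


def write_ld(ld: LDMatrix, path) -> None:
    """Write the r² matrix as TSV with SNP ids as first row and column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_ld(path, table: SummaryTable) -> LDMatrix:
    """Read an r² TSV; positions and chromosomes are taken from ``table``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    snp_ids = [str(s) for s in df.index]
    meta = table.df.set_index("snp_id")
    pos = np.array([int(meta.loc[s, "pos"]) if s in meta.index else -1 for s in snp_ids])
    chrom = np.array([str(meta.loc[s, "chrom"]) if s in meta.index else "NA"
                      for s in snp_ids], dtype=object)
    return LDMatrix(snp_ids, df.to_numpy(dtype=float), pos, chrom)
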