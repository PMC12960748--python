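"""Multivariable Mendelian randomization (MVMR).

MVMR regresses outcome effects jointly on several exposures' effects at a
pooled instrument set, estimating each exposure's *direct* effect on the
outcome conditional on the others — the adjusted models behind statements
like "the association remained after adjusting for exposure B".

Instrument pooling: instruments are selected per exposure, unioned, and the
union is clumped once jointly (index p-value = the minimum across exposures)
so the final set is approximately independent.  The regression is weighted
least squares of ``beta_out`` on the exposure-beta matrix with weights
``1/se_out²`` and *no intercept*; per-exposure SEs carry the same
multiplicative overdispersion scale as MR-Egger, ``max(1, √(RSS_w/(J−K)))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import gwas_io
from .gwas_io import SummaryTable
from .instruments import LDMatrix, SelectionConfig, clump, select_instruments
from .mr_core import InsufficientInstrumentsError  # shared error taxonomy


class CollinearExposuresError(np.linalg.LinAlgError):
    """The exposure design matrix is rank deficient."""


@dataclass
class MVMRResult:
    exposures: list
    betas: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    n_snp: int
    conditional_f: np.ndarray | None = None

    def coef(self, exposure: str) -> tuple[float, float, float]:
        """(beta, se, pval) for one exposure by label."""
        i = self.exposures.index(exposure)
        return float(self.betas[i]), float(self.ses[i]), float(self.pvals[i])


def _wls_no_intercept(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                      labels: list) -> tuple[np.ndarray, np.ndarray, int]:
    """Weighted LS of y on x (no intercept) with overdispersion-scaled SEs."""
    j, k = x.shape
    if j <= k:
        raise InsufficientInstrumentsError(
            f"MVMR needs more SNPs ({j}) than exposures ({k})")
    xtwx = x.T @ (w[:, None] * x)
    # an exposure with no instrument signal (all-zero column) contributes a
    # zero row/column; pin its coefficient to 0 rather than failing
    live = np.sqrt(np.diag(xtwx)) > 1e-12 * max(1.0, np.sqrt(np.abs(xtwx)).max())
    sub = xtwx[np.ix_(live, live)]
    if np.linalg.matrix_rank(sub) < int(live.sum()):
        # name the most collinear pair for the error message
        c = np.corrcoef(x[:, live], rowvar=False)
        np.fill_diagonal(c, 0.0)
        i, m = np.unravel_index(np.nanargmax(np.abs(c)), c.shape)
        lab = [labels[t] for t in np.flatnonzero(live)]
        raise CollinearExposuresError(
            f"collinear exposures: {lab[i]!r} and {lab[m]!r} "
            f"(|r| = {abs(c[i, m]):.3f}); design is rank deficient")
    beta = np.zeros(k)
    beta[live] = np.linalg.solve(sub, (x.T @ (w * y))[live])
    resid = y - x @ beta
    rss_w = float(np.sum(w * resid ** 2))
    scale = max(1.0, np.sqrt(rss_w / (j - k)))
    ses = np.full(k, np.inf)
    ses[live] = np.sqrt(np.diag(np.linalg.inv(sub))) * scale
    return beta, ses, j - k


def _conditional_f(x: np.ndarray, se_x: np.ndarray) -> np.ndarray:
    """Heuristic conditional instrument strength per exposure.

    For exposure k, its betas are regressed on the other exposures' betas
    (ordinary LS); the conditional F is the mean squared residual in units of
    that exposure's squared SE — the multi-exposure analogue of the mean
    single-SNP F, describing the instrument signal not explained by the other
    exposures.  Values below 10 indicate conditionally weak instruments.
    """
    j, k = x.shape
    out = np.empty(k)
    for m in range(k):
        others = np.delete(x, m, axis=1)
        coef, *_ = np.linalg.lstsq(others, x[:, m], rcond=None)
        resid = x[:, m] - others @ coef
        out[m] = float(np.mean(resid ** 2 / se_x[:, m] ** 2))
    return out


def mvmr_estimate(exposure_tables: list, outcome: SummaryTable, ld: LDMatrix,
                  config: SelectionConfig | None = None) -> MVMRResult:
    """Joint direct-effect estimation for ≥ 2 exposures on one outcome.

    Raises :class:`CollinearExposuresError` for a rank-deficient design (for
    example the same exposure entered twice).
    """
    if len(exposure_tables) < 2:
        raise ValueError("MVMR needs at least 2 exposures")
    cfg = config or SelectionConfig()
    labels = [t.trait_label for t in exposure_tables]

    # union of per-exposure instruments, then one joint clump on the union
    union_ids: list = []
    for t in exposure_tables:
        for s in select_instruments(t, ld, cfg).snp_ids:
            if s not in union_ids:
                union_ids.append(s)
    min_p: dict = {}
    rows = {}
    for t in exposure_tables:
        sub = t.df[t.df["snp_id"].isin(union_ids)]
        for r in sub.itertuples(index=False):
            if r.snp_id not in min_p or r.pval < min_p[r.snp_id]:
                min_p[r.snp_id] = r.pval
                rows[r.snp_id] = r
    pool_df = pd.DataFrame([rows[s] for s in union_ids if s in rows])
    pool_df["pval"] = [min_p[s] for s in pool_df["snp_id"]]
    pooled = clump(SummaryTable(pool_df.reset_index(drop=True), "mvmr_pool"),
                   ld, cfg.r2_threshold, cfg.window_kb)

    # harmonize every table to the pooled reference allele convention
    ref = pooled
    h_out = gwas_io.harmonize(ref, outcome)
    keep = [s for s in ref.df["snp_id"] if s in h_out.snp_ids]
    h_exps = []
    for t in exposure_tables:
        h = gwas_io.harmonize(ref, t)
        keep = [s for s in keep if s in h.snp_ids]
        h_exps.append(h)

    idx_out = [h_out.snp_ids.index(s) for s in keep]
    y = h_out.beta_out[idx_out]
    w = 1.0 / h_out.se_out[idx_out] ** 2
    x = np.column_stack([h.beta_out[[h.snp_ids.index(s) for s in keep]] for h in h_exps])
    se_x = np.column_stack([h.se_out[[h.snp_ids.index(s) for s in keep]] for h in h_exps])

    beta, ses, df = _wls_no_intercept(x, y, w, labels)
    pvals = 2 * stats.norm.sf(np.abs(beta / ses))
    cond_f = _conditional_f(x, se_x) if x.shape[1] >= 2 else None
    return MVMRResult(labels, beta, ses, pvals, len(keep), cond_f)


def mvmr_from_effects(x: np.ndarray, y: np.ndarray, se_out: np.ndarray,
                      labels: list) -> MVMRResult:
    """MVMR on pre-harmonized effect matrices (J SNPs × K exposures)."""
    w = 1.0 / np.asarray(se_out, float) ** 2
    beta, ses, _ = _wls_no_intercept(np.asarray(x, float), np.asarray(y, float), w, labels)
    pvals = 2 * stats.norm.sf(np.abs(beta / ses))
    return MVMRResult(list(labels), beta, ses, pvals, len(y))
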