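"""Heterogeneity, pleiotropy and outlier diagnostics for an MR analysis.

Cochran's Q measures dispersion of the per-SNP Wald ratios around the pooled
IVW estimate; under homogeneous valid instruments it is chi-square with
J − 1 degrees of freedom.  The Egger intercept tests for directional
pleiotropy.  MR-PRESSO is a simulation-based residual-sum-of-squares test
with per-SNP outlier detection and a distortion assessment of how much the
flagged outliers move the IVW estimate.  Leave-one-out re-estimates IVW
dropping each SNP in turn to expose single-SNP leverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gwas_io import HarmonizedSet
from .mr_core import (DEFAULT_SEED, InsufficientInstrumentsError,
                      _egger_wls, _ratios_weights, ivw)


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    pval: float


@dataclass
class PleiotropyResult:
    intercept: float
    se: float
    pval: float


@dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_snps: list           # (snp_id, bonferroni-adjusted p)
    distortion_pval: float | None
    beta_outlier_corrected: float | None
    n_sim: int
    seed: int


@dataclass
class LeaveOneOutResult:
    rows: list                   # (excluded_snp_id, beta, se, pval)


def cochran_q(hset: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q with first-order IVW weights; p from the chi-square upper tail."""
    if hset.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs ≥ 2 SNPs")
    r, w = _ratios_weights(hset)
    beta_fe = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta_fe) ** 2))
    df = hset.n_snp - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))


def heterogeneity_pval(q: float, df: int) -> float:
    """Upper-tail chi-square probability of a printed (Q, df) pair."""
    return float(stats.chi2.sf(q, df))


def egger_intercept_test(hset: HarmonizedSet) -> PleiotropyResult:
    """Directional-pleiotropy test: Egger intercept with two-sided t p (df = J − 2)."""
    _, _, intercept, se_i, df = _egger_wls(hset)
    pval = float(2 * stats.t.sf(abs(intercept / se_i), df))
    return PleiotropyResult(intercept, se_i, pval)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for regression of by on bx with weights w.

    Slope form: β = Σ w·bx·by / Σ w·bx² (no intercept), identical to the IVW
    ratio form with weights (bx/se_out)².  Vectorized: element j is the slope
    with SNP j removed.
    """
    num = np.sum(w * bx * by) - w * bx * by
    den = np.sum(w * bx * bx) - w * bx * bx
    return num / den


def _rss_contributions(bx: np.ndarray, by: np.ndarray, so: np.ndarray) -> np.ndarray:
    """Per-SNP contribution (by_j − β̂_{−j}·bx_j)²/so_j² to the PRESSO RSS."""
    w = 1.0 / so ** 2
    slopes = _loo_slopes(bx, by, w)
    return (by - slopes * bx) ** 2 / so ** 2


def mr_presso(hset: HarmonizedSet, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int | None = None) -> PressoResult:
    """MR-PRESSO global heterogeneity test, outlier search and distortion test.

    *Global*: the observed residual sum of squares (each SNP's residual taken
    against the leave-one-out IVW slope) is compared against ``n_sim``
    parametric simulations drawing ``beta_out_j ~ N(β̂_{−j}·beta_exp_j, se_out_j)``
    and ``beta_exp_j ~ N(beta_exp_j, se_exp_j)``; the p-value uses the add-one
    estimator ``(1 + #{RSS_sim ≥ RSS_obs})/(n_sim + 1)``.

    *Outliers*: per-SNP p from the simulated distribution of that SNP's
    residual contribution, Bonferroni-adjusted over J; only searched when the
    global test is significant at ``outlier_alpha``.

    *Distortion*: the shift in the IVW estimate after removing the flagged
    outliers is compared with the shifts from removing equally many SNPs at
    random (``n_sim`` re-draws, two-sided).
    """
    j = hset.n_snp
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs ≥ 4 SNPs, got {j}")
    seed = DEFAULT_SEED if seed is None else seed
    rng = np.random.default_rng(seed)
    bx, by = hset.beta_exp, hset.beta_out
    sx, so = hset.se_exp, hset.se_out
    w = 1.0 / so ** 2

    obs_contrib = _rss_contributions(bx, by, so)
    global_rss = float(obs_contrib.sum())

    # parametric simulations under the no-pleiotropy model
    exp_by = _loo_slopes(bx, by, w) * bx
    sim_bx = rng.normal(bx, sx, size=(n_sim, j))
    sim_by = rng.normal(exp_by, so, size=(n_sim, j))
    sim_num = (w * sim_bx * sim_by).sum(axis=1, keepdims=True) - w * sim_bx * sim_by
    sim_den = (w * sim_bx ** 2).sum(axis=1, keepdims=True) - w * sim_bx ** 2
    sim_contrib = (sim_by - (sim_num / sim_den) * sim_bx) ** 2 / so ** 2
    sim_rss = sim_contrib.sum(axis=1)

    global_pval = float((1 + np.sum(sim_rss >= global_rss)) / (n_sim + 1))

    outliers: list = []
    distortion_pval = None
    beta_corrected = None
    if global_pval < outlier_alpha:
        per_snp_p = (1 + np.sum(sim_contrib >= obs_contrib, axis=0)) / (n_sim + 1)
        adj = np.minimum(per_snp_p * j, 1.0)
        flagged = np.flatnonzero(adj < outlier_alpha)
        outliers = [(hset.snp_ids[i], float(adj[i])) for i in flagged]
        if len(flagged) and len(flagged) < j:
            keep = np.setdiff1d(np.arange(j), flagged)
            beta_all = ivw(hset, mode="fixed").beta
            beta_corrected = ivw(hset.subset(keep), mode="fixed").beta
            d_obs = beta_corrected - beta_all
            d_null = np.empty(n_sim)
            for k in range(n_sim):
                drop = rng.choice(j, size=len(flagged), replace=False)
                d_null[k] = ivw(hset.subset(np.setdiff1d(np.arange(j), drop)),
                                mode="fixed").beta - beta_all
            distortion_pval = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))
    return PressoResult(global_rss, global_pval, outliers, distortion_pval,
                        beta_corrected, n_sim, seed)


def leave_one_out(hset: HarmonizedSet, mode: str = "multiplicative_random") -> LeaveOneOutResult:
    """IVW re-estimated with each SNP excluded in turn (same mode as the primary fit)."""
    if hset.n_snp < 2:
        raise InsufficientInstrumentsError("leave-one-out needs ≥ 2 SNPs")
    rows = []
    for i, snp in enumerate(hset.snp_ids):
        est = ivw(hset.subset([k for k in range(hset.n_snp) if k != i]), mode=mode)
        rows.append((snp, est.beta, est.se, est.pval))
    return LeaveOneOutResult(rows)
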