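"""Univariable two-sample Mendelian randomization estimators.

Every estimator consumes a :class:`~netmr.gwas_io.HarmonizedSet` of per-SNP
exposure effects ``beta_exp`` (SE ``se_exp``) and outcome effects ``beta_out``
(SE ``se_out``) on a shared effect-allele convention, and returns an
:class:`MREstimate` on the log-odds (binary outcome) or trait-SD scale;
odds ratios are derived by exponentiation, never estimated directly.

Estimators
----------
wald_ratio
    Single-SNP causal estimate ``beta_out / beta_exp`` with first-order SE.
ivw
    Inverse-variance-weighted meta-analysis of the per-SNP Wald ratios with
    first-order weights ``w_j = (beta_exp_j / se_out_j)²``.  Fixed-effect SE is
    ``(Σw)^(-1/2)``; the multiplicative-random-effects model inflates it by
    ``max(1, √(Q/(J−1)))`` and is the conservative default under heterogeneity.
egger
    Weighted regression of (sign-oriented) outcome effects on |exposure
    effects| *with* an intercept; a nonzero intercept signals directional
    pleiotropy and the slope is the pleiotropy-adjusted causal estimate.
    Inference is t-based with J − 2 degrees of freedom.
weighted_median / simple_median
    Median of the ratio estimates under inverse-variance (or equal) weights;
    consistent when SNPs carrying ≥ 50% of the weight are valid instruments.
    SEs come from a seeded parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gwas_io import HarmonizedSet, SummaryTable
from .instruments import LDMatrix, SelectionConfig, select_instruments
from . import gwas_io

#: normal quantile used for all 95% Wald intervals
Z95 = 1.96
DEFAULT_SEED = 20240910


class UndefinedRatioError(ZeroDivisionError):
    """A Wald ratio with a zero exposure effect is undefined."""


class InsufficientInstrumentsError(ValueError):
    """Too few SNPs for the requested estimator."""


@dataclass
class MREstimate:
    """A causal-effect estimate with Wald 95% CI and odds-ratio view."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    df: int | None = None
    direction: str = "forward"

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high))

    def as_dict(self) -> dict:
        return {
            "method": self.method, "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "or": self.or_, "or_ci_low": self.or_ci_low, "or_ci_high": self.or_ci_high,
            "pval": self.pval, "n_snp": self.n_snp, "direction": self.direction,
        }


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp with first-order SE se_out/|beta_exp|."""
    if beta_exp == 0:
        raise UndefinedRatioError("Wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate("wald_ratio", beta, se, _norm_p(beta / se), n_snp=1)


def _ratios_weights(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    if np.any(hset.beta_exp == 0):
        bad = hset.snp_ids[int(np.argmax(hset.beta_exp == 0))]
        raise UndefinedRatioError(f"beta_exp = 0 for SNP {bad!r}; ratio undefined")
    ratios = hset.beta_out / hset.beta_exp
    weights = (hset.beta_exp / hset.se_out) ** 2
    return ratios, weights


def ivw_beta(hset: HarmonizedSet) -> float:
    """The IVW point estimate alone (weighted mean of Wald ratios)."""
    r, w = _ratios_weights(hset)
    return float(np.sum(w * r) / np.sum(w))


def ivw(hset: HarmonizedSet, mode: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate over the per-SNP Wald ratios.

    ``mode="fixed"`` uses the fixed-effect SE; ``"multiplicative_random"``
    (default) multiplies it by ``max(1, √(Q/(J−1)))`` where Q is Cochran's
    heterogeneity statistic — identical to fixed when J = 1 or Q ≤ J − 1.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    r, w = _ratios_weights(hset)
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    label = "ivw_fe"
    if mode == "multiplicative_random":
        label = "ivw_mre"
        if hset.n_snp >= 2:
            q = float(np.sum(w * (r - beta) ** 2))
            se *= max(1.0, np.sqrt(q / (hset.n_snp - 1)))
    return MREstimate(label, beta, se, _norm_p(beta / se), n_snp=hset.n_snp)


def _egger_wls(hset: HarmonizedSet) -> tuple[float, float, float, float, int]:
    """Weighted least squares for MR-Egger; returns (slope, se_s, intercept, se_i, df).

    Orientation: each SNP's outcome effect is multiplied by sign(beta_exp) and
    the regressor is |beta_exp|, so the fit is invariant to arbitrary allele
    coding.  SEs carry a multiplicative overdispersion scale
    ``max(1, √(RSS_w/(J−2)))``.
    """
    j = hset.n_snp
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs ≥ 3 SNPs, got {j}")
    sgn = np.sign(hset.beta_exp)
    x = np.abs(hset.beta_exp)
    y = hset.beta_out * sgn
    w = 1.0 / hset.se_out ** 2
    # weighted normal equations for y = a + b x
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx ** 2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = y - intercept - slope * x
    rss_w = float((w * resid ** 2).sum())
    scale = max(1.0, np.sqrt(rss_w / (j - 2)))
    se_slope = np.sqrt(sw / det) * scale
    se_int = np.sqrt(swxx / det) * scale
    return float(slope), float(se_slope), float(intercept), float(se_int), j - 2


def egger(hset: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression; returns (slope estimate, intercept estimate).

    The slope is the causal effect adjusted for directional pleiotropy; the
    intercept estimates the mean pleiotropic effect.  Two-sided t p-values
    with df = J − 2.
    """
    slope, se_s, intercept, se_i, df = _egger_wls(hset)
    p_slope = float(2 * stats.t.sf(abs(slope / se_s), df))
    p_int = float(2 * stats.t.sf(abs(intercept / se_i), df))
    return (MREstimate("egger_slope", slope, se_s, p_slope, hset.n_snp, df=df),
            MREstimate("egger_intercept", intercept, se_i, p_int, hset.n_snp, df=df))


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ``ratios`` under ``weights``.

    With sorted ratios β_(1) ≤ … ≤ β_(J) and normalized weights w_(j), the
    cumulative position s_j = Σ_{k≤j} w_(k) − w_(j)/2 is the centre of mass of
    each step; the estimate interpolates linearly between the bracketing β
    values where s crosses 1/2.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5, side="right")) - 1  # s[k] < 0.5 <= s[k+1]
    frac = (0.5 - s[k]) / (s[k + 1] - s[k])
    return float(r[k] + frac * (r[k + 1] - r[k]))


def _median_estimator(hset: HarmonizedSet, weighted: bool, n_boot: int,
                      seed: int | None, method: str) -> MREstimate:
    if hset.n_snp < 3:
        raise InsufficientInstrumentsError(f"{method} needs ≥ 3 SNPs, got {hset.n_snp}")
    ratios, ivw_w = _ratios_weights(hset)
    weights = ivw_w if weighted else np.ones_like(ratios)
    beta = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    # parametric bootstrap: redraw per-SNP effects from their sampling distributions
    bx = rng.normal(hset.beta_exp, hset.se_exp, size=(n_boot, hset.n_snp))
    by = rng.normal(hset.beta_out, hset.se_out, size=(n_boot, hset.n_snp))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        with np.errstate(divide="ignore", invalid="ignore"):
            rb = by[b] / bx[b]
        ok = np.isfinite(rb)
        wb = weights[ok] if not weighted else (bx[b][ok] / hset.se_out[ok]) ** 2
        boot[b] = _weighted_median_point(rb[ok], wb)
    se = float(np.std(boot, ddof=1))
    return MREstimate(method, beta, se, _norm_p(beta / se), hset.n_snp)


def weighted_median(hset: HarmonizedSet, n_boot: int = 5000,
                    seed: int | None = None) -> MREstimate:
    """Weighted-median causal estimate; bootstrap SE (seeded, reproducible)."""
    return _median_estimator(hset, True, n_boot, seed, "weighted_median")


def simple_median(hset: HarmonizedSet, n_boot: int = 5000,
                  seed: int | None = None) -> MREstimate:
    """Equal-weight median causal estimate; bootstrap SE (seeded)."""
    return _median_estimator(hset, False, n_boot, seed, "simple_median")


def reverse_mr(outcome_as_exposure: SummaryTable, exposure_as_outcome: SummaryTable,
               ld: LDMatrix, config: SelectionConfig | None = None,
               mode: str = "multiplicative_random") -> MREstimate:
    """IVW MR with the roles swapped, testing for a reverse causal path.

    Selects instruments for the original outcome, harmonizes against the
    original exposure and runs IVW; the returned estimate is tagged
    ``direction="reverse"``.
    """
    inst = select_instruments(outcome_as_exposure, ld, config)
    hset = gwas_io.harmonize(inst.records, exposure_as_outcome)
    est = ivw(hset, mode=mode)
    est.direction = "reverse"
    return est
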