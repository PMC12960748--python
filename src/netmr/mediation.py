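"""Two-step (network) MR mediation analysis.

The total causal effect of an exposure X on an outcome Y is decomposed
through a candidate mediator M:

* total effect  β_total — univariable IVW, X → Y;
* step 1        β_EM    — univariable IVW, X → M;
* step 2        β_MO    — the mediator's coefficient from MVMR of Y on
  (M, X), i.e. the M → Y effect adjusted for X;
* indirect      β_EM · β_MO, with delta-method SE
  √(β_EM²·se_MO² + β_MO²·se_EM²);
* direct        β_total − β_indirect (exactly additive by construction);
* proportion mediated = β_indirect / β_total, reported as a percentage with
  its sign preserved — negative for *competitive* mediation, where the
  indirect path opposes the total effect.

Candidate mediators are screened by requiring nominal significance of both
steps plus a direction guard: no significant reverse effect of the mediator
on the exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import gwas_io, mr_core
from .gwas_io import SummaryTable
from .instruments import (LDMatrix, NoInstrumentsError, SelectionConfig,
                          select_instruments)
from .mr_core import Z95
from .mvmr import mvmr_estimate

logger = logging.getLogger(__name__)


class UndefinedProportionError(ZeroDivisionError):
    """Proportion mediated is undefined when the total effect is zero."""


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    beta_total: float
    se_total: float
    beta_em: float
    se_em: float
    beta_mo: float
    se_mo: float
    beta_indirect: float
    se_indirect: float
    beta_direct: float
    proportion_mediated: float      # fraction; × 100 for percent
    prop_ci_low: float
    prop_ci_high: float
    classification: str             # partial | competitive | full | none

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion_mediated


def decompose(beta_total: float, se_total: float, beta_em: float, se_em: float,
              beta_mo: float, se_mo: float, exposure: str = "exposure",
              mediator: str = "mediator", outcome: str = "outcome") -> MediationResult:
    """Product-of-coefficients decomposition with delta-method uncertainty.

    Classification: *none* when the indirect 95% CI includes 0;
    *competitive* when indirect and total effects have opposite signs;
    *full* when the direct-effect CI includes 0 while the indirect excludes 0;
    *partial* otherwise (same signs, |indirect| < |total|).
    """
    if beta_total == 0:
        raise UndefinedProportionError("proportion mediated undefined: beta_total = 0")
    beta_ind = beta_em * beta_mo
    se_ind = float(np.sqrt(beta_em ** 2 * se_mo ** 2 + beta_mo ** 2 * se_em ** 2))
    beta_dir = beta_total - beta_ind
    prop = beta_ind / beta_total
    # delta method on the ratio (independence of numerator and denominator assumed)
    var_prop = (se_ind ** 2 / beta_total ** 2
                + beta_ind ** 2 * se_total ** 2 / beta_total ** 4)
    se_prop = float(np.sqrt(var_prop))
    # the ratio CI is reliable only when the denominator is bounded away from 0
    total_sig = abs(beta_total) > Z95 * se_total
    lo, hi = (prop - Z95 * se_prop, prop + Z95 * se_prop) if total_sig else (-np.inf, np.inf)

    ind_sig = se_ind > 0 and abs(beta_ind) > Z95 * se_ind
    se_dir = float(np.sqrt(se_total ** 2 + se_ind ** 2))
    dir_sig = abs(beta_dir) > Z95 * se_dir
    if not ind_sig or beta_ind == 0:
        cls = "none"
    elif np.sign(beta_ind) != np.sign(beta_total):
        cls = "competitive"
    elif not dir_sig:
        cls = "full"
    else:
        cls = "partial"
    return MediationResult(exposure, mediator, outcome,
                           beta_total, se_total, beta_em, se_em, beta_mo, se_mo,
                           beta_ind, se_ind, beta_dir, prop, lo, hi, cls)


def mediate(exposure: SummaryTable, mediator: SummaryTable, outcome: SummaryTable,
            ld: LDMatrix, config: SelectionConfig | None = None,
            ivw_mode: str = "multiplicative_random") -> MediationResult:
    """Full two-step mediation for one (exposure, mediator, outcome) triple."""
    cfg = config or SelectionConfig()
    inst = select_instruments(exposure, ld, cfg)
    h_total = gwas_io.harmonize(inst.records, outcome)
    total = mr_core.ivw(h_total, mode=ivw_mode)
    h_em = gwas_io.harmonize(inst.records, mediator)
    em = mr_core.ivw(h_em, mode=ivw_mode)
    mv = mvmr_estimate([mediator, exposure], outcome, ld, cfg)
    b_mo, se_mo, _ = mv.coef(mediator.trait_label)
    return decompose(total.beta, total.se, em.beta, em.se, b_mo, se_mo,
                     exposure.trait_label, mediator.trait_label, outcome.trait_label)


def screen_mediators(exposure: SummaryTable, mediator_tables, outcome: SummaryTable,
                     ld: LDMatrix, alpha: float = 0.05,
                     config: SelectionConfig | None = None,
                     ivw_mode: str = "multiplicative_random") -> list:
    """Two-step screen over candidate mediators.

    A mediator is a candidate iff the exposure→mediator IVW p < alpha, the
    mediator→outcome IVW p < alpha, and the reverse mediator→exposure IVW
    p ≥ alpha (direction guard).  Mediators without instruments are skipped
    with a logged reason.  Returns the list of candidate trait labels.
    """
    cfg = config or SelectionConfig()
    try:
        exp_inst = select_instruments(exposure, ld, cfg)
    except NoInstrumentsError:
        logger.warning("exposure %s has no instruments; screen is empty",
                       exposure.trait_label)
        return []
    candidates = []
    for med in mediator_tables:
        label = med.trait_label
        try:
            h_em = gwas_io.harmonize(exp_inst.records, med)
            p_em = mr_core.ivw(h_em, mode=ivw_mode).pval
            med_inst = select_instruments(med, ld, cfg)
            h_mo = gwas_io.harmonize(med_inst.records, outcome)
            p_mo = mr_core.ivw(h_mo, mode=ivw_mode).pval
            h_rev = gwas_io.harmonize(med_inst.records, exposure)
            p_rev = mr_core.ivw(h_rev, mode=ivw_mode).pval
        except (NoInstrumentsError, gwas_io.EmptyOverlapError) as exc:
            logger.info("mediator %s skipped: %s", label, exc)
            continue
        ok = p_em < alpha and p_mo < alpha and p_rev >= alpha
        logger.info("mediator %s: p_em=%.3g p_mo=%.3g p_rev=%.3g -> %s",
                    label, p_em, p_mo, p_rev, "candidate" if ok else "rejected")
        if ok:
            candidates.append(label)
    return candidates
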