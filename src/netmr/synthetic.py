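"""Synthetic GWAS summary statistics under a known causal chain.

The generator emulates the statistical structure of a two-sample MR study:
three summary-statistics tables (a quantitative exposure such as a plasma
protein, a quantitative mediator such as an immune phenotype, and a binary
outcome on the log-odds scale) whose per-SNP effects follow the linear
causal chain

    exposure --θ_em--> mediator --θ_mo--> outcome
        \\------------θ_direct-----------/

so that θ_total = θ_direct + θ_em·θ_mo.  Sampling noise is set analytically
from per-study sample sizes: for a standardized quantitative trait
``se = 1/√(2·maf·(1−maf)·n)``, and for the binary outcome the log-odds SE
additionally scales with the case fraction φ as ``1/√(2·maf(1−maf)·n·φ(1−φ))``.
Horizontal pleiotropy (balanced and/or directional) and planted outlier SNPs
perturb the outcome effects; LD is block-diagonal by construction.

Effects are generated directly on the summary-statistic scale with Gaussian
noise — no individual-level genotype or logistic simulation — which is what
summary-statistic MR methods actually see, and orders of magnitude faster.

Defaults mirror the cohorts the pipeline is aimed at: an exposure GWAS of
~2600 (plasma-protein panel), a mediator GWAS of ~3400 (immunophenotypes)
and a binary-outcome GWAS of ~412,000 with ~1.1% cases (disease endpoint
from a national biobank).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas_io import SummaryTable
from .instruments import LDMatrix, write_ld

logger = logging.getLogger(__name__)

_NONPALINDROMIC = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                   ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimConfig:
    """Generating parameters for one synthetic causal chain.

    ``theta_total`` is derived as ``theta_direct + theta_em·theta_mo`` when
    ``theta_direct`` is given; supplying all four checks consistency.
    ``mean_f`` sets the scale of true exposure effects so the expected
    single-SNP F statistic is near that value (instrument strength).

    ``n_snp_med`` adds SNPs that instrument the *mediator only* (zero true
    exposure effect).  The mediator→outcome path is identified in
    multivariable MR only through such mediator-specific instruments — with
    exposure instruments alone the mediator and exposure effect columns are
    proportional — so mediation-recovery experiments need ``n_snp_med > 0``.
    """

    n_snp: int = 50
    n_snp_med: int = 0
    n_snp_out: int = 0
    n_exp: int = 2639
    n_med: int = 3394
    n_out: int = 412_181
    case_fraction: float = 4681 / 412_181
    theta_total: float | None = None
    theta_em: float = 0.0
    theta_mo: float = 0.0
    theta_direct: float | None = None
    pleiotropy_sd: float = 0.0
    directional_pleiotropy: float = 0.0
    n_outlier: int = 0
    outlier_scale: float = 10.0
    maf_range: tuple = (0.1, 0.5)
    ld_block_size: int = 1
    ld_within_r2: float = 0.0
    palindrome_fraction: float = 0.0
    mean_f: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        indirect = self.theta_em * self.theta_mo
        if self.theta_direct is None:
            if self.theta_total is None:
                self.theta_total = indirect
            self.theta_direct = self.theta_total - indirect
        elif self.theta_total is None:
            self.theta_total = self.theta_direct + indirect
        elif abs(self.theta_total - (self.theta_direct + indirect)) > 1e-9:
            raise ValueError(
                "inconsistent paths: theta_total != theta_direct + theta_em*theta_mo")


@dataclass
class SimTruth:
    """Generating parameters plus realized per-SNP truths, for recovery tests."""

    config: SimConfig
    per_snp_effects: pd.DataFrame   # snp_id, true_beta_exp, pleiotropy, is_outlier


def _se_quant(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _se_binary(maf: np.ndarray, n: int, case_fraction: float) -> np.ndarray:
    phi = case_fraction
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * phi * (1.0 - phi))


def _make_table(rng, snp_ids, chrom, pos, alleles, maf, true_beta, se,
                n, label, trait_type) -> SummaryTable:
    from scipy import stats
    beta_hat = rng.normal(true_beta, se)
    z = beta_hat / se
    pval = np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos,
        "effect_allele": [a[0] for a in alleles],
        "other_allele": [a[1] for a in alleles],
        "eaf": maf, "beta": beta_hat, "se": se, "pval": pval, "n": n,
    })
    return SummaryTable(df, label, trait_type)


def simulate_chain(config: SimConfig) -> tuple:
    """Generate (exposure, mediator, outcome, LDMatrix, SimTruth).

    True exposure effects are ``b_j ~ N(0, σ_b²)`` with σ_b chosen so the
    expected single-SNP F on the exposure is ``mean_f``; observed betas add
    analytic sampling noise.  The mediator inherits ``θ_em·b_j``, the outcome
    ``θ_direct·b_j + θ_mo·θ_em·b_j`` plus a pleiotropic term
    ``α_j ~ N(directional_pleiotropy, pleiotropy_sd²)``; the first
    ``n_outlier`` SNPs get α inflated by ``outlier_scale``.  The LD matrix is
    block-diagonal: ``ld_within_r2`` inside blocks of ``ld_block_size``, 0
    between; blocks never span chromosomes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    # panel layout: exposure instruments, then mediator-specific, then
    # outcome-specific susceptibility loci (needed for reverse-MR experiments)
    j = cfg.n_snp + cfg.n_snp_med + cfg.n_snp_out

    snp_ids = [f"rs{100000 + i}" for i in range(j)]
    # spread SNPs over 22 chromosomes; adjacent SNPs 50 kb apart within a chrom
    chrom = np.array([str(1 + (i % 22)) for i in range(j)], dtype=object)
    pos = np.array([1_000_000 + 50_000 * (i // 22) for i in range(j)], dtype=np.int64)
    if cfg.ld_block_size > 1:
        # co-locate each LD block on one chromosome, blocks well separated
        chrom = np.array([str(1 + ((i // cfg.ld_block_size) % 22)) for i in range(j)],
                         dtype=object)
        pos = np.array([1_000_000 + 100_000_000 * (i // (22 * cfg.ld_block_size))
                        + 1_000 * (i % cfg.ld_block_size) for i in range(j)],
                       dtype=np.int64)

    maf = rng.uniform(*cfg.maf_range, size=j)
    n_pal = int(round(cfg.palindrome_fraction * j))
    pal_idx = rng.choice(j, size=n_pal, replace=False) if n_pal else np.array([], int)
    alleles = [list(_NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]) for _ in range(j)]
    for i in pal_idx:
        alleles[i] = list(_PALINDROMIC[rng.integers(len(_PALINDROMIC))])

    se_exp = _se_quant(maf, cfg.n_exp)
    se_med = _se_quant(maf, cfg.n_med)
    se_out = _se_binary(maf, cfg.n_out, cfg.case_fraction)

    # scale true effects so E[F] = E[(b/se)²] + 1 ≈ mean_f on the exposure
    sigma_b = np.sqrt(max(cfg.mean_f - 1.0, 1.0)) * float(np.mean(se_exp))
    b = np.zeros(j)
    b[: cfg.n_snp] = rng.normal(0.0, sigma_b, size=cfg.n_snp)
    m_own = np.zeros(j)
    if cfg.n_snp_med:
        sigma_m = np.sqrt(max(cfg.mean_f - 1.0, 1.0)) * float(np.mean(se_med))
        m_own[cfg.n_snp: cfg.n_snp + cfg.n_snp_med] = rng.normal(
            0.0, sigma_m, size=cfg.n_snp_med)
    o_own = np.zeros(j)
    if cfg.n_snp_out:
        sigma_o = np.sqrt(max(cfg.mean_f - 1.0, 1.0)) * float(np.mean(se_out))
        o_own[cfg.n_snp + cfg.n_snp_med:] = rng.normal(0.0, sigma_o, size=cfg.n_snp_out)

    # pleiotropy attaches to the exposure instruments only, and its direction
    # is defined relative to the exposure-increasing allele (sign(b)); a
    # fixed-allele-coding constant would cancel under Egger's orientation
    alpha = np.zeros(j)
    if cfg.pleiotropy_sd > 0 or cfg.directional_pleiotropy != 0:
        draw = rng.normal(cfg.directional_pleiotropy, cfg.pleiotropy_sd, size=cfg.n_snp)
        alpha[: cfg.n_snp] = draw * np.where(b[: cfg.n_snp] >= 0, 1.0, -1.0)
    is_outlier = np.zeros(j, dtype=bool)
    if cfg.n_outlier:
        # plant outliers at the strongest instruments, where a perturbation is
        # well determined relative to sampling noise
        strongest = np.argsort(-np.abs(b))[: cfg.n_outlier]
        is_outlier[strongest] = True
        # an outlier's Wald ratio is inflated to outlier_scale × theta_total
        # (or, under a null chain, to outlier_scale × sigma_b in absolute terms)
        if cfg.theta_total:
            alpha[is_outlier] += (cfg.outlier_scale - 1.0) * cfg.theta_total * b[is_outlier]
        else:
            alpha[is_outlier] += cfg.outlier_scale * sigma_b

    true_med = cfg.theta_em * b + m_own
    true_out = cfg.theta_direct * b + cfg.theta_mo * true_med + alpha + o_own

    exposure = _make_table(rng, snp_ids, chrom, pos, alleles, maf, b, se_exp,
                           cfg.n_exp, "exposure", "quantitative")
    mediator = _make_table(rng, snp_ids, chrom, pos, alleles, maf, true_med, se_med,
                           cfg.n_med, "mediator", "quantitative")
    outcome = _make_table(rng, snp_ids, chrom, pos, alleles, maf, true_out, se_out,
                          cfg.n_out, "outcome", "binary")

    r2 = np.eye(j)
    if cfg.ld_block_size > 1 and cfg.ld_within_r2 > 0:
        for start in range(0, j, cfg.ld_block_size):
            blk = slice(start, min(start + cfg.ld_block_size, j))
            r2[blk, blk] = cfg.ld_within_r2
        np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(snp_ids, r2, pos, chrom)

    truth = SimTruth(cfg, pd.DataFrame({
        "snp_id": snp_ids, "true_beta_exp": b, "true_beta_med": true_med,
        "true_beta_out": true_out, "pleiotropy": alpha, "is_outlier": is_outlier,
    }))
    return exposure, mediator, outcome, ld, truth


def simulate_screen(template: SimConfig, n_exposures: int, n_mediators: int,
                    causal: list, out_dir, force: bool = False,
                    snps_per_trait: int | None = None) -> dict:
    """Write a small screening study: many exposures × mediators, one outcome.

    ``causal`` lists (exposure_index, mediator_index) pairs that truly follow
    the chain with the template's θ parameters; every other trait is null.
    Each trait gets its own block of instrument SNPs on a shared panel, so
    traits are instrumented independently.  Writes one TSV per trait plus
    ``ld.tsv`` and ``manifest.json`` recording the planted truth; refuses a
    non-empty output directory unless ``force``.

    Returns the manifest as a dict.
    """
    if n_exposures < 1 or n_mediators < 1:
        raise ValueError("counts must be >= 1")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty; pass force=True to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(template.seed)
    k = snps_per_trait or template.n_snp
    n_traits = n_exposures + n_mediators
    j = k * n_traits
    causal = [tuple(c) for c in causal]

    snp_ids = [f"rs{200000 + i}" for i in range(j)]
    chrom = np.array([str(1 + (t % 22)) for t in range(n_traits) for _ in range(k)],
                     dtype=object)
    pos = np.array([1_000_000 + 10_000_000 * (t // 22) + 50_000 * i
                    for t in range(n_traits) for i in range(k)], dtype=np.int64)
    maf = rng.uniform(*template.maf_range, size=j)
    alleles = [list(_NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]) for _ in range(j)]

    se_exp = _se_quant(maf, template.n_exp)
    se_med = _se_quant(maf, template.n_med)
    se_out = _se_binary(maf, template.n_out, template.case_fraction)
    sigma_b = np.sqrt(max(template.mean_f - 1.0, 1.0)) * float(np.mean(se_exp))

    # block t of the panel instruments trait t (exposures first, then mediators)
    own = np.zeros((j, n_traits))
    for t in range(n_traits):
        own[t * k:(t + 1) * k, t] = rng.normal(0.0, sigma_b, size=k)

    true_exp = [own[:, e] for e in range(n_exposures)]
    true_med = []
    for m in range(n_mediators):
        tm = own[:, n_exposures + m].copy()
        for (e, mm) in causal:
            if mm == m:
                tm += template.theta_em * true_exp[e]
        true_med.append(tm)
    true_out = np.zeros(j)
    for (e, m) in causal:
        true_out += template.theta_direct * true_exp[e] + template.theta_mo * true_med[m]

    files = {}
    for e in range(n_exposures):
        t = _make_table(rng, snp_ids, chrom, pos, alleles, maf, true_exp[e], se_exp,
                        template.n_exp, f"exposure_{e}", "quantitative")
        files[f"exposure_{e}"] = f"exposure_{e}.tsv"
        t.df.to_csv(out_dir / files[f"exposure_{e}"], sep="\t", index=False,
                    float_format="%.17g")
    for m in range(n_mediators):
        t = _make_table(rng, snp_ids, chrom, pos, alleles, maf, true_med[m], se_med,
                        template.n_med, f"mediator_{m}", "quantitative")
        files[f"mediator_{m}"] = f"mediator_{m}.tsv"
        t.df.to_csv(out_dir / files[f"mediator_{m}"], sep="\t", index=False,
                    float_format="%.17g")
    out_table = _make_table(rng, snp_ids, chrom, pos, alleles, maf, true_out, se_out,
                            template.n_out, "outcome", "binary")
    out_table.df.to_csv(out_dir / "outcome.tsv", sep="\t", index=False,
                        float_format="%.17g")
    files["outcome"] = "outcome.tsv"

    ld = LDMatrix(snp_ids, np.eye(j), pos, chrom)
    write_ld(ld, out_dir / "ld.tsv")

    manifest = {
        "seed": template.seed,
        "n_exposures": n_exposures,
        "n_mediators": n_mediators,
        "snps_per_trait": k,
        "causal_triples": [[e, m] for (e, m) in causal],
        "theta_em": template.theta_em,
        "theta_mo": template.theta_mo,
        "theta_direct": template.theta_direct,
        "theta_total": template.theta_total,
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
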