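"""Heterogeneity, pleiotropy and outlier diagnostics on contaminated data.

Simulates an MR dataset in which one instrument carries a 10x-inflated
pleiotropic effect, then shows how Cochran's Q, the Egger intercept,
MR-PRESSO and leave-one-out each expose it.
"""

import numpy as np

from netmr import SimConfig, simulate_chain, ivw, cochran_q, \
    egger_intercept_test, mr_presso, leave_one_out
from netmr.gwas_io import HarmonizedSet

cfg = SimConfig(n_snp=20, theta_total=0.2, n_exp=200_000, mean_f=300,
                n_outlier=1, outlier_scale=10.0, seed=2)
exposure, _, outcome, ld, truth = simulate_chain(cfg)
hset = HarmonizedSet(exposure.df["snp_id"].tolist(),
                     exposure.df["beta"].to_numpy(), exposure.df["se"].to_numpy(),
                     outcome.df["beta"].to_numpy(), outcome.df["se"].to_numpy())
planted = truth.per_snp_effects.loc[truth.per_snp_effects["is_outlier"],
                                    "snp_id"].iloc[0]
print(f"planted outlier: {planted} (Wald ratio inflated to 10x the truth)\n")

het = cochran_q(hset)
print(f"Cochran's Q = {het.q:.2f} on {het.df} df, p = {het.pval:.2e}"
      "  -> significant heterogeneity")

ple = egger_intercept_test(hset)
print(f"Egger intercept = {ple.intercept:.4f} (SE {ple.se:.4f}), "
      f"p = {ple.pval:.3f}")

pres = mr_presso(hset, n_sim=1000, seed=1)
print(f"MR-PRESSO global p = {pres.global_pval:.4f}; "
      f"outliers flagged: {[s for s, _ in pres.outlier_snps]}")
print(f"IVW before/after outlier removal: {ivw(hset, 'fixed').beta:.3f} -> "
      f"{pres.beta_outlier_corrected:.3f} (truth 0.2), "
      f"distortion p = {pres.distortion_pval:.3f}")

loo = leave_one_out(hset)
moved = max(loo.rows, key=lambda r: abs(r[1] - ivw(hset).beta))
print(f"leave-one-out: largest shift when dropping {moved[0]} "
      f"(beta {ivw(hset).beta:.3f} -> {moved[1]:.3f})")
print("\nAll four diagnostics converge on the planted SNP; the corrected "
      "estimate moves back toward the simulated truth.")
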