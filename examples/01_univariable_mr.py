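"""Univariable two-sample MR on a simulated exposure-outcome pair.

Simulates GWAS summary statistics for a quantitative exposure and a binary
outcome with a true causal effect of 0.2 on the log-odds scale, selects
instruments (p < 1e-5, LD clumping, F > 10), harmonizes effect alleles, and
runs the four standard estimators.
"""

from netmr import SimConfig, harmonize, ivw, egger, weighted_median, \
    simple_median, select_instruments, simulate_chain

cfg = SimConfig(n_snp=60, theta_total=0.2, n_exp=50_000, seed=7)
exposure, _, outcome, ld, truth = simulate_chain(cfg)

inst = select_instruments(exposure, ld)
print(f"instruments selected: {inst.n_snp} of {exposure.n_snp} SNPs "
      f"(mean F = {inst.f_stats.mean():.0f})")

hset = harmonize(inst.records, outcome)
print(f"harmonized SNPs: {hset.n_snp}\n")

print(f"{'method':<18}{'beta':>8}{'SE':>8}{'OR':>7}{'95% CI':>17}{'p':>11}")
estimates = [ivw(hset, "fixed"), ivw(hset, "multiplicative_random"),
             egger(hset)[0], weighted_median(hset, seed=1),
             simple_median(hset, seed=1)]
for e in estimates:
    print(f"{e.method:<18}{e.beta:>8.3f}{e.se:>8.3f}{e.or_:>7.3f}"
          f"{f'({e.or_ci_low:.3f}, {e.or_ci_high:.3f})':>17}{e.pval:>11.2e}")

print("\nAll estimators should agree with the simulated truth (beta = 0.2, "
      "OR = 1.22): a per-allele one-unit increase in the exposure raises the "
      "odds of the outcome by ~22%.")
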