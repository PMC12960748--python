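"""Multivariable MR: direct effects of two correlated exposures.

Builds two exposures with disjoint instrument blocks and direct effects
(0.3, -0.2) on a shared outcome, and shows that joint weighted least squares
on the pooled instruments separates them.
"""

import numpy as np

from netmr import mvmr_estimate
from netmr.instruments import LDMatrix
from netmr.gwas_io import SummaryTable
import pandas as pd

rng = np.random.default_rng(11)
j = 40  # 20 instruments per exposure
ids = [f"rs{i}" for i in range(j)]
pos = np.arange(j) * 1_000_000
b1 = np.zeros(j)
b2 = np.zeros(j)
b1[:20] = rng.uniform(0.2, 0.4, 20) * rng.choice([-1, 1], 20)
b2[20:] = rng.uniform(0.2, 0.4, 20) * rng.choice([-1, 1], 20)
se = np.full(j, 0.01)
y = 0.3 * b1 - 0.2 * b2 + rng.normal(0, 0.002, j)


def table(beta, label):
    from scipy import stats
    noisy = beta + rng.normal(0, 1e-3, j)
    return SummaryTable(pd.DataFrame({
        "snp_id": ids, "chrom": "1", "pos": pos, "effect_allele": "A",
        "other_allele": "G", "eaf": 0.3, "beta": noisy, "se": se,
        "pval": 2 * stats.norm.sf(np.abs(noisy / se)), "n": 10_000,
    }), label)


ld = LDMatrix(ids, np.eye(j), pos, np.array(["1"] * j, dtype=object))
res = mvmr_estimate([table(b1, "protein_A"), table(b2, "protein_B")],
                    table(y, "disease"), ld)

print(f"{'exposure':<12}{'direct beta':>12}{'SE':>9}{'p':>12}{'cond. F':>9}")
for lab, b, s, p, f in zip(res.exposures, res.betas, res.ses, res.pvals,
                           res.conditional_f):
    print(f"{lab:<12}{b:>12.4f}{s:>9.4f}{p:>12.2e}{f:>9.0f}")
print(f"\n{res.n_snp} pooled instruments. Direct effects recover the "
      "generating values (0.3, -0.2): each exposure's effect is estimated "
      "net of the other; conditional F >> 10 means neither is a "
      "conditionally weak instrument.")
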