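"""The full screening study: many exposures, many mediators, one outcome.

Writes a synthetic screen (3 exposures x 4 candidate mediators, one planted
causal triple), then drives the whole design: instrument selection,
univariable MR with four estimators, the sensitivity suite, reverse MR,
multivariable adjustment and the two-step mediator screen, emitting
forest-plot-ready TSV tables.
"""

import tempfile
from pathlib import Path

from netmr import SimConfig, StudyConfig, run_study, simulate_screen

workdir = Path(tempfile.mkdtemp())
data = workdir / "data"
template = SimConfig(theta_em=0.1, theta_mo=0.5, theta_direct=0.15, seed=17)
simulate_screen(template, n_exposures=3, n_mediators=4, causal=[(1, 2)],
                out_dir=data, snps_per_trait=15)

config = StudyConfig(
    exposures={f"exposure_{e}": str(data / f"exposure_{e}.tsv")
               for e in range(3)},
    outcome=str(data / "outcome.tsv"), outcome_label="disease",
    mediators={f"mediator_{m}": str(data / f"mediator_{m}.tsv")
               for m in range(4)},
    ld=str(data / "ld.tsv"), out_dir=str(workdir / "results"),
)
bundle = run_study(config)

mr = bundle["mr_results"]
print("primary IVW (multiplicative random effects) per exposure:")
print(mr[mr["method"] == "ivw_mre"]
      [["exposure", "or", "or_ci_low", "or_ci_high", "pval"]]
      .to_string(index=False, float_format="%.3f"))

print("\nsensitivity (heterogeneity Q and Egger intercept):")
print(bundle["sensitivity"]
      [["exposure", "Q", "Q_df", "Q_pval", "egger_intercept", "egger_pval"]]
      .to_string(index=False, float_format="%.3f"))

print("\nmediation decomposition for screened candidates:")
print(bundle["mediation"]
      [["exposure", "mediator", "beta_total", "beta_indirect",
        "proportion_mediated_pct", "classification"]]
      .to_string(index=False, float_format="%.4f"))

print(f"\nOnly the planted exposure_1 is causal (total effect 0.2); its "
      f"planted mediator_2 carries ~25% of the effect. Full tables in "
      f"{workdir / 'results'}.")
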