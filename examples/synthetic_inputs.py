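"""Synthetic inputs: parametric life table and re-test cohorts.

The package ships no national data.  A Gompertz-Makeham generator makes
the background-mortality table (defaults give ~25.8 remaining years at
age 60), and a seeded generator draws re-test classification cohorts with
the same nested-detection structure the decision tree assumes — so the
classification module's sensitivity reconstruction can be validated
end to end.
"""

from uacr_cea import (
    AStage,
    LifeTableSpec,
    RetestSpec,
    life_expectancy,
    parameter_recovery_check,
    synth_life_table,
    synth_retest_counts,
    upcr_sensitivities,
)

table = synth_life_table(LifeTableSpec())
print(f"life table ages {table['age'].min()}-{table['age'].max()}, "
      f"q(60)={table.loc[table['age'] == 60, 'qx'].iloc[0]:.5f}, "
      f"remaining life expectancy at 60: {life_expectancy(table, 60):.1f} y")

spec = RetestSpec(n=1238, seed=7)
retest = synth_retest_counts(spec)
sens = upcr_sensitivities(retest)
print(f"\none synthetic cohort (n=1238, seed=7): reconstructed UPCR "
      f"sensitivity A2={sens[AStage.A2]:.3f}, A3={sens[AStage.A3]:.3f} "
      f"(generating values {75 / 198:.3f}, 1.000)")

report = parameter_recovery_check(200, spec)
print(f"\n200 replicates: mean estimate A2={report.mean_estimate[AStage.A2]:.4f}"
      f" (bias {report.bias[AStage.A2]:+.4f}, MC SE "
      f"{report.mc_se[AStage.A2]:.4f}); unbiased within MC error: "
      f"{report.within_mc_error}")
print("\nThe nested-detection reconstruction recovers the generating")
print("sensitivities, validating the decision-tree classification logic.")
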