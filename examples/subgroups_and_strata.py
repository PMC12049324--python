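"""Subgroup analyses: starting CKD risk state and prior dipstick result.

Risk-state subgroups restrict the starting cohort to one KDIGO prognosis
band; dipstick strata condition the starting albuminuria distribution
(and the test-accuracy data) on a prior dipstick result.  UACR testing is
dominated in the low-risk band (nobody to treat, tests still paid for)
and dominant in the high-risk bands (prevented progression outweighs the
testing cost).
"""

from uacr_cea import DipstickStratum, RiskState, load_config, run_subgroup

cfg = load_config()

print("UACR vs no urine testing, by starting CKD risk band:")
for state in (RiskState.LOW, RiskState.MODERATE, RiskState.HIGH,
              RiskState.VERY_HIGH):
    c = run_subgroup(cfg, state).comparisons["UACR_vs_NONE"]
    icer = f"{c.icer:,.0f} ¥/QALY" if c.icer is not None else c.label
    print(f"  {state.value:10s} Δcost={c.delta_cost:16,.0f}  "
          f"ΔQALY={c.delta_qaly:8.2f}  {icer}")

print("\nUACR vs no urine testing, by prior dipstick result:")
for stratum in (DipstickStratum.DIPSTICK_NEGATIVE,
                DipstickStratum.DIPSTICK_TRACE,
                DipstickStratum.DIPSTICK_POSITIVE):
    c = run_subgroup(cfg, stratum).comparisons["UACR_vs_NONE"]
    icer = f"{c.icer:,.0f} ¥/QALY" if c.icer is not None else c.label
    print(f"  {stratum.value:18s} Δcost={c.delta_cost:16,.0f}  "
          f"ΔQALY={c.delta_qaly:8.2f}  {icer}")

print("\nHigher prior risk concentrates treatable albuminuria, so testing")
print("moves from a pure cost (negative dipstick) to outright savings.")
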