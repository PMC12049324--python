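"""Treatment paradigms: ACEi/ARB standard of care vs adding SGLT2i.

The value of accurate testing depends on what a diagnosis triggers.  The
combination scenario applies a stronger progression effect (RRR 0.35 vs
0.21) and adds the SGLT2i drug cost for the higher-risk diagnosed groups;
the UACR-vs-UPCR comparison improves because each extra detected case is
worth more.
"""

from uacr_cea import Scenario, load_config, run_scenario

cfg = load_config()
for scenario, label in ((Scenario.ACEI_ARB, "ACEi/ARB"),
                        (Scenario.ACEI_ARB_PLUS_SGLT2I, "ACEi/ARB + SGLT2i")):
    res = run_scenario(cfg, scenario)
    c = res.comparisons["UACR_vs_UPCR"]
    icer = f"{c.icer:,.0f} ¥/QALY" if c.icer is not None else c.label
    print(f"{label:18s} UACR vs UPCR: Δcost={c.delta_cost:14,.0f}  "
          f"ΔQALY={c.delta_qaly:7.2f}  {icer}")

print("\nA stronger post-diagnosis therapy amplifies the QALY gain from the")
print("more sensitive test and lowers the incremental cost per QALY.")
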