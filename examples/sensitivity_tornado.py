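"""One-way deterministic sensitivity analysis (tornado ordering).

Each driver parameter is set to ±20% of its base value (utilities capped
at 1) and the base-case UACR-vs-no-testing comparison is recomputed; the
spread between the two ICERs ranks the drivers.  An infinite spread marks
a bound where the comparison flips into dominance.
"""

from uacr_cea import load_config, one_way_dsa

cfg = load_config()
records = one_way_dsa(cfg)

print(f"{'parameter':45s} {'ICER low':>14s} {'ICER high':>14s} {'spread':>14s}")
for r in records:
    lo = f"{r.icer_low:,.0f}" if r.icer_low is not None else r.label_low
    hi = f"{r.icer_high:,.0f}" if r.icer_high is not None else r.label_high
    spread = "flip" if r.spread == float("inf") else f"{r.spread:,.0f}"
    print(f"{r.parameter:45s} {lo:>14s} {hi:>14s} {spread:>14s}")

print("\nParameters at the top move the ICER most; 'flip' means one bound")
print("made UACR testing dominant (cheaper and more effective) or dominated.")
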