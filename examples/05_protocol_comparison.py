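"""Full fixed-budget experiment: many short switches vs fewer long ones.

Every protocol spends the same total number of switching steps.  For each,
the one-sided Jarzynski estimate is compared with the bidirectional
Crooks/BAR reference (delta = JAR - CRO) and with the exact quadrature
value.  The bidirectional reference barely moves with switching length,
while the one-sided estimate improves as switches get longer.
"""

import neqswitch as ns

cfg = ns.validate_config({"seed": 1, "output_dir": "scratch/example_run",
                          "reduced": {"from": "NSWI400", "keep_per_block": 5}})
res = ns.run_experiment(cfg)

print(f"exact Delta A = {res.exact:+.4f} kcal/mol\n")
print("protocol    n_switch  n_rep   JAR        CRO        delta(JAR-CRO)")
lengths = {p.name: p.n_switch for p in cfg.protocols}
for c in res.cells:
    n_sw = lengths.get(c.protocol, "-")
    print(f"{c.protocol:10s} {n_sw!s:>8} {len(res.worksets[(c.protocol, 'forward')]):>6} "
          f"{c.delta_a_jar:+.4f}    {c.delta_a_cro:+.4f}    {c.delta_delta_a:+.4f}")
print(f"\nCRO spread across switching lengths: {res.cro_spread:.4f} kcal/mol")
print(f"(combined 3-sigma allowance: {res.cro_spread_limit:.4f})")
print("\nAt fixed budget the longest-switch protocol usually sits closest to")
print("the reference: fewer, longer switches buy lower dissipation per")
print("switch, which matters more than the extra averaging of many short")
print("switches.  Artifacts written under", res.run_dir)
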