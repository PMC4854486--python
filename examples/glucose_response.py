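"""Glucose-stimulated steady states.

Computes the resting state at 3 mM extracellular glucose and the activated
state at 8 mM, printing the membrane potential, cytosolic/ER calcium, cAMP
and the lipid messengers.  The glucose step closes K_ATP channels (via the
ATP/ADP ratio), depolarizes the membrane, opens voltage-gated Ca²⁺ channels
and secondarily activates the PLC and cAMP branches.
"""

import betacell as bc

p = bc.load_parameters()
low = bc.find_steady_state(p, {"Glu": 3000.0})
high = bc.find_steady_state(p, {"Glu": 8000.0}, from_state=low.state)

print(f"{'quantity':<10} {'3 mM':>10} {'8 mM':>10}")
for name, unit in [("Vp", "mV"), ("Cac", "uM"), ("CaER", "uM"),
                   ("cAMP", "uM"), ("ATD", "-"), ("IP3", "uM"),
                   ("DAG", "#/um^2"), ("PIP2", "#/um^2")]:
    print(f"{name:<10} {low[name]:>10.3f} {high[name]:>10.3f}   [{unit}]")

d_lo, d_hi = low.derived(p), high.derived(p)
print(f"\nK_ATP open fraction: {d_lo['O_KATP']:.4f} -> {d_hi['O_KATP']:.4f}")
print("The drop in K_ATP conductance depolarizes the membrane by "
      f"{high['Vp'] - low['Vp']:.1f} mV and roughly doubles cytosolic Ca2+, "
      "while cAMP rises only slightly without receptor agonists.")
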