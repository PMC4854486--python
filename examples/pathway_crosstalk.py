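"""Cross-talk between the cAMP and PLC pathways.

Order-of-addition experiment at 8 mM glucose: GLP-1 first (cAMP pathway),
then an FFAR1/GPR40 agonist (PLC pathway) — and the reverse.  The cAMP
pathway feeds the PLC pathway (PKA raises Ca²⁺, which activates PLC), but
PLC activation does not raise cAMP, because cAMP production needs Gs-coupled
receptors to engage the membrane adenylyl cyclase.
"""

import betacell as bc

for name, order, t_first in [("fig10", "GLP-1 then FFAR1 agonist", 3900),
                             ("fig11", "FFAR1 agonist then GLP-1", 2900)]:
    traj = bc.integrate(bc.preset_scenario(name))
    t_end = traj.time[-1]
    print(f"{order}:")
    print(f"  after first agonist : cAMP {traj.value_at('cAMP', t_first):6.3f} uM, "
          f"IP3 {traj.value_at('IP3', t_first):5.3f} uM, "
          f"Cac {traj.value_at('Cac', t_first):6.4f} uM")
    print(f"  after both agonists : cAMP {traj.value_at('cAMP', t_end):6.3f} uM, "
          f"IP3 {traj.value_at('IP3', t_end):5.3f} uM, "
          f"Cac {traj.value_at('Cac', t_end):6.4f} uM")

print("\nGLP-1 raises cAMP and, through PKA and calcium, also IP3; the "
      "FFAR1 agonist raises IP3 but leaves cAMP untouched — the cross-talk "
      "is asymmetric.")
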