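# betacell

A deterministic whole-cell kinetic model of GPCR and second-messenger
signaling in the pancreatic β-cell, packaged as a scriptable simulator.

Insulin secretion is triggered by glucose metabolism but tuned by a set of
G-protein-coupled receptors: the incretin receptors GLP-1R and GIPR and the
inhibitory α2A-adrenergic receptor converge on a membrane adenylyl cyclase
(AC_p) and the cAMP→PKA/Epac branch, while the M3 muscarinic receptor and
the free-fatty-acid receptor FFAR1/GPR40 converge on membrane phospholipase
C (PLC_p) and the PIP₂→IP₃/DAG→PKC branch. Both branches feed back on
membrane excitability and calcium. This package couples all of these in a
single 43-state ODE system for quantitative *in-silico* experiments:
agonist additions, receptor-abundance scans, channel block, PDE
manipulation, and a type-2-diabetes-like metabolic lesion.

## Model summary

State variables and the main couplings:

- **Metabolism** — the ATP/ADP ratio relaxes to a Hill function of glucose
  (plus an FFA glucose-equivalent, `k_GFr`); free ATP/MgADP set the K_ATP
  channel open fraction (Magnus–Keizer-type kinetics), with PIP₂ enhancing
  and PKA phosphorylation reducing the current.
- **Membrane potential** — slow current balance
  `dV_p/dt = −(I_KATP + I_Kr + I_Ca + I_SOC + I_PCa + I_Nab)/C_m` with
  stationary Boltzmann gating (spike activity is deliberately excluded).
- **Five GPCR cascades** — mass-action receptor→G-protein→effector chains;
  collision coupling for GLP-1R, GIPR, α2A-AdR and FFAR1, pre-coupling for
  M3R; private G-protein pools, shared effector-enzyme pools (AC_p, PLC_p);
  one desensitization/recycling loop per receptor. The Gi (α2A) complex
  occupies AC_p without catalyzing — catecholamines occlude the cyclase.
- **cAMP branch** — calmodulin equilibria (active CaM = Ca₃CaM + Ca₄CaM),
  CaM-stimulated membrane AC and soluble Ca²⁺/ATP-driven AC, CaM-activated
  phosphodiesterase, and first-order PKA/Epac activation by Hill functions
  of cAMP.
- **PLC branch** — P4P/PIP₂ pool dynamics, PLC activity from G-protein-bound
  and cytosolic Ca²⁺-activated isoforms, IP₃ (cytosolic) and DAG
  (membrane-bound) production in stoichiometric proportion, PKC activation
  feeding back on P4P synthesis.
- **Calcium** — cytosolic and ER free Ca²⁺ with SERCA uptake, a
  PKA-sensitized IP₃-receptor release channel plus leak, plasma-membrane
  pump, L-type and store-operated entry.

All parameters carry their source units in the bundled
`src/betacell/data/parameters.yaml`; two printed constants of the membrane
calcium current are reconstructed (see `docs/methods.md`, "Reconstructed
constants") because the values as printed leave the model without a resting
state.

## Worked example

```python
import betacell as bc

p = bc.load_parameters()
low  = bc.find_steady_state(p, {"Glu": 3000.0})             # 3 mM glucose
high = bc.find_steady_state(p, {"Glu": 8000.0}, from_state=low.state)
print(round(low["Vp"], 1), round(low["Cac"], 3), round(low["cAMP"], 2))
print(round(high["Vp"], 1), round(high["Cac"], 3), round(high["cAMP"], 2))
```

prints

```
-61.7 0.107 1.84
-25.6 0.223 2.23
```

— at rest the membrane sits at −61.7 mV with ~0.1 μM cytosolic Ca²⁺ and
1.84 μM cAMP; the glucose step closes K_ATP channels, depolarizes the
membrane by ~36 mV, doubles cytosolic Ca²⁺ and (without incretins) nudges
cAMP up by ~20%. Adding GLP-1 on the high-glucose background
(`{"Glu": 8000.0, "GLP1": 6.2e-4}`) raises cAMP to ~8 μM through the Gs
cascade.

Timed protocols are event schedules:

```python
traj = bc.integrate(bc.preset_scenario("fig3"))   # glucose step, then GLP-1
traj.states        # DataFrame of all 43 state variables
traj.derived       # currents, enzyme activities, Ca fluxes per sample
```

See `examples/` for narrative scripts (glucose response, incretin
stimulation, receptor-abundance scans, pathway cross-talk) and
`betacell --help` for the command-line interface (`simulate`,
`steady-state`, `list-scenarios`, `params`).

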