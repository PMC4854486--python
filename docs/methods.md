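# Methods

## Model structure and assumptions

The simulator couples seven submodels into one 43-variable ODE system:
glucose/FFA-driven ATP/ADP kinetics; a slow plasma-membrane potential
balance over six currents; five mass-action GPCR cascades; calmodulin and
the cAMP–PKA–Epac branch; phosphoinositide/PLC/IP₃/DAG/PKC dynamics; and
two-compartment (cytosol/ER) calcium handling. Key modeling assumptions,
inherited from the model family this implementation follows:

- species are well mixed within each compartment (no microdomains, no
  stochasticity — copy numbers are high enough for deterministic kinetics);
- membrane-bound species are area densities (#·μm⁻²), cytosolic and ER
  species are concentrations (μM); the geometric factor
  f_Nc = 1e6·S_c/(N_av·V_c) ≈ 0.00211 μM/(#·μm⁻²) converts between them
  where a membrane reaction produces a cytosolic product (IP₃);
- electrical activity is reduced to a single slow potential with stationary
  Boltzmann gating; action-potential spiking is out of scope, so V_p is the
  spike-envelope (plateau) potential;
- ligands are never depleted by binding: receptor occupancy enters as the
  saturating factor L/(K_L+L);
- receptor, G-protein, effector-enzyme and calmodulin totals are conserved;
  free species are computed algebraically from the totals rather than
  integrated, so conservation is exact by construction;
- constitutive (tonic) receptor activity is represented by small basal
  ligand concentrations (~1% occupancy), chosen so each Gs-coupled receptor
  keeps ~0.1 of its effector pool engaged at rest.

Units: μM, #·μm⁻², s, mV, fA, pS, fF, μm³. Current→flux conversion uses
F = 96485 C/mol and the cytosolic volume in liters:
1 fA of divalent-cation current into 764 μm³ equals 6.78·10⁻³ μM/s.

## Parameters

All constants live in `src/betacell/data/parameters.yaml` with units and a
source group; `ParameterSet` is immutable, and overrides (for
receptor-abundance scans, channel block, PDE swaps, the ATD_m lesion) are
applied functionally. Four runtime parameters (`g_mKATP`, `g_mNM3`,
`V_mPLP`, `k_ipde`) default to their tabulated basal values and are the
usual targets of timed events. Two initial values are package choices:
`cAMP_in` = 1.8 μM (no tabulated value exists; it is erased by the
equilibrate-first protocol) and `d_inact` = 0.4 μM (the IP₃-receptor
inactivation scale of the source model for that receptor, not tabulated).

The parameters that matter most for the headline behavior:

- `ATD_m` (32, dimensionless): saturating ATP/ADP ratio; reducing it to 15
  is the type-2-diabetes-like lesion.
- `K_GF` (5200 μM), `hgla` (5): glucose half-saturation and steepness of the
  metabolic response; `k_GFr` (7.4) converts FFA to glucose equivalents.
- `g_mKATPi` (24 nS) with the K_ATP open fraction (~0.01 at 3 mM glucose,
  ~0.002 at 8 mM): the dominant resting conductance and the glucose switch.
- `P_mCa` (6000 fA), `K_pCa` (0.2 μM): the only steady-state calcium exit
  from the cell; at any quiescent state the pump current must equal
  I_KATP+I_Kr+I_Nab (see "Structural identity" below).
- `V_mCaM` (2 μM/s), `K_PCaM` (0.348 μM): the CaM-stimulated membrane AC —
  the locus of glucose/incretin synergy (no Ca²⁺/CaM, no cAMP response).
- `t_pka`, `t_ep` (900 s): the slow PKA/Epac activation; stimulated steady
  states need several thousand seconds to settle.

## Reconstructed constants

Two printed constants of the L-type Ca²⁺ current are incompatible with the
model's own reported steady states and are reconstructed here. Both
reconstructions are single-character-level corrections and are the
package's deliberate design choice:

1. **Constitutive-activity constant `k_dCap` (0.01).** Printed as an
   additive floor on the activation gate, it injects ≈1.5 pA of standing
   Ca²⁺ influx at −62 mV. The plasma-membrane pump can export at most
   1.2 pA·2 at saturation, and only 2.4 pA·equivalents at the reported
   resting Ca²⁺ of 0.1 μM — with the floor, the published resting state is
   not a fixed point and integration runs away to a depolarized high-Ca
   state. Placing `k_dCap` inside the Boltzmann denominator,
   d = 1/(1+exp((V_dCa−V)/k_dCa)+k_dCap), removes the spurious influx; the
   computed basal steady state then reproduces the published resting
   potential, cytosolic and ER calcium, cAMP, PIP₂ and P4P simultaneously
   to within a few percent.
2. **Inactivation midpoint `V_fCa` (−39 mV; printed −9).** With midpoint
   −9 mV the channel barely inactivates below −20 mV; at the depolarized
   plateau that the delayed-rectifier current enforces (≈−25 mV), the
   window current is ~35 pA — several-fold beyond the pump — and the model
   has no finite high-glucose steady state. With −39 mV (one dropped
   digit) the high-glucose state is finite and lands near the published
   values (V_p ≈ −25.6 mV, Ca_c 0.223 μM, cAMP 2.23 μM, DAG 924 #·μm⁻²).
   The basal state is essentially unchanged by this correction.

## Structural identity and known deviations

At any quiescent steady state, the membrane balance (ΣI = 0), the cytosolic
calcium balance, and the ER balance (J_ser = J_rel) jointly imply

    I_PCa = I_KATP + I_Kr + I_Nab   (up to the tiny k_sg drain),

independently of the current→flux conversion. The steady cytosolic calcium
is therefore pinned by the K⁺/Na⁺ currents at the operating potential. Two
published values cannot be met under this identity with the printed
parameters, and the corresponding checks are left failing rather than
tuned:

- the high-glucose Ca_c comes out 0.223 μM against a reported 0.272 μM
  (−18%), and the GLP-1-stimulated Ca_c 0.232 against 0.302; DAG scales
  with the same gap (924 vs 1131 #·μm⁻²). The directions and relative
  changes (ER discharge under GLP-1, DAG drop under M3-receptor knockdown)
  are reproduced.
- the NALCN scenarios: with the printed pre-coupling constants
  (k₂/k₂r = 0.1 μm²/#, G6t = 20) the basal ligand-bound M3 complex is
  LRG6 ≈ 0.19 #·μm⁻², so enabling g_mNM3 = 35 nS gives ≈6.7 nS of standing
  Na⁺ conductance and the "no-agonist" baseline is already pinned near the
  delayed-rectifier wall. The published protocol (NALCN-enabled baseline at
  rest, depolarization only upon acetylcholine) is unreachable with these
  constants under any parse we found, so the cAMP fold-change checks of
  that scenario fail (measured ≈0.7× instead of 4.8×/24×). Likewise the
  ATD_m = 15 lesion still depolarizes at 8 mM in this implementation (its
  K_ATP conductance falls below the resting requirement), so the
  "no response until K_ATP block" signature is not reproduced.

## Numerics

- Stiff integration with `scipy.integrate.solve_ivp(method="BDF")`,
  rtol 1e-8 and per-variable absolute tolerances (state magnitudes span
  1e-3…1e5). Timed events are integration breakpoints: the solver restarts
  with updated inputs/parameters, giving exact step discontinuities.
- The right-hand side is kept smooth: conservation closures clamp at zero
  (instead of raising) inside the RHS because implicit solvers probe
  out-of-region trial states; strict closure checking
  (`model.check_closures`) runs on every accepted trajectory sample.
  Round-off negatives are tolerated in the RHS (the mass-action form is
  self-correcting) — clipping at zero would place derivative kinks exactly
  where trajectories graze zero and collapse step sizes.
- Steady states: chunked integration (2000 s per chunk, cap 50 000 s)
  until the scaled derivative norm is small, with a Newton polish
  (`scipy.optimize.root`, hybr) accepted only if non-negative and close to
  the integrated state. The polish removes the slow receptor-recycling
  tail (time constant 1/k_8n = 2·10⁴ s) that pure integration would need
  >10⁵ model seconds to relax. Non-converged (cycling) cases return a
  time-averaged state with an `oscillatory` flag.
- Stimulated protocols equilibrate at their initial inputs before t = 0
  (`steady_state_first`), matching the equilibrate-then-stimulate design of
  the scenario presets; halving solver tolerances moves reported steady
  values by <0.1% (tested).

## Scope and limitations

Insulin-granule exocytosis, spiking electrical activity, K_Ca and Na⁺/Ca²⁺
exchange currents, mitochondrial calcium, PDE isoform inventories and
compartmentalized cAMP are outside the model. The parameter set describes
an "average" rodent β-cell; species differences (notably the rat-like PDE
composition scenario) are represented only by the documented parameter
swaps. All quantitative claims in this note are computed by the test suite
or by `scripts/acceptance.py`.
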