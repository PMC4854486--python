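"""Assembly of the full ODE system.

The model state is a flat vector of 43 variables: the metabolic ATP/ADP
ratio, the membrane potential, six bound species for each of the five
receptor cascades, and the second-messenger block (CaCaM, cAMP, PKA, Epac,
lipids, IP₃, DAG, PKC, cytosolic and ER calcium).  Everything else —
free receptors/G-proteins/enzymes, calmodulin species, currents, fluxes —
is algebraic and recomputed from the state.

External inputs (glucose, FFA and the five receptor ligands) are a plain
mapping; timed step protocols are handled by the engine, which re-invokes
the derivative function with updated inputs/parameters after each event.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from . import calcium, camp, currents, lipids, metabolism, receptors
from .params import ParameterSet, UnitContext

__all__ = [
    "check_closures",
    "STATE_NAMES",
    "STATE_INDEX",
    "INPUT_NAMES",
    "default_inputs",
    "table_initial_state",
    "assemble_derivatives",
    "derived_quantities",
    "DERIVED_NAMES",
]

_CASCADE_STATE_NAMES = {
    "GLP1R": ("LR1", "LRG1", "ReGLd", "GaT1", "GaD1", "ACGLP"),
    "GIPR": ("LR2", "LRG2", "ReGId", "GaT2", "GaD2", "ACGIP"),
    "A2AR": ("LR3", "LRG3", "ReARd", "GaT3", "GaD3", "ACAR"),
    "M3R": ("RG6", "LRG6", "ReM3d", "GaT6", "GaD6", "PLCM3"),
    "FFAR1": ("LR7", "LRG7", "ReR40d", "GaT7", "GaD7", "PLCR40"),
}

STATE_NAMES: tuple[str, ...] = (
    ("ATD", "Vp")
    + tuple(n for spec in receptors.RECEPTORS
            for n in _CASCADE_STATE_NAMES[spec.name])
    + ("CaCaM", "cAMP", "PKAa", "EPa",
       "P4P", "PIP2", "IP3", "DAG", "PKCa", "Cac", "CaER")
)

STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}

N_STATES = len(STATE_NAMES)

INPUT_NAMES: tuple[str, ...] = ("Glu", "FFA", "GLP1", "GIP", "AR3", "AM3", "AR7")

_INPUT_BASALS = {
    "Glu": "Glu_i", "FFA": "FFA_i", "GLP1": "GLP1i", "GIP": "GIPi",
    "AR3": "AR3i", "AM3": "AM3i", "AR7": "AR7i",
}

# names that should never go negative (all but the membrane potential)
_NONNEG = np.array([name != "Vp" for name in STATE_NAMES])


def default_inputs(p: ParameterSet) -> dict[str, float]:
    """Basal inputs: low glucose, no FFA, constitutive ligand levels."""
    return {name: p[param] for name, param in _INPUT_BASALS.items()}


def table_initial_state(p: ParameterSet) -> np.ndarray:
    """Tabulated basal initial conditions as a state vector."""
    x = np.empty(N_STATES)
    x[STATE_INDEX["ATD"]] = p.ATD_in
    x[STATE_INDEX["Vp"]] = p.Vp_in
    for spec in receptors.RECEPTORS:
        s0 = spec.initial_state(p)
        for name, value in zip(_CASCADE_STATE_NAMES[spec.name], s0):
            x[STATE_INDEX[name]] = value
    for name, param in (("CaCaM", "CaCaM_in"), ("cAMP", "cAMP_in"),
                        ("PKAa", "PKAa_in"), ("EPa", "EPa_in"),
                        ("P4P", "P4P_in"), ("PIP2", "PIP2_in"),
                        ("IP3", "IP3_in"), ("DAG", "DAG_in"),
                        ("PKCa", "PKCa_in"), ("Cac", "Cac_in"),
                        ("CaER", "CaER_in")):
        x[STATE_INDEX[name]] = p[param]
    return x


def _clip_state(y: np.ndarray) -> np.ndarray:
    """Guard against far-out-of-region solver trial states.

    Small round-off negatives are left untouched: the mass-action right-hand
    side is polynomial/rational, self-correcting for them, and clipping at
    zero would put derivative kinks exactly where trajectories graze zero,
    collapsing stiff-solver step sizes.  Only clearly unphysical excursions
    (beyond −1e-6 of a species' scale) are projected back.
    """
    y = np.asarray(y, dtype=float)
    mask = _NONNEG & (y < -1e-6 * (1.0 + np.abs(y)))
    if mask.any():
        y = y.copy()
        y[mask] = 0.0
    return y


def _cascade_slices(y: np.ndarray):
    states = {}
    for spec in receptors.RECEPTORS:
        names = _CASCADE_STATE_NAMES[spec.name]
        states[spec.name] = receptors.CascadeState(
            *(y[STATE_INDEX[n]] for n in names))
    return states


def assemble_derivatives(t: float, y: np.ndarray, inputs: Mapping[str, float],
                         p: ParameterSet,
                         ctx: UnitContext | None = None) -> np.ndarray:
    """Full right-hand side dy/dt for the flat state vector ``y``.

    Module operations are called in dependency order: metabolism, membrane
    gating, cascades with shared-pool closure, calmodulin/cAMP, lipids and
    calcium.  ``t`` is unused (inputs are piecewise-constant between engine
    events) but kept for the ODE-solver signature.
    """
    if ctx is None:
        ctx = UnitContext.from_parameters(p)
    y = _clip_state(y)
    dy = np.zeros(N_STATES)
    ix = STATE_INDEX

    ATD, Vp = y[ix["ATD"]], y[ix["Vp"]]
    CaCaM, cAMP = y[ix["CaCaM"]], y[ix["cAMP"]]
    PKAa, EPa = y[ix["PKAa"]], y[ix["EPa"]]
    P4P, PIP2, IP3 = y[ix["P4P"]], y[ix["PIP2"]], y[ix["IP3"]]
    DAG, PKCa = y[ix["DAG"]], y[ix["PKCa"]]
    Cac, CaER = y[ix["Cac"]], y[ix["CaER"]]

    # metabolism ----------------------------------------------------------
    dy[ix["ATD"]] = metabolism.d_atd(ATD, inputs["Glu"], inputs["FFA"], p)
    nuc = metabolism.nucleotide_partition(ATD, PKAa, p)

    # receptor cascades with shared effector pools ------------------------
    cascades = _cascade_slices(y)
    ac = receptors.ac_pool_partition(cascades["GLP1R"].GE, cascades["GIPR"].GE,
                                     cascades["A2AR"].GE, p, strict=False)
    plc = receptors.plc_pool_partition(cascades["M3R"].GE, cascades["FFAR1"].GE,
                                       p, strict=False)
    pool_free = {"AC": ac.AC_pf, "PLC": plc.PLC_pf}
    for spec in receptors.RECEPTORS:
        ds = receptors.cascade_derivatives(
            spec, cascades[spec.name], inputs[spec.ligand],
            pool_free[spec.pool], p, strict=False)
        for name, value in zip(_CASCADE_STATE_NAMES[spec.name], ds):
            dy[ix[name]] = value

    # membrane potential --------------------------------------------------
    O_KATP = currents.katp_open_fraction(nuc.MgADP_f, nuc.ATP, p)
    I = currents.membrane_currents(
        Vp, PIP2, O_KATP, Cac, CaER, cascades["M3R"].LRG,
        g_mKATP=p.g_mKATP, g_mNM3=p.g_mNM3, p=p)
    dy[ix["Vp"]] = currents.d_vp(I, p)

    # calmodulin and cAMP branch ------------------------------------------
    cam = camp.calmodulin_species(Cac, CaCaM, p, strict=False)
    dy[ix["CaCaM"]] = p.k_1f * Cac * cam.CaM - p.k_1b * CaCaM
    V_ACp = camp.v_acp(ac.AC_par, cam.CaMa, Cac, p)
    V_ACc = camp.v_acc(nuc.ATP, Cac, p)
    V_PDE = camp.v_pde(cam.CaMa, cAMP, p.k_ipde, p)
    dy[ix["cAMP"]] = camp.d_camp(V_ACp, V_ACc, V_PDE, cAMP, p)
    dy[ix["PKAa"]] = camp.d_pka(PKAa, cAMP, p)
    dy[ix["EPa"]] = camp.d_epac(EPa, cAMP, p)

    # lipids and PLC ------------------------------------------------------
    fPI = lipids.f_pi(Cac, PKCa, p)
    act = lipids.v_pl(Cac, plc.PLC_pa, p.V_mPLP, p)
    fP2 = lipids.f_pip2(PIP2, p)
    dy[ix["P4P"]] = lipids.d_p4p(P4P, PIP2, fPI, p)
    dy[ix["PIP2"]] = lipids.d_pip2(PIP2, P4P, act.V_PL, p)
    dy[ix["IP3"]] = lipids.d_ip3(IP3, act.V_PL, fP2, ctx.f_Nc, p)
    dy[ix["DAG"]] = lipids.d_dag(DAG, act.V_PL, fP2, p)
    dy[ix["PKCa"]] = lipids.d_pkca(PKCa, DAG, p)

    # calcium -------------------------------------------------------------
    flux = calcium.calcium_fluxes(Cac, CaER, IP3, PKAa, p)
    dy[ix["Cac"]] = calcium.d_cac(I.I_Ca, I.I_SOC, I.I_PCa,
                                  flux.J_ser, flux.J_rel, Cac, ctx, p)
    dy[ix["CaER"]] = calcium.d_caer(flux.J_ser, flux.J_rel, ctx, p)
    return dy


DERIVED_NAMES: tuple[str, ...] = (
    "I_KATP", "I_Kr", "I_Ca", "I_SOC", "I_PCa", "I_Nab",
    "O_KATP", "ATP", "ADP_f", "MgADP_f",
    "AC_pf", "AC_pa", "AC_par", "PLC_pf", "PLC_pa",
    "CaMa", "V_ACp", "V_ACc", "V_PDE",
    "V_PL", "V_PLP", "V_PLC",
    "J_ser", "J_rel", "P_RIP3",
)


def derived_quantities(y: np.ndarray, inputs: Mapping[str, float],
                       p: ParameterSet,
                       ctx: UnitContext | None = None) -> dict[str, float]:
    """Algebraic quantities (currents, rates, fluxes) at one state."""
    if ctx is None:
        ctx = UnitContext.from_parameters(p)
    y = _clip_state(y)
    ix = STATE_INDEX
    cascades = _cascade_slices(y)
    ac = receptors.ac_pool_partition(cascades["GLP1R"].GE, cascades["GIPR"].GE,
                                     cascades["A2AR"].GE, p, strict=False)
    plc = receptors.plc_pool_partition(cascades["M3R"].GE, cascades["FFAR1"].GE,
                                       p, strict=False)
    nuc = metabolism.nucleotide_partition(y[ix["ATD"]], y[ix["PKAa"]], p)
    O_KATP = currents.katp_open_fraction(nuc.MgADP_f, nuc.ATP, p)
    I = currents.membrane_currents(
        y[ix["Vp"]], y[ix["PIP2"]], O_KATP, y[ix["Cac"]], y[ix["CaER"]],
        cascades["M3R"].LRG, g_mKATP=p.g_mKATP, g_mNM3=p.g_mNM3, p=p)
    cam = camp.calmodulin_species(y[ix["Cac"]], y[ix["CaCaM"]], p, strict=False)
    act = lipids.v_pl(y[ix["Cac"]], plc.PLC_pa, p.V_mPLP, p)
    flux = calcium.calcium_fluxes(y[ix["Cac"]], y[ix["CaER"]], y[ix["IP3"]],
                                  y[ix["PKAa"]], p)
    return {
        "I_KATP": I.I_KATP, "I_Kr": I.I_Kr, "I_Ca": I.I_Ca,
        "I_SOC": I.I_SOC, "I_PCa": I.I_PCa, "I_Nab": I.I_Nab,
        "O_KATP": O_KATP, "ATP": nuc.ATP, "ADP_f": nuc.ADP_f,
        "MgADP_f": nuc.MgADP_f,
        "AC_pf": ac.AC_pf, "AC_pa": ac.AC_pa, "AC_par": ac.AC_par,
        "PLC_pf": plc.PLC_pf, "PLC_pa": plc.PLC_pa,
        "CaMa": cam.CaMa,
        "V_ACp": camp.v_acp(ac.AC_par, cam.CaMa, y[ix["Cac"]], p),
        "V_ACc": camp.v_acc(nuc.ATP, y[ix["Cac"]], p),
        "V_PDE": camp.v_pde(cam.CaMa, y[ix["cAMP"]], p.k_ipde, p),
        "V_PL": act.V_PL, "V_PLP": act.V_PLP, "V_PLC": act.V_PLC,
        "J_ser": flux.J_ser, "J_rel": flux.J_rel, "P_RIP3": flux.P_RIP3,
    }


def check_closures(y: np.ndarray, p: ParameterSet, t: float | None = None) -> None:
    """Strictly verify every conservation closure at a state.

    Raises :class:`betacell.receptors.ConservationError` (or ``ValueError``
    for calmodulin) naming the violated pool.  The engine applies this to
    accepted trajectory samples; the derivative evaluation itself uses
    clamped closures so that implicit-solver trial states do not abort the
    integration.
    """
    y = np.asarray(y, dtype=float)
    cascades = _cascade_slices(y)
    for spec in receptors.RECEPTORS:
        receptors.free_receptor(spec, cascades[spec.name], p, strict=True)
        receptors.free_gprotein(spec, cascades[spec.name], p, strict=True)
    receptors.ac_pool_partition(cascades["GLP1R"].GE, cascades["GIPR"].GE,
                                cascades["A2AR"].GE, p, strict=True)
    receptors.plc_pool_partition(cascades["M3R"].GE, cascades["FFAR1"].GE,
                                 p, strict=True)
    camp.calmodulin_species(y[STATE_INDEX["Cac"]], y[STATE_INDEX["CaCaM"]],
                            p, strict=True)
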