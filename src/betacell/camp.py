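"""Calmodulin equilibria and the cAMP/PKA/Epac branch.

Ca²⁺ binds calmodulin in four sequential steps; only the first binding step
is integrated (it is the slowest), and the higher-occupancy species are
slaved to it through equilibrium ratios.  Calmodulin with at least three
bound Ca²⁺ (``CaMa``) is the active form that stimulates both the
membrane-bound adenylyl cyclase (AC_p, G-protein gated) and the
calmodulin-dependent phosphodiesterase.  A soluble cyclase (AC_c) adds
glucose/Ca²⁺-driven synthesis independent of G-proteins.  PKA and Epac
relax toward Hill-type functions of cAMP.
"""

from __future__ import annotations

from typing import NamedTuple

from .params import ParameterSet

__all__ = [
    "CalmodulinSpecies",
    "calmodulin_species",
    "d_cacam",
    "v_acp",
    "v_acc",
    "v_pde",
    "d_camp",
    "d_pka",
    "d_epac",
]


class CalmodulinSpecies(NamedTuple):
    CaM: float     # apo-calmodulin, μM
    Ca2CaM: float
    Ca3CaM: float
    Ca4CaM: float
    CaMa: float    # active fraction: Ca3CaM + Ca4CaM


def calmodulin_species(Ca_c: float, CaCaM: float, p: ParameterSet,
                       strict: bool = True) -> CalmodulinSpecies:
    """Equilibrium calmodulin species given Ca_c and the integrated CaCaM.

    The total CaMo is conserved by closure.  In strict mode a CaCaM
    exceeding the total raises; at high Ca²⁺ the slaved higher-occupancy
    species can transiently overfill the pool, in which case apo-CaM clamps
    at zero and the CaCaM ODE (pure dissociation when CaM = 0) restores the
    balance.
    """
    if strict and CaCaM > p.CaMo * (1.0 + 1e-6):
        raise ValueError(
            f"calmodulin closure violated: CaCaM = {CaCaM:.3g} μM exceeds "
            f"the total CaMo = {p.CaMo:.3g} μM")
    CaCaM = min(CaCaM, p.CaMo)
    Ca2 = (p.k_2f / p.k_2b) * Ca_c * CaCaM
    Ca3 = (p.k_3f / p.k_3b) * Ca_c * Ca2
    Ca4 = (p.k_4f / p.k_4b) * Ca_c * Ca3
    CaM = max(p.CaMo - CaCaM - Ca2 - Ca3 - Ca4, 0.0)
    return CalmodulinSpecies(CaM=CaM, Ca2CaM=Ca2, Ca3CaM=Ca3,
                             Ca4CaM=Ca4, CaMa=Ca3 + Ca4)


def d_cacam(Ca_c: float, CaCaM: float, p: ParameterSet) -> float:
    """dCaCaM/dt = k_1f·Ca_c·CaM − k_1b·CaCaM (μM/s)."""
    CaM = calmodulin_species(Ca_c, CaCaM, p).CaM
    return p.k_1f * Ca_c * CaM - p.k_1b * CaCaM


def v_acp(AC_par: float, CaMa: float, Ca_c: float, p: ParameterSet) -> float:
    """Membrane AC rate: V_mCaM·f_acca·AC_par (μM/s).

    f_acca couples activation by active calmodulin with inhibition by very
    high Ca²⁺ (K_NCa = 75 μM, far above physiological cytosolic levels).
    """
    f_acca = (CaMa / (CaMa + p.K_PCaM)) * (p.K_NCa / (p.K_NCa + Ca_c))
    return p.V_mCaM * f_acca * AC_par


def v_acc(ATP: float, Ca_c: float, p: ParameterSet) -> float:
    """Soluble AC rate, Michaelis–Menten in ATP and Ca²⁺ plus a
    constitutive floor k_ACS (μM/s)."""
    return (p.V_mACc * (ATP / (ATP + p.K_mAACS))
            * (Ca_c / (Ca_c + p.K_mCACS)) + p.k_ACS)


def v_pde(CaMa: float, cAMP: float, k_ipde: float, p: ParameterSet) -> float:
    """Phosphodiesterase rate (μM/s): a Ca/CaM-independent component V_gpde
    plus a CaMa-activated component V_cpde, both saturating in cAMP, and a
    global inhibition/activation scale k_ipde."""
    return (k_ipde * (p.V_gpde + p.V_cpde * CaMa / (CaMa + p.K_dpe))
            * cAMP / (cAMP + p.K_pde))


def d_camp(V_ACp: float, V_ACc: float, V_PDE: float, cAMP: float,
           p: ParameterSet) -> float:
    """dcAMP/dt = synthesis − PDE hydrolysis − first-order loss (μM/s)."""
    return V_ACp + V_ACc - V_PDE - p.k_da * cAMP


def _hill(x: float, K: float, h: float) -> float:
    if x <= 0.0:
        return 0.0
    xh = (x / K) ** h
    return xh / (1.0 + xh)


def d_pka(PKAa: float, cAMP: float, p: ParameterSet) -> float:
    """Relaxation of active PKA toward its cAMP-driven target (s⁻¹).

    dPKAa/dt = k_ak·(f_pca·(1−PKAa) − PKAa)/t_pka keeps PKAa in [0, 1]; the
    steady level is f_pca/(1 + f_pca).
    """
    f_pca = _hill(cAMP, p.K_pcm, p.hpca)
    return p.k_ak * (f_pca * (1.0 - PKAa) - PKAa) / p.t_pka


def d_epac(EPa: float, cAMP: float, p: ParameterSet) -> float:
    """Epac activation, same form as PKA with its own (weaker) cAMP
    affinity K_mep and Hill coefficient hce."""
    f_eca = _hill(cAMP, p.K_mep, p.hce)
    return (f_eca * (1.0 - EPa) - EPa) / p.t_ep
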