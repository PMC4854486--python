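"""Cytosolic and ER free-calcium balance.

The cytosolic equation collects plasma-membrane fluxes (L-type and
store-operated entry, pump extrusion) converted from currents to μM/s, ER
release through the PKA-sensitized IP₃ receptor plus a passive leak, SERCA
uptake, and a small first-order sequestration drain.  Both fluxes J_ser and
J_rel are expressed on the cytosol-volume basis (μM of cytosol per second);
the ER equation rescales them by V_c/V_ER so that total calcium
(V_c·Ca_c/f_cf + V_ER·Ca_ER/f_er) is conserved in the exchange-only limit.

The IP₃-receptor open probability follows the cubic activation/inactivation
form with Ca²⁺ activation, IP₃ activation (PKA lowers the effective IP₃
constant through f_IPKA = 1/(PKAa + K_IP3R)) and Ca²⁺ inactivation at high
concentrations (scale d_inact).
"""

from __future__ import annotations

from typing import NamedTuple

from .params import ParameterSet, UnitContext

__all__ = [
    "j_serca",
    "ip3r_open_probability",
    "j_rel",
    "CalciumFluxes",
    "calcium_fluxes",
    "d_cac",
    "d_caer",
]


class CalciumFluxes(NamedTuple):
    J_ser: float    # μM/s, cytosol basis
    J_rel: float    # μM/s, cytosol basis (positive: ER -> cytosol)
    P_RIP3: float   # IP3R open probability
    f_IPKA: float


def j_serca(Ca_c: float, p: ParameterSet) -> float:
    """SERCA uptake P_CaER·Ca_c²/(K_ser² + Ca_c²), μM/s on cytosol basis."""
    c2 = Ca_c * Ca_c
    return p.P_CaER * c2 / (p.K_ser ** 2 + c2)


def ip3r_open_probability(Ca_c: float, IP3: float, PKAa: float,
                          p: ParameterSet) -> float:
    """Open probability of the IP₃ receptor channel.

    Product of cubed activation by Ca²⁺ and IP₃ and cubed inactivation at
    high Ca²⁺.  Active PKA increases IP₃ sensitivity by shrinking the
    effective activation constant f_IPKA·K_IP3.
    """
    f_IPKA = 1.0 / (PKAa + p.K_IP3R)
    act_ca = Ca_c / (p.K_RPCa + Ca_c)
    act_ip3 = IP3 / (f_IPKA * p.K_IP3 + IP3)
    inact = p.d_inact / (p.d_inact + Ca_c)
    return (act_ca * act_ip3 * inact) ** 3


def j_rel(Ca_c: float, Ca_ER: float, P_RIP3: float, p: ParameterSet) -> float:
    """ER→cytosol release (k_mIP·P_RIP3 + k_leak)·(Ca_ER − Ca_c), μM/s."""
    return (p.k_mIP * P_RIP3 + p.k_leak) * (Ca_ER - Ca_c)


def calcium_fluxes(Ca_c: float, Ca_ER: float, IP3: float, PKAa: float,
                   p: ParameterSet) -> CalciumFluxes:
    P = ip3r_open_probability(Ca_c, IP3, PKAa, p)
    return CalciumFluxes(
        J_ser=j_serca(Ca_c, p),
        J_rel=j_rel(Ca_c, Ca_ER, P, p),
        P_RIP3=P,
        f_IPKA=1.0 / (PKAa + p.K_IP3R),
    )


def d_cac(I_Ca: float, I_SOC: float, I_PCa: float, J_ser: float, J_rel: float,
          Ca_c: float, ctx: UnitContext, p: ParameterSet) -> float:
    """dCa_c/dt (μM/s).

    The membrane term converts (−I_Ca − I_SOC − 2·I_PCa) from fA to μM/s
    through 1/(2F·V_c); inward (negative) Ca²⁺ currents raise Ca_c.  The
    buffering fraction f_cf scales all fluxes; k_sg is a slow sequestration
    drain.
    """
    pm_flux = ctx.current_to_flux(-I_Ca - I_SOC - 2.0 * I_PCa, z=2)
    return p.f_cf * (pm_flux + J_rel - J_ser) - p.k_sg * Ca_c


def d_caer(J_ser: float, J_rel: float, ctx: UnitContext, p: ParameterSet) -> float:
    """dCa_ER/dt (μM/s); fluxes rescaled to the ER volume for mass balance."""
    return p.f_er * (J_ser - J_rel) * (ctx.V_c / ctx.V_ER)
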