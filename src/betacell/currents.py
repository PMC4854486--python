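"""Plasma-membrane currents and the slow potential balance.

Six whole-cell currents are modeled with stationary (Boltzmann/Hill) gating,
deliberately excluding millisecond spike activity: the ATP-sensitive K⁺
current (PIP₂- and PKA-modulated), a delayed-rectifier K⁺ current, an L-type
Ca²⁺ current with one inactivation gate, a store-operated cation current
driven by ER Ca²⁺ depletion, the plasma-membrane Ca²⁺ pump, and a Na⁺
background current whose conductance grows with ligand-bound M3 receptor
(NALCN channels).  Sign convention: outward positive, so
dV_p/dt = −ΣI/C_m.
"""

from __future__ import annotations

import math
from typing import NamedTuple

from .params import ParameterSet

__all__ = [
    "katp_open_fraction",
    "current_ikatp",
    "current_ikr",
    "current_ica",
    "current_isoc",
    "current_ipca",
    "current_inab",
    "membrane_currents",
    "d_vp",
    "CurrentBreakdown",
]


class CurrentBreakdown(NamedTuple):
    """Per-channel currents in fA (outward positive)."""
    I_KATP: float
    I_Kr: float
    I_Ca: float
    I_SOC: float
    I_PCa: float
    I_Nab: float

    @property
    def total(self) -> float:
        return sum(self)


def _boltzmann(V: float, V_half: float, slope: float) -> float:
    return 1.0 / (1.0 + math.exp((V_half - V) / slope))


def katp_open_fraction(MgADP_f: float, ATP_f: float, p: ParameterSet) -> float:
    """Open fraction of K_ATP channels from free MgADP and free ATP.

    The adopted kinetic form is not normalized to 1; it evaluates to 0.08
    with no nucleotides bound and rises with MgADP (which relieves ATP
    block) while ATP occupancy closes the channel.
    """
    m = MgADP_f / p.k_dd
    num = 0.08 * (1.0 + 2.0 * m) + 0.89 * m * m
    den = (1.0 + m) ** 2 * (1.0 + 0.45 * MgADP_f / p.k_td + ATP_f / p.k_tt)
    return num / den


def current_ikatp(V_p: float, PIP2: float, O_KATP: float, g_mKATP: float,
                  p: ParameterSet) -> float:
    """I_KATP = g_mKATP·f_KPI·O_KATP·(V_p − E_K); PIP₂ enhances the current."""
    f_KPI = PIP2 / (PIP2 + p.K_KPI2)
    return g_mKATP * f_KPI * O_KATP * (V_p - p.E_K)


def current_ikr(V_p: float, p: ParameterSet) -> float:
    """Delayed-rectifier K⁺ current with stationary activation squared."""
    d_Kri = _boltzmann(V_p, p.V_dKr, p.k_dKr)
    f_Kri = 1.0  # inactivation negligible on the modeled time scales
    return p.g_mKr * d_Kri * d_Kri * f_Kri * (V_p - p.E_K)


def current_ica(V_p: float, p: ParameterSet) -> float:
    """L-type Ca²⁺ current with stationary activation and one stationary
    inactivation gate.

    The small constitutive-activity constant k_dCap sits inside the
    activation denominator, d = 1/(1 + exp((V_dCa−V)/k_dCa) + k_dCap): an
    additive floor instead would inject ~1.5 pA of standing Ca²⁺ influx at
    rest, more than the plasma-membrane pump can export at the reported
    resting Ca²⁺, and the model would have no resting state (see
    docs/methods.md).
    """
    d_Cai = 1.0 / (1.0 + math.exp((p.V_dCa - V_p) / p.k_dCa) + p.k_dCap)
    f_Cai = 1.0 / (1.0 + math.exp(-(p.V_fCa - V_p) / p.k_fCa))
    return p.g_mCa * d_Cai * f_Cai * (V_p - p.E_Ca)


def current_isoc(V_p: float, Ca_ER: float, p: ParameterSet) -> float:
    """Store-operated current, gated by ER Ca²⁺ depletion (Hill n=4)."""
    k4 = p.K_NS ** 4
    f_SOC = k4 / (k4 + Ca_ER ** 4)
    return p.g_mSOC * f_SOC * (V_p - p.E_Ca)


def current_ipca(Ca_c: float, p: ParameterSet) -> float:
    """Plasma-membrane Ca²⁺ pump current (outward, saturating in Ca_c)."""
    c2 = Ca_c * Ca_c
    return p.P_mCa * c2 / (p.K_pCa ** 2 + c2)


def current_inab(V_p: float, LRG6: float, g_mNM3: float, p: ParameterSet) -> float:
    """Voltage-independent Na⁺ background current; the NALCN component is
    proportional to ligand/G-protein-bound M3 receptor density."""
    g_Nab = p.g_mNb + g_mNM3 * LRG6
    return g_Nab * (V_p - p.E_Na)


def membrane_currents(V_p: float, PIP2: float, O_KATP: float, Ca_c: float,
                      Ca_ER: float, LRG6: float, g_mKATP: float,
                      g_mNM3: float, p: ParameterSet) -> CurrentBreakdown:
    return CurrentBreakdown(
        I_KATP=current_ikatp(V_p, PIP2, O_KATP, g_mKATP, p),
        I_Kr=current_ikr(V_p, p),
        I_Ca=current_ica(V_p, p),
        I_SOC=current_isoc(V_p, Ca_ER, p),
        I_PCa=current_ipca(Ca_c, p),
        I_Nab=current_inab(V_p, LRG6, g_mNM3, p),
    )


def d_vp(currents: CurrentBreakdown, p: ParameterSet) -> float:
    """dV_p/dt = −ΣI/C_m (mV/s); net outward current hyperpolarizes."""
    return -currents.total / p.C_m
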