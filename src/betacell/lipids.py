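"""Phosphoinositide pools, phospholipase C activity, IP₃/DAG/PKC.

P4P is made from a large constant PI reservoir (PKC- and Ca²⁺-stimulated)
and interconverts with PIP₂.  Total PLC activity sums a G-protein-coupled
membrane isoform (PLC_p, driven by the occupied fraction of the shared
enzyme pool and by Ca²⁺), a cytosolic Ca²⁺-activated isoform (PLC_c), and a
constitutive floor.  PIP₂ hydrolysis produces IP₃ (converted to a cytosolic
concentration through f_Nc) and DAG (which stays membrane-bound)
stoichiometrically; DAG activates PKC, which feeds back on P4P synthesis.

Membrane rates (V_PL and friends) are in #·μm⁻²·s⁻¹; only the IP₃
production term crosses to μM/s via f_Nc.
"""

from __future__ import annotations

from typing import NamedTuple

from .params import ParameterSet

__all__ = [
    "f_pi",
    "d_p4p",
    "f_pip2",
    "v_pl",
    "PLCActivity",
    "d_pip2",
    "d_ip3",
    "d_dag",
    "d_pkca",
]


class PLCActivity(NamedTuple):
    V_PL: float    # total, #·μm⁻²·s⁻¹
    V_PLP: float   # G-protein-coupled membrane isoform
    V_PLC: float   # cytosolic Ca²⁺-activated isoform


def _hill2(x: float, K: float) -> float:
    x2 = x * x
    return x2 / (x2 + K * K)


def f_pi(Ca_c: float, PKCa: float, p: ParameterSet) -> float:
    """PKC/Ca²⁺ activation factor for P4P synthesis, with constitutive
    floor k_cpi."""
    return _hill2(Ca_c, p.K_CaPI) * _hill2(PKCa, p.K_P4PK) + p.k_cpi


def d_p4p(P4P: float, PIP2: float, f_PI: float, p: ParameterSet) -> float:
    """dP4P/dt (#·μm⁻²·s⁻¹): synthesis from PI, back-flux from PIP₂,
    dephosphorylation and forward phosphorylation to PIP₂."""
    return (p.k_PI * f_PI * p.PI + p.k_P4Pr * PIP2
            - p.k_PIr * P4P - p.k_P4P * P4P)


def f_pip2(PIP2: float, p: ParameterSet) -> float:
    """Saturating availability of PIP₂ to PLC."""
    return PIP2 / (p.K_PIP2 + PIP2)


def v_pl(Ca_c: float, PLC_pa: float, V_mPLP: float, p: ParameterSet) -> PLCActivity:
    """Total PLC activity and its isoform breakdown.

    V_PLP scales with the G-protein-occupied fraction of the PLC_p pool and
    a Ca²⁺ Hill term (K_CaPL = 0.4 μM); V_PLC depends on Ca²⁺ only, with
    higher affinity (K_CCaPL = 0.2 μM); k_pPL is constitutive.
    """
    V_PLP = V_mPLP * (PLC_pa / p.PLC_pt) * _hill2(Ca_c, p.K_CaPL)
    V_PLC = p.V_mPLC * _hill2(Ca_c, p.K_CCaPL)
    return PLCActivity(V_PL=V_PLP + V_PLC + p.k_pPL, V_PLP=V_PLP, V_PLC=V_PLC)


def d_pip2(PIP2: float, P4P: float, V_PL: float, p: ParameterSet) -> float:
    """dPIP₂/dt (#·μm⁻²·s⁻¹): production from P4P minus PLC hydrolysis and
    back-flux to P4P."""
    return p.k_P4P * P4P - f_pip2(PIP2, p) * V_PL - p.k_P4Pr * PIP2


def d_ip3(IP3: float, V_PL: float, f_PIP2: float, f_Nc: float,
          p: ParameterSet) -> float:
    """dIP₃/dt (μM/s): membrane production rescaled by f_Nc, first-order
    degradation."""
    return V_PL * f_Nc * f_PIP2 - p.k_dIP3 * IP3


def d_dag(DAG: float, V_PL: float, f_PIP2: float, p: ParameterSet) -> float:
    """dDAG/dt (#·μm⁻²·s⁻¹): produced stoichiometrically with IP₃ but
    remains membrane-bound (no f_Nc)."""
    return V_PL * f_PIP2 - p.k_dDAG * DAG


def d_pkca(PKCa: float, DAG: float, p: ParameterSet) -> float:
    """Active PKC fraction: DAG recruits inactive PKC, first-order
    deactivation; bounded in [0, 1] by construction."""
    return p.k_PKC * DAG * (1.0 - PKCa) - p.k_PKCr * PKCa
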