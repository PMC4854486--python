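"""Glucose/FFA-driven adenine-nucleotide kinetics.

The ATP/ADP ratio (``ATD``) is the single metabolic state variable.  It
relaxes first-order toward a Hill-type target set by extracellular glucose
and free fatty acid; the FFA contribution is folded into a glucose-equivalent
concentration through the scaling coefficient ``k_GFr``.  Total adenine
nucleotide ``AT`` is conserved, which fixes free ATP and ADP algebraically,
and PKA phosphorylation of the K_ATP channel's SUR1 subunit lowers the
effective free MgADP seen by the channel.
"""

from __future__ import annotations

from typing import NamedTuple

from .params import ParameterSet

__all__ = [
    "atd_target",
    "d_atd",
    "nucleotide_partition",
    "NucleotideState",
]


class NucleotideState(NamedTuple):
    ATP: float      # μM
    ADP_f: float    # μM free ADP
    MgADP_f: float  # μM free Mg-bound ADP after PKA modulation
    f_KPKa: float   # PKA attenuation factor in (0, 1]


def glucose_equivalent(Glu: float, FFA: float, p: ParameterSet) -> float:
    """Glucose-equivalent nutrient concentration Glu + k_GFr·FFA (μM)."""
    if Glu < 0 or FFA < 0:
        raise ValueError("nutrient concentrations must be >= 0")
    return Glu + p.k_GFr * FFA


def atd_target(Glu: float, FFA: float, p: ParameterSet) -> float:
    """Saturating ATP/ADP target ATD_m·G^h/(G^h + K_GF^h)."""
    G = glucose_equivalent(Glu, FFA, p)
    if G == 0.0:
        return 0.0
    gh = (G / p.K_GF) ** p.hgla
    return p.ATD_m * gh / (gh + 1.0)


def d_atd(ATD: float, Glu: float, FFA: float, p: ParameterSet) -> float:
    """First-order relaxation rate of the ATP/ADP ratio (s⁻¹)."""
    return (atd_target(Glu, FFA, p) - ATD) / p.t_ATD


def nucleotide_partition(ATD: float, PKAa: float, p: ParameterSet) -> NucleotideState:
    """Split total adenine nucleotide into ATP, free ADP and free MgADP.

    ADP_f = AT/(1+ATD) and ATP = AT − ADP_f enforce conservation exactly.
    Active PKA reduces the MgADP fraction through
    f_KPKa = 1/(1 + k_KPKa·PKAa), mimicking SUR1 phosphorylation.
    """
    ADP_f = p.AT / (1.0 + ATD)
    ATP = p.AT - ADP_f
    f_KPKa = 1.0 / (1.0 + p.k_KPKa * PKAa)
    MgADP_f = 0.055 * f_KPKa * ADP_f
    return NucleotideState(ATP=ATP, ADP_f=ADP_f, MgADP_f=MgADP_f, f_KPKa=f_KPKa)
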