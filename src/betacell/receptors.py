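"""Mass-action GPCR cascades and shared effector-enzyme pools.

Five receptors are modeled with a common minimal cascade: ligand binding,
G-protein engagement, Gα·GTP release, Gα·GTP capture by a membrane effector
enzyme, GTP hydrolysis, heterotrimer recombination, and a single
desensitization/recycling loop.  Two coupling topologies are supported:

* **collision coupling** — ligand binds the free receptor and the LR complex
  then encounters a free G-protein (GLP-1R, GIPR, α2A-adrenergic,
  FFAR1/GPR40);
* **pre-coupling** — a stable receptor·G-protein complex exists before
  ligand binding (M3 muscarinic).

Each cascade has a private G-protein pool; only the target enzymes are
shared.  GLP-1R, GIPR and the α2A receptor all bind the same
plasma-membrane adenylyl cyclase pool (AC_p), but the α2A (Gi) complex is
catalytically silent, so catecholamine signaling occludes AC_p rather than
activating it.  M3R and FFAR1 compete for the membrane phospholipase C pool
(PLC_p).

Free receptor, free G-protein, free enzyme and Gβγ are closed algebraically
from the conserved totals; only the six bound species per cascade are
integrated.  Ligands are never depleted, so binding uses the saturating
occupancy factor L/(K_L + L).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .params import ParameterSet

__all__ = [
    "ReceptorSpec",
    "CascadeState",
    "CascadeRates",
    "RECEPTORS",
    "ligand_occupancy",
    "free_receptor",
    "free_gprotein",
    "cascade_derivatives",
    "ac_pool_partition",
    "plc_pool_partition",
    "ConservationError",
]


class ConservationError(ValueError):
    """A derived free species went negative: bound species exceed a total."""


class CascadeState(NamedTuple):
    """Bound species of one cascade, all in #·μm⁻².

    ``coupled`` is LR_n for collision coupling and RG_n for pre-coupling;
    the remaining fields are shared between the two topologies.  ``GE`` is
    the Gα·GTP–effector complex (AC_GLP, AC_GIP, AC_AR, PLC_M3 or PLC_R40).
    """
    coupled: float
    LRG: float
    Rd: float
    GaT: float
    GaD: float
    GE: float


class CascadeRates(NamedTuple):
    k1: float
    k2: float
    k2r: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k9: float


@dataclass(frozen=True)
class ReceptorSpec:
    """Static description of one receptor cascade."""
    name: str
    mode: str                 # 'collision' | 'precoupled'
    ligand: str               # input key, e.g. 'GLP1'
    ligand_basal: str         # parameter holding the basal concentration
    K_L: str                  # parameter name of the binding constant
    Re_t: str                 # total receptor density parameter
    G_t: str                  # total G-protein density parameter
    rates: tuple[str, ...]    # parameter names for k1,k2,k2r,k3..k9
    pool: str                 # 'AC' | 'PLC'
    role: str                 # 'activating' | 'inhibiting'
    complex_name: str         # name of GE in trajectory output
    initials: tuple[str, ...]  # parameter names of the six initial values

    def rate_values(self, p: ParameterSet) -> CascadeRates:
        return CascadeRates(*(p[name] for name in self.rates))

    def initial_state(self, p: ParameterSet) -> CascadeState:
        return CascadeState(*(p[name] for name in self.initials))


def _rnames(i: int) -> tuple[str, ...]:
    return (f"R{i}1", f"R{i}2", f"R{i}2r", f"R{i}3", f"R{i}4",
            f"R{i}5", f"R{i}6", f"R{i}7", f"R{i}8", f"R{i}9")


RECEPTORS: tuple[ReceptorSpec, ...] = (
    ReceptorSpec("GLP1R", "collision", "GLP1", "GLP1i", "K_GLP1",
                 "Re_GLt", "G1t", _rnames(1), "AC", "activating", "ACGLP",
                 ("LR1_in", "LRG1_in", "ReGLd_in", "GaT1_in", "GaD1_in",
                  "ACGLP_in")),
    ReceptorSpec("GIPR", "collision", "GIP", "GIPi", "K_GIP",
                 "Re_GIt", "G2t", _rnames(2), "AC", "activating", "ACGIP",
                 ("LR2_in", "LRG2_in", "ReGId_in", "GaT2_in", "GaD2_in",
                  "ACGIP_in")),
    ReceptorSpec("A2AR", "collision", "AR3", "AR3i", "K_AR3",
                 "Re_ARt", "G3t", _rnames(3), "AC", "inhibiting", "ACAR",
                 ("LR3_in", "LRG3_in", "ReARd_in", "GaT3_in", "GaD3_in",
                  "ACAR_in")),
    ReceptorSpec("M3R", "precoupled", "AM3", "AM3i", "K_AM3",
                 "Re_M3t", "G6t", _rnames(6), "PLC", "activating", "PLCM3",
                 ("RG6_in", "LRG6_in", "ReM3d_in", "GaT6_in", "GaD6_in",
                  "PLCM3_in")),
    ReceptorSpec("FFAR1", "collision", "AR7", "AR7i", "K_AR7",
                 "Re_R40t", "G7t", _rnames(7), "PLC", "activating", "PLCR40",
                 ("LR7_in", "LRG7_in", "ReR40d_in", "GaT7_in", "GaD7_in",
                  "PLCR40_in")),
)

# relative slack on conservation closures before raising; solver round-off
# can push derived free species marginally negative
_CLOSURE_RTOL = 1e-6


def ligand_occupancy(L: float, K_L: float) -> float:
    """Fractional receptor occupancy L/(K_L + L) for a non-depleted ligand."""
    if L < 0:
        raise ValueError(f"ligand concentration must be >= 0, got {L}")
    if K_L <= 0:
        raise ValueError(f"binding constant must be > 0, got {K_L}")
    return L / (K_L + L)


def _closure(total: float, bound: float, what: str, name: str,
             strict: bool = True) -> float:
    """Free species from a conservation total.

    ``strict`` raises when the bound species exceed the total beyond solver
    round-off; the non-strict form clamps at zero, which keeps the
    right-hand side total on the out-of-region trial states implicit
    solvers probe.
    """
    free = total - bound
    if strict and free < -_CLOSURE_RTOL * total:
        raise ConservationError(
            f"{name}: derived free {what} is negative ({free:.3g}); "
            f"bound species exceed the total {total:.3g}")
    return max(free, 0.0)


def free_receptor(spec: ReceptorSpec, s: CascadeState, p: ParameterSet,
                  strict: bool = True) -> float:
    """R_n from the receptor conservation closure."""
    return _closure(p[spec.Re_t], s.Rd + s.coupled + s.LRG, "receptor",
                    spec.name, strict)


def free_gprotein(spec: ReceptorSpec, s: CascadeState, p: ParameterSet,
                  strict: bool = True) -> float:
    """G_n (heterotrimeric, GDP-bound) from the G-protein closure.

    The pre-coupled RG complex sequesters G-protein; in collision mode the
    ``coupled`` species is LR and contains no G-protein.
    """
    bound = s.LRG + s.GaT + s.GaD + s.GE
    if spec.mode == "precoupled":
        bound += s.coupled
    return _closure(p[spec.G_t], bound, "G-protein", spec.name, strict)


def cascade_derivatives(spec: ReceptorSpec, s: CascadeState, L: float,
                        pool_free: float, p: ParameterSet,
                        strict: bool = True) -> CascadeState:
    """Time derivatives of the six bound species of one cascade.

    ``pool_free`` is the free effector enzyme of the shared pool the cascade
    feeds (AC_pf or PLC_pf), supplied by the caller so that cross-receptor
    competition for the finite pool is honored.
    """
    k = spec.rate_values(p)
    occ = ligand_occupancy(L, p[spec.K_L])
    R = free_receptor(spec, s, p, strict)
    G = free_gprotein(spec, s, p, strict)
    Gbg = s.GaT + s.GaD + s.GE

    if spec.mode == "collision":
        d_coupled = (k.k1 * R * occ + k.k2r * s.LRG
                     - k.k2 * G * s.coupled - k.k9 * s.coupled)
        d_LRG = k.k2 * G * s.coupled - k.k2r * s.LRG - k.k3 * s.LRG
        d_Rd = k.k9 * s.coupled - k.k8 * s.Rd
    elif spec.mode == "precoupled":
        d_coupled = k.k2 * R * G - k.k1 * s.coupled * occ - k.k2r * s.coupled
        d_LRG = k.k1 * s.coupled * occ - k.k3 * s.LRG - k.k9 * s.LRG
        d_Rd = k.k9 * s.LRG - k.k8 * s.Rd
    else:  # pragma: no cover - specs are fixed above
        raise ValueError(f"unknown coupling mode {spec.mode!r}")

    d_GaT = k.k3 * s.LRG - k.k4 * s.GaT * pool_free - k.k5 * s.GaT
    d_GE = k.k4 * s.GaT * pool_free - k.k6 * s.GE
    d_GaD = k.k5 * s.GaT + k.k6 * s.GE - k.k7 * s.GaD * Gbg

    return CascadeState(d_coupled, d_LRG, d_Rd, d_GaT, d_GaD, d_GE)


class ACPool(NamedTuple):
    AC_pf: float   # free enzyme
    AC_pa: float   # catalytically active complexes (GLP-1R + GIPR bound)
    AC_par: float  # active fraction of the total pool


class PLCPool(NamedTuple):
    PLC_pf: float
    PLC_pa: float  # active complexes (M3R + FFAR1 bound)


def ac_pool_partition(AC_GLP: float, AC_GIP: float, AC_AR: float,
                      p: ParameterSet, strict: bool = True) -> ACPool:
    """Partition the membrane adenylyl-cyclase pool.

    All three complexes occupy enzyme, but only the Gs-coupled ones (GLP-1R,
    GIPR) catalyze; the Gi-bound complex (AC_AR) is sequestered and silent.
    """
    AC_pf = _closure(p.AC_pt, AC_GLP + AC_GIP + AC_AR, "adenylyl cyclase",
                     "AC_p pool", strict)
    AC_pa = AC_GLP + AC_GIP
    return ACPool(AC_pf=AC_pf, AC_pa=AC_pa, AC_par=AC_pa / p.AC_pt)


def plc_pool_partition(PLC_M3: float, PLC_R40: float, p: ParameterSet,
                       strict: bool = True) -> PLCPool:
    """Partition the membrane phospholipase-C pool (both complexes active)."""
    PLC_pf = _closure(p.PLC_pt, PLC_M3 + PLC_R40, "phospholipase C",
                      "PLC_p pool", strict)
    return PLCPool(PLC_pf=PLC_pf, PLC_pa=PLC_M3 + PLC_R40)
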