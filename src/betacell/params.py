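"""Model constants, unit conventions and conversions.

Internal units follow the model's conventions throughout: cytosolic and ER
species in μM, membrane-bound species as area densities in #·μm⁻², time in s,
potential in mV, current in fA, conductance in pS, capacitance in fF and
volumes in μm³.  The bundled ``data/parameters.yaml`` holds every named
constant with its unit string and source group; :class:`ParameterSet` wraps
that table and applies user overrides.

A handful of runtime parameters (``g_mKATP``, ``g_mNM3``, ``V_mPLP``,
``k_ipde``) default to their tabulated initial levels (``g_mKATPi`` etc.)
and are the usual targets of timed step events in stimulation protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import yaml

__all__ = [
    "ParameterSet",
    "UnitContext",
    "load_parameters",
    "default_parameters",
    "rate_from_halflife",
]

# runtime name -> tabulated initial-value name
_RUNTIME_ALIASES = {
    "g_mKATP": "g_mKATPi",
    "g_mNM3": "g_mNM3i",
    "V_mPLP": "V_mPLPi",
    "k_ipde": "k_ipdei",
}

# strictly positive totals / capacities
_STRICTLY_POSITIVE = {
    "Re_GLt", "Re_GIt", "Re_ARt", "Re_M3t", "Re_R40t",
    "G1t", "G2t", "G3t", "G6t", "G7t",
    "AC_pt", "PLC_pt", "CaMo", "AT",
    "C_m", "V_c", "S_c", "V_ER", "N_av", "F",
}

# non-negative quantities (conductances, Michaelis constants, rates, ...).
# Reversal potentials and Boltzmann midpoints may be negative and are
# excluded.
_MAY_BE_NEGATIVE = {
    "Vp_in", "E_K", "E_Ca", "E_Na", "V_dKr", "V_dCa", "V_fCa",
    "k_dKr", "k_dCa", "k_fCa",
}


def _read_default_table() -> dict[str, dict]:
    text = resources.files("betacell.data").joinpath("parameters.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULT_TABLE = _read_default_table()


class ParameterSet(Mapping[str, float]):
    """Immutable mapping of parameter name to value, with unit metadata.

    Values are reachable as items (``p["ATD_m"]``) or attributes
    (``p.ATD_m``).  ``with_overrides`` returns a new set; the original is
    never mutated, so timed parameter changes are handled by the engine
    swapping parameter sets between integration segments.
    """

    def __init__(self, values: Mapping[str, float] | None = None,
                 overridden: frozenset[str] = frozenset()):
        base = {name: float(entry["value"]) for name, entry in _DEFAULT_TABLE.items()}
        if values is not None:
            base.update({k: float(v) for k, v in values.items()})
        object.__setattr__(self, "_values", base)
        object.__setattr__(self, "overridden", overridden)
        self._validate()

    # Mapping interface -----------------------------------------------------
    def __getitem__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            alias = _RUNTIME_ALIASES.get(name)
            if alias is not None:
                return self._values[alias]
            raise

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __contains__(self, name: object) -> bool:
        return name in self._values or name in _RUNTIME_ALIASES

    def __getattr__(self, name: str) -> float:
        if name.startswith("_"):
            raise AttributeError(name)
        try:
            return self[name]
        except KeyError:
            raise AttributeError(f"unknown parameter {name!r}") from None

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("ParameterSet is immutable; use with_overrides()")

    def __repr__(self) -> str:
        n_over = len(self.overridden)
        return f"ParameterSet({len(self)} parameters, {n_over} overridden)"

    # construction ----------------------------------------------------------
    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with ``overrides`` applied.

        Raises ``KeyError`` for names absent from the default table (runtime
        aliases such as ``g_mKATP`` are accepted) and ``ValueError`` for
        non-finite values.
        """
        resolved: dict[str, float] = dict(self._values)
        names: set[str] = set(self.overridden)
        for name, value in overrides.items():
            key = name if name in _DEFAULT_TABLE else _RUNTIME_ALIASES.get(name)
            if key is None and name in _RUNTIME_ALIASES.values():
                key = name
            if key is None:
                raise KeyError(
                    f"unknown parameter {name!r}; not in the default table")
            value = float(value)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value}")
            resolved[key] = value
            names.add(name)
        return ParameterSet(resolved, frozenset(names))

    # metadata ---------------------------------------------------------------
    @staticmethod
    def unit(name: str) -> str:
        key = name if name in _DEFAULT_TABLE else _RUNTIME_ALIASES[name]
        return _DEFAULT_TABLE[key]["unit"]

    @staticmethod
    def source(name: str) -> str:
        key = name if name in _DEFAULT_TABLE else _RUNTIME_ALIASES[name]
        return _DEFAULT_TABLE[key]["source"]

    def provenance(self, name: str) -> str:
        if name in self.overridden:
            return "user override"
        return self.source(name)

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    def dump_yaml(self, path) -> None:
        """Write the effective parameter table (values + units) to YAML."""
        out = {
            name: {
                "value": self._values[name],
                "unit": _DEFAULT_TABLE[name]["unit"],
                "source": self.provenance(name),
            }
            for name in self._values
        }
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)

    # validation -------------------------------------------------------------
    def _validate(self) -> None:
        for name, value in self._values.items():
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} is not finite: {value}")
            if name in _STRICTLY_POSITIVE and value <= 0:
                raise ValueError(f"parameter {name!r} must be > 0, got {value}")
            if name not in _MAY_BE_NEGATIVE and name not in _STRICTLY_POSITIVE \
                    and value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value}")


def default_parameters() -> ParameterSet:
    """The tabulated default parameter set."""
    return ParameterSet()


def load_parameters(overrides: Mapping[str, float] | None = None) -> ParameterSet:
    """Defaults with ``overrides`` applied; unknown names raise ``KeyError``."""
    p = ParameterSet()
    if overrides:
        p = p.with_overrides(overrides)
    return p


def rate_from_halflife(t_half: float) -> float:
    """First-order rate constant ln(2)/t_half for a measured half-life in s."""
    if t_half <= 0:
        raise ValueError(f"half-life must be positive, got {t_half}")
    return math.log(2.0) / t_half


@dataclass(frozen=True)
class UnitContext:
    """Geometry-derived unit conversions between membrane and cytosol.

    ``f_Nc`` converts an area density on the plasma membrane (#·μm⁻²) to a
    cytosolic concentration (μM): f_Nc = 1e6·S_c/(N_av·V_c) with V_c in
    liters.  ``current_to_flux`` converts a membrane current in fA to a
    cytosolic concentration rate in μM/s for an ion of charge ``z``,
    I/(z·F·V_c); the divalent-calcium form I/(2F·V_c) is the one used by the
    calcium balance.
    """

    S_c: float = 973.0      # μm²
    V_c: float = 764.0      # μm³
    V_ER: float = 280.0     # μm³
    N_av: float = 6.022e23  # mol⁻¹
    F: float = 96485.0      # C/mol

    @classmethod
    def from_parameters(cls, p: ParameterSet) -> "UnitContext":
        return cls(S_c=p.S_c, V_c=p.V_c, V_ER=p.V_ER, N_av=p.N_av, F=p.F)

    @property
    def V_c_liters(self) -> float:
        return self.V_c * 1e-15

    @property
    def f_Nc(self) -> float:
        # 1e6 converts mol/L to μmol/L given the #/N_av mole count
        return 1e6 * self.S_c / (self.N_av * self.V_c_liters)

    def area_density_to_concentration(self, x: float) -> float:
        """Convert #·μm⁻² on the membrane to μM in the cytosol."""
        if x < 0:
            raise ValueError(f"area density must be >= 0, got {x}")
        return self.f_Nc * x

    def concentration_to_area_density(self, c: float) -> float:
        """Inverse of :meth:`area_density_to_concentration`."""
        if c < 0:
            raise ValueError(f"concentration must be >= 0, got {c}")
        return c / self.f_Nc

    def current_to_flux(self, current_fA: float, z: int = 2) -> float:
        """Concentration rate (μM/s) carried by ``current_fA`` into V_c.

        1 fA = 1e-15 C/s; dividing by z·F gives mol/s, by V_c (liters) gives
        mol/L/s, and 1e6 rescales to μM/s.  The sign of the current is
        preserved.
        """
        return current_fA * 1e-15 / (z * self.F * self.V_c_liters) * 1e6
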