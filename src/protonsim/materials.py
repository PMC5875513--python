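"""Material table and the power-law range-energy model.

All range/energy conversions use a Bragg-Kleeman power law for water,
``R = alpha * E**p`` with configurable constants (defaults
``alpha = 0.0022 cm/MeV**p``, ``p = 1.77``).  Non-water materials are
handled entirely through their relative stopping power (RSP): a slab of
thickness ``t`` behaves like ``t * RSP`` of water (its water-equivalent
thickness, WET).  This keeps the whole engine on a single water range
scale, which is exactly how the layered source is constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "Material",
    "RangeEnergyModel",
    "DEFAULT_MODEL",
    "DEFAULT_MATERIALS",
    "WATER",
    "range_from_energy",
    "energy_from_range",
    "stopping_power",
    "wet",
    "material_table",
    "BOHR_STRAGGLING_MEV2_PER_CM",
    "LOW_ENERGY_CAP_MEV",
    "PROTON_MASS_MEV",
]

#: Proton rest mass (MeV/c^2); used for the pv factor in scattering.
PROTON_MASS_MEV = 938.272

#: Bohr-like energy-loss straggling variance rate in water (MeV^2 per cm).
BOHR_STRAGGLING_MEV2_PER_CM = 0.087

#: Below this kinetic energy the stopping power is held constant to avoid
#: the integrable (R -> 0) singularity; the residual is deposited locally.
LOW_ENERGY_CAP_MEV = 0.25


@dataclass(frozen=True)
class Material:
    """A transport material described by bulk surrogate quantities.

    Parameters
    ----------
    name : str
        Lookup key in the material table.
    mass_density : float
        Bulk density in g/cm^3.
    relative_stopping_power : float
        Stopping power relative to water (dimensionless).  WET of a slab
        is ``thickness * relative_stopping_power``.
    radiation_length : float
        Radiation length X0 in g/cm^2, used by the Highland scattering
        formula.
    """

    name: str
    mass_density: float
    relative_stopping_power: float
    radiation_length: float = 36.08

    def __post_init__(self) -> None:
        if self.mass_density <= 0:
            raise ValueError(f"mass_density must be > 0, got {self.mass_density}")
        if self.relative_stopping_power <= 0:
            raise ValueError(
                f"relative_stopping_power must be > 0, got {self.relative_stopping_power}"
            )
        if self.radiation_length <= 0:
            raise ValueError(f"radiation_length must be > 0, got {self.radiation_length}")


@dataclass(frozen=True)
class RangeEnergyModel:
    """Power-law range-energy relation for protons in water.

    ``range(E) = alpha * E**p`` (cm of water, E in MeV).
    """

    alpha: float = 0.0022
    p: float = 1.77

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.p <= 1:
            raise ValueError("require alpha > 0 and p > 1")


DEFAULT_MODEL = RangeEnergyModel()

#: Bundled default material table.  All values overridable via
#: :func:`material_table`.  Lead RSP is a per-cm effective value used for
#: foil WET bookkeeping, not a physical stopping-power ratio.
DEFAULT_MATERIALS: dict[str, Material] = {
    "water": Material("water", 1.0, 1.0, 36.08),
    "lucite": Material("lucite", 1.19, 1.16, 40.55),
    "lead": Material("lead", 11.35, 5.4, 6.37),
    "bone": Material("bone", 1.85, 1.6, 26.0),
    "lung": Material("lung", 0.26, 0.26, 36.08),
    "solid-water": Material("solid-water", 1.04, 1.0, 36.08),
    "air": Material("air", 0.0012, 0.001, 36.62),
}

WATER = DEFAULT_MATERIALS["water"]


def material_table(overrides: Mapping[str, Mapping[str, float]] | None = None) -> dict[str, Material]:
    """Return a copy of the default material table with optional overrides.

    ``overrides`` maps material name to a dict of field values; unknown
    names create new materials (all four fields then required except
    ``radiation_length`` which defaults to water's).
    """
    table = dict(DEFAULT_MATERIALS)
    if overrides:
        for name, fields in overrides.items():
            if name in table:
                table[name] = replace(table[name], **dict(fields))
            else:
                table[name] = Material(name=name, **dict(fields))
    return table


def _as_nonnegative(x, what: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{what} must be >= 0")
    return arr


def range_from_energy(energy_mev, model: RangeEnergyModel = DEFAULT_MODEL):
    """CSDA range in water (cm) for kinetic energy in MeV.

    Vectorized; raises ``ValueError`` for negative energies.
    """
    e = _as_nonnegative(energy_mev, "energy")
    r = model.alpha * e**model.p
    return r if r.ndim else float(r)


def energy_from_range(range_cm, model: RangeEnergyModel = DEFAULT_MODEL):
    """Kinetic energy (MeV) whose water range equals ``range_cm``.

    Exact inverse of :func:`range_from_energy`.
    """
    r = _as_nonnegative(range_cm, "range")
    e = (r / model.alpha) ** (1.0 / model.p)
    return e if e.ndim else float(e)


def stopping_power(
    energy_mev,
    material: Material = WATER,
    model: RangeEnergyModel = DEFAULT_MODEL,
):
    """Linear stopping power (MeV/cm) in ``material``.

    Water value is the derivative inverse of the range law,
    ``1 / (alpha * p * E**(p-1))``, scaled by the material's RSP.  Below
    :data:`LOW_ENERGY_CAP_MEV` the value is capped at the cap-energy value.
    """
    e = _as_nonnegative(energy_mev, "energy")
    e_eff = np.maximum(e, LOW_ENERGY_CAP_MEV)
    s = material.relative_stopping_power / (model.alpha * model.p * e_eff ** (model.p - 1.0))
    return s if s.ndim else float(s)


def wet(thickness_cm, material: Material):
    """Water-equivalent thickness (cm water) of a slab of ``material``."""
    t = _as_nonnegative(thickness_cm, "thickness")
    w = t * material.relative_stopping_power
    return w if w.ndim else float(w)
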