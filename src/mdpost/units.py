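"""Unit systems and conversion to internal SI.

Everything inside a trajectory store is strict SI: metres, seconds,
kilograms, coulombs, joules, pascals.  A :class:`UnitSystem` carries the
multiplicative factor from a simulation engine's native unit to SI for
each base dimension; derived dimensions (velocity, force) are composed
from the base factors.
"""

from __future__ import annotations

from dataclasses import dataclass

# CODATA 2018 exact values
BOLTZMANN = 1.380649e-23  # J/K
ELEMENTARY_CHARGE = 1.602176634e-19  # C
AVOGADRO = 6.02214076e23  # 1/mol


@dataclass(frozen=True)
class UnitSystem:
    """Multiplicative factors converting native units to SI."""

    name: str
    length: float = 1.0
    time: float = 1.0
    mass: float = 1.0
    energy: float = 1.0
    charge: float = 1.0
    pressure: float = 1.0

    @property
    def velocity(self) -> float:
        return self.length / self.time

    @property
    def force(self) -> float:
        return self.energy / self.length

    def factor_for(self, property_name: str) -> float:
        """SI conversion factor for a stored property."""
        return _PROPERTY_DIMENSIONS.get(property_name, lambda u: 1.0)(self)


_PROPERTY_DIMENSIONS = {
    "positions": lambda u: u.length,
    "unwrapped_positions": lambda u: u.length,
    "velocities": lambda u: u.velocity,
    "forces": lambda u: u.force,
    "image_flags": lambda u: 1.0,
    "per_particle_energy": lambda u: u.energy,
    "stress": lambda u: u.pressure,
}

SI = UnitSystem("si")

# LAMMPS 'metal': Angstrom, picosecond, g/mol, eV, multiples of e, bar
LAMMPS_METAL = UnitSystem(
    "lammps_metal",
    length=1e-10,
    time=1e-12,
    mass=1e-3 / AVOGADRO,
    energy=ELEMENTARY_CHARGE,
    charge=ELEMENTARY_CHARGE,
    pressure=1e5,
)

# LAMMPS 'real': Angstrom, femtosecond, g/mol, kcal/mol, e, atm
LAMMPS_REAL = UnitSystem(
    "lammps_real",
    length=1e-10,
    time=1e-15,
    mass=1e-3 / AVOGADRO,
    energy=4184.0 / AVOGADRO,
    charge=ELEMENTARY_CHARGE,
    pressure=101325.0,
)

PRESETS = {u.name: u for u in (SI, LAMMPS_METAL, LAMMPS_REAL)}


def get_unit_system(name_or_system: str | UnitSystem) -> UnitSystem:
    if isinstance(name_or_system, UnitSystem):
        return name_or_system
    try:
        return PRESETS[name_or_system]
    except KeyError:
        from .errors import UnitSystemError

        raise UnitSystemError(
            f"unknown unit system {name_or_system!r}; presets: {sorted(PRESETS)}"
        ) from None
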