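"""Seeded synthetic trajectory generators with closed-form observables.

These generators stand in for a simulation engine: every calculator in
the package can be exercised against a known answer without external
data.  They are statistical fixtures, not physical simulations — there
are no forces, and positions/velocities realise stochastic processes
whose transport coefficients are exact in expectation:

* ``random_walk`` — Gaussian steps of per-axis variance 2 D dt, so the
  MSD is 6 D t and the white-noise velocity ACF integrates to 3 D
  (the lag-0 trapezoid half-weight makes the discrete integral exact).
* ``ou_velocity`` / ``ou_flux`` — exact discretisation of the
  Ornstein-Uhlenbeck process (not Euler), so ACF(t) = sigma^2 e^{-t/tau}
  holds at any timestep and the Green-Kubo integral is sigma^2 tau per
  component.
* ``lattice`` — simple-cubic crystal with 6 first neighbours at the
  lattice constant.
* ``dimer_fluid`` — rigid dimers whose centres of mass random-walk with
  a known D; some straddle periodic boundaries.
* ``charged_walkers`` — independent walkers per species, so cross
  (distinct) diffusion vanishes and Nernst-Einstein is exact.

All randomness flows through ``numpy.random.default_rng`` (PCG64),
fixed project-wide; a given seed is bitwise-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .store import BoxMetadata, SpeciesRecord, TrajectoryStore, ConfigurationBatch

DEFAULT_MASS = 1e-26  # kg, inert placeholder for abstract species


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic fixture (seed included)."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    rng_algorithm: str = "PCG64"

    def generate(self):
        try:
            fn = _GENERATORS[self.kind]
        except KeyError:
            raise ValueError(f"unknown fixture kind {self.kind!r}") from None
        return fn(**self.params)


def _make_store(
    path,
    box_length: float,
    dt: float,
    temperature: float,
    species: Sequence[SpeciesRecord],
) -> TrajectoryStore:
    box = BoxMetadata(
        (box_length,) * 3, timestep=dt, temperature=temperature, unit_system="si"
    )
    return TrajectoryStore.create(path, box, species)


def ideal_gas(
    n_particles: int = 500,
    n_frames: int = 20,
    box_length: float = 10.0,
    dt: float = 1.0,
    temperature: float = 300.0,
    seed: int = 0,
    species_name: str = "X",
    path=None,
) -> TrajectoryStore:
    """I.i.d. uniform positions every frame: g(r) = 1 in expectation."""
    rng = np.random.default_rng(seed)
    sp = SpeciesRecord(species_name, tuple(range(n_particles)), mass=DEFAULT_MASS)
    store = _make_store(path, box_length, dt, temperature, [sp])
    pos = rng.uniform(0.0, box_length, size=(n_particles, n_frames, 3))
    store.ingest([ConfigurationBatch({species_name: {"positions": pos}})])
    return store


def random_walk(
    n_particles: int = 100,
    n_frames: int = 5000,
    D: float = 1e-9,
    box_length: float = 1e-8,
    dt: float = 1e-12,
    temperature: float = 300.0,
    seed: int = 0,
    species_name: str = "X",
    charge_number: int = 0,
    mass: float = DEFAULT_MASS,
    path=None,
) -> TrajectoryStore:
    """Gaussian random walk with per-step variance 2 D dt per axis.

    Stores unwrapped and wrapped positions, integer image flags and the
    white-noise velocities (step / dt), so both unwrap methods and both
    diffusion estimators can be tested against the construction.
    """
    rng = np.random.default_rng(seed)
    sp = SpeciesRecord(species_name, tuple(range(n_particles)),
                       mass=mass, charge_number=charge_number)
    store = _make_store(path, box_length, dt, temperature, [sp])
    v = rng.normal(0.0, np.sqrt(2.0 * D / dt), size=(n_particles, n_frames, 3))
    if D == 0:
        v[:] = 0.0
    r0 = rng.uniform(0.0, box_length, size=(n_particles, 1, 3))
    unwrapped = r0 + np.concatenate(
        [np.zeros((n_particles, 1, 3)), np.cumsum(v[:, :-1, :] * dt, axis=1)], axis=1
    )
    flags = np.floor(unwrapped / box_length).astype(np.int64)
    wrapped = unwrapped - flags * box_length
    # re-derive the unwrapped view from (wrapped, flags) so the identity
    # r_unwrapped = r_wrapped + n L holds to the bit, not just to rounding
    unwrapped = wrapped + flags * box_length
    store.ingest([ConfigurationBatch({species_name: {
        "positions": wrapped,
        "unwrapped_positions": unwrapped,
        "image_flags": flags,
        "velocities": v,
    }})])
    return store


def ou_series(
    sigma2: float,
    tau: float,
    n_frames: int,
    dt: float,
    rng: np.random.Generator,
    shape: tuple[int, ...] = (),
) -> np.ndarray:
    """Exact stationary Ornstein-Uhlenbeck sample paths.

    Returns an array of shape ``shape + (n_frames,)`` with per-sample
    variance sigma2 and ACF sigma2 * exp(-t/tau) at any dt (the update
    uses the exact transition density, not an Euler step).
    """
    from scipy.signal import lfilter

    rho = np.exp(-dt / tau)
    innov_sd = np.sqrt(sigma2 * (1.0 - rho**2))
    e = rng.normal(0.0, innov_sd, size=shape + (n_frames,))
    e[..., 0] = rng.normal(0.0, np.sqrt(sigma2), size=shape)  # stationary start
    # x_t = rho x_{t-1} + e_t is an AR(1) recursion == IIR filter 1/(1 - rho z^-1)
    return lfilter([1.0], [1.0, -rho], e, axis=-1)


def ou_velocity(
    n_particles: int = 100,
    n_frames: int = 5000,
    sigma_v2: float = 1e5,
    tau: float = 2e-14,
    box_length: float = 1e-8,
    dt: float = 5e-15,
    temperature: float = 300.0,
    seed: int = 0,
    species_name: str = "X",
    path=None,
) -> TrajectoryStore:
    """OU velocities (D = sigma_v2 * tau) plus their integrated positions,
    so Green-Kubo and Einstein-Helfand estimators apply to one fixture."""
    rng = np.random.default_rng(seed)
    sp = SpeciesRecord(species_name, tuple(range(n_particles)), mass=DEFAULT_MASS)
    store = _make_store(path, box_length, dt, temperature, [sp])
    v = np.moveaxis(ou_series(sigma_v2, tau, n_frames, dt, rng,
                              shape=(n_particles, 3)), -1, 1)
    r0 = rng.uniform(0.0, box_length, size=(n_particles, 1, 3))
    unwrapped = r0 + np.concatenate(
        [np.zeros((n_particles, 1, 3)), np.cumsum(v[:, :-1, :] * dt, axis=1)], axis=1
    )
    store.ingest([ConfigurationBatch({species_name: {
        "velocities": v,
        "unwrapped_positions": unwrapped,
        "positions": unwrapped - np.floor(unwrapped / box_length) * box_length,
    }})])
    return store


def ou_flux(
    sigma2: float,
    tau: float,
    n_frames: int,
    dt: float,
    seed: int = 0,
    n_components: int = 3,
) -> np.ndarray:
    """A stationary OU vector flux series, shape (n_frames, n_components)."""
    rng = np.random.default_rng(seed)
    return np.moveaxis(ou_series(sigma2, tau, n_frames, dt, rng,
                                 shape=(n_components,)), -1, 0)


def lattice(
    n_side: int = 6,
    a: float = 1.0,
    temperature: float = 300.0,
    seed: int = 0,
    species_name: str = "X",
    path=None,
) -> TrajectoryStore:
    """Single-frame simple-cubic crystal, spacing ``a``, box edge n_side*a."""
    n = n_side**3
    sp = SpeciesRecord(species_name, tuple(range(n)), mass=DEFAULT_MASS)
    store = _make_store(path, n_side * a, 1.0, temperature, [sp])
    grid = np.arange(n_side) * a
    x, y, z = np.meshgrid(grid, grid, grid, indexing="ij")
    pos = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=-1)[:, None, :]
    store.ingest([ConfigurationBatch({species_name: {"positions": pos}})])
    return store


def dimer_fluid(
    n_dimers: int = 50,
    n_frames: int = 2000,
    D: float = 1e-9,
    bond_length: float = 1e-10,
    box_length: float = 2e-9,
    dt: float = 1e-12,
    temperature: float = 300.0,
    seed: int = 0,
    path=None,
) -> TrajectoryStore:
    """Rigid A-B dimers whose centres of mass random-walk with known D.

    Bond vectors are fixed random orientations of constant length.  COMs
    start on a jittered cubic grid (excluded volume, so distinct dimers
    never sit within bonding distance in the reference frame) and the
    whole configuration is shifted to put dimer 0 on the box corner, so
    molecules straddle periodic boundaries in the wrapped view.  Equal
    A/B masses put the COM at the bond midpoint.
    """
    rng = np.random.default_rng(seed)
    idx_a = tuple(range(0, 2 * n_dimers, 2))
    idx_b = tuple(range(1, 2 * n_dimers, 2))
    sp_a = SpeciesRecord("A", idx_a, mass=DEFAULT_MASS)
    sp_b = SpeciesRecord("B", idx_b, mass=DEFAULT_MASS)
    store = _make_store(path, box_length, dt, temperature, [sp_a, sp_b])

    n_side = int(np.ceil(n_dimers ** (1.0 / 3.0)))
    spacing = box_length / n_side
    if spacing < 4.0 * bond_length:
        raise ValueError("box too small: dimers would overlap in the reference frame")
    grid = (np.stack(np.meshgrid(*[np.arange(n_side)] * 3, indexing="ij"), axis=-1)
            .reshape(-1, 3)[:n_dimers] + 0.5) * spacing
    jitter = rng.uniform(-0.1, 0.1, size=(n_dimers, 3)) * spacing
    com0 = (grid + jitter - (grid[0] + jitter[0]))[:, None, :]  # dimer 0 at corner
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_dimers, n_frames - 1, 3))
    com = com0 + np.concatenate(
        [np.zeros((n_dimers, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    u = rng.normal(size=(n_dimers, 1, 3))
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    half = 0.5 * bond_length * u
    data = {}
    for name, sign in (("A", -1.0), ("B", +1.0)):
        unwrapped = com + sign * half
        flags = np.floor(unwrapped / box_length).astype(np.int64)
        wrapped = unwrapped - flags * box_length
        data[name] = {
            "positions": wrapped,
            "unwrapped_positions": wrapped + flags * box_length,
            "image_flags": flags,
        }
    store.ingest([ConfigurationBatch(data)])
    return store


def charged_walkers(
    species_specs: Sequence[tuple[str, int, float, int]] = (
        ("P", 50, 1e-9, +1),
        ("M", 50, 1e-9, -1),
    ),
    n_frames: int = 5000,
    box_length: float = 1e-8,
    dt: float = 1e-12,
    temperature: float = 300.0,
    seed: int = 0,
    path=None,
) -> TrajectoryStore:
    """Independent charged random walkers, one walk per species member.

    ``species_specs`` lists (name, count, D, charge_number).  Because
    walkers are independent, cross-correlations vanish and the
    Nernst-Einstein conductivity is exact in expectation.
    """
    rng = np.random.default_rng(seed)
    records, offset = [], 0
    for name, count, _D, z in species_specs:
        records.append(SpeciesRecord(name, tuple(range(offset, offset + count)),
                                     mass=DEFAULT_MASS, charge_number=z))
        offset += count
    store = _make_store(path, box_length, dt, temperature, records)
    data = {}
    for name, count, D, _z in species_specs:
        v = rng.normal(0.0, np.sqrt(2.0 * D / dt), size=(count, n_frames, 3))
        r0 = rng.uniform(0.0, box_length, size=(count, 1, 3))
        unwrapped = r0 + np.concatenate(
            [np.zeros((count, 1, 3)), np.cumsum(v[:, :-1, :] * dt, axis=1)], axis=1
        )
        flags = np.floor(unwrapped / box_length).astype(np.int64)
        wrapped = unwrapped - flags * box_length
        data[name] = {
            "velocities": v,
            "unwrapped_positions": wrapped + flags * box_length,
            "positions": wrapped,
            "image_flags": flags,
        }
    store.ingest([ConfigurationBatch(data)])
    return store


_GENERATORS = {
    "ideal_gas": ideal_gas,
    "random_walk": random_walk,
    "ou_velocity": ou_velocity,
    "ou_flux": ou_flux,
    "lattice": lattice,
    "dimer_fluid": dimer_fluid,
    "charged_walkers": charged_walkers,
}
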