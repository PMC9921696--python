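"""Time-dependent derived series computed from stored raw data.

Array-level functions are pure; the ``ensure_*``/:func:`ensure` wrappers
read from a :class:`~mdpost.store.TrajectoryStore`, compute a missing
property and write it back, so a calculator that hits a
:class:`~mdpost.errors.TransformationRequired` signal can resolve its
dependency and retry the load.

Volume convention: the heat flux is stored *extensive* (sum over
particles, no 1/V prefactor); the Green-Kubo thermal-conductivity
calculator divides by V accordingly.  Both pairings are dimensionally
consistent; keeping fluxes extensive makes replication exactly double
every stored flux (ionic current, dipole, heat current alike).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .errors import MissingInputError, TransformationRequired
from .store import BoxMetadata, SpeciesRecord, TrajectoryStore
from .units import ELEMENTARY_CHARGE

# Off-diagonal index pairs for the Helfand viscosity moment, in order.
OFFDIAG_PAIRS = ((0, 1), (0, 2), (1, 2))  # xy, xz, yz


# ---------------------------------------------------------------------------
# coordinate (un)wrapping
# ---------------------------------------------------------------------------

def wrap(positions: np.ndarray, box: BoxMetadata) -> np.ndarray:
    """Fold coordinates into [0, L) per periodic axis."""
    out = np.array(positions, dtype=float, copy=True)
    L = box.edges
    for ax in range(3):
        if box.periodic_flags[ax]:
            out[..., ax] = np.mod(out[..., ax], L[ax])
    return out


def unwrap_images(
    wrapped_positions: np.ndarray,
    image_flags: np.ndarray,
    box: BoxMetadata,
) -> np.ndarray:
    """Reconstruct continuous paths from stored image counts.

    ``r_unwrapped = r_wrapped + n * L`` per axis, exactly.
    """
    if image_flags is None:
        raise TransformationRequired(None, "image_flags",
                                     hint="use unwrap_boxhop instead")
    return np.asarray(wrapped_positions, dtype=float) + \
        np.asarray(image_flags, dtype=float) * box.edges[None, None, :]


def unwrap_boxhop(wrapped_positions: np.ndarray, box: BoxMetadata) -> np.ndarray:
    """Unwrap by jump detection: a per-frame displacement larger than L/2
    on any axis is read as a box crossing and shifted by the box length.

    Requires sampling fast enough that no true displacement exceeds L/2
    per stored frame; violations mis-unwrap silently (undetectable from
    wrapped data alone).  The first frame is the reference.
    """
    r = np.asarray(wrapped_positions, dtype=float)
    L = box.edges
    steps = np.diff(r, axis=1)
    hops = np.round(steps / L[None, None, :])
    for ax in range(3):
        if not box.periodic_flags[ax]:
            hops[..., ax] = 0.0
    shifts = np.concatenate(
        [np.zeros_like(r[:, :1, :]), np.cumsum(hops, axis=1)], axis=1
    )
    return r - shifts * L[None, None, :]


# ---------------------------------------------------------------------------
# flux series (array level)
# ---------------------------------------------------------------------------

def ionic_current(
    velocities_by_species: Mapping[str, np.ndarray],
    species: Sequence[SpeciesRecord],
    elementary_charge: float = ELEMENTARY_CHARGE,
) -> np.ndarray:
    """J(t) = q sum_i z_i v_i(t); shape (n_frames, 3), SI A·m."""
    out = None
    for sp in species:
        v = velocities_by_species[sp.name]  # (atoms, frames, 3)
        contrib = sp.charge_number * v.sum(axis=0)
        out = contrib if out is None else out + contrib
    return elementary_charge * out


def translational_dipole(
    unwrapped_by_species: Mapping[str, np.ndarray],
    species: Sequence[SpeciesRecord],
    elementary_charge: float = ELEMENTARY_CHARGE,
) -> np.ndarray:
    """M(t) = q sum_i z_i r_i(t) with unwrapped coordinates; (n_frames, 3)."""
    out = None
    for sp in species:
        r = unwrapped_by_species[sp.name]
        contrib = sp.charge_number * r.sum(axis=0)
        out = contrib if out is None else out + contrib
    return elementary_charge * out


def thermal_flux(
    per_particle_energy: np.ndarray,
    velocities: np.ndarray,
    pairwise_terms: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, dict[str, bool]]:
    """Extensive heat flux, shape (n_frames, 3).

    Convective term ``sum_i e_i v_i`` always; the pair-interaction term
    ``-(1/2) sum_{i<j} (F_ij . (v_i + v_j)) r_ij`` is added only when
    ``pairwise_terms = (F, R)`` is supplied, where ``F[p, t, :]`` and
    ``R[p, t, :]`` list force and separation for each i<j pair.  The
    scalar-product contraction of the printed force term is a
    documented reading of an ambiguous expression (see methods note).
    Returns (flux, flags of included terms).
    """
    if per_particle_energy is None:
        raise MissingInputError(
            "thermal flux needs per-particle energies "
            "(e.g. a LAMMPS 'compute pe/atom' column in the dump)"
        )
    e = np.asarray(per_particle_energy, dtype=float)  # (atoms, frames, 1)
    v = np.asarray(velocities, dtype=float)  # (atoms, frames, 3)
    flux = (e * v).sum(axis=0)
    terms = {"convective": True, "pairwise": False}
    if pairwise_terms is not None:
        F, R = pairwise_terms  # (pairs, frames, 3) each; v indexed separately
        raise NotImplementedError(
            "pairwise term requires per-pair velocities; use thermal_flux_pairwise"
        )
    return flux, terms


def thermal_flux_pairwise(
    per_particle_energy: np.ndarray,
    velocities: np.ndarray,
    pair_indices: np.ndarray,
    pair_forces: np.ndarray,
    pair_separations: np.ndarray,
) -> tuple[np.ndarray, dict[str, bool]]:
    """Heat flux with the pair-interaction (virial-like) term included.

    ``pair_indices`` is (n_pairs, 2) with i<j; ``pair_forces`` and
    ``pair_separations`` are (n_pairs, n_frames, 3) giving F_ij and r_ij.
    """
    flux, terms = thermal_flux(per_particle_energy, velocities)
    v = np.asarray(velocities, dtype=float)
    vi = v[pair_indices[:, 0]]  # (pairs, frames, 3)
    vj = v[pair_indices[:, 1]]
    dot = np.einsum("pfc,pfc->pf", pair_forces, vi + vj)
    flux = flux - 0.5 * np.einsum("pf,pfc->fc", dot, pair_separations)
    terms["pairwise"] = True
    return flux, terms


def integrated_heat_current(
    per_particle_energy: np.ndarray,
    unwrapped_positions: np.ndarray,
) -> np.ndarray:
    """Helfand moment of heat transport: sum_i e_i(t) r_i(t); (n_frames, 3)."""
    e = np.asarray(per_particle_energy, dtype=float)
    r = np.asarray(unwrapped_positions, dtype=float)
    return (e * r).sum(axis=0)


def helfand_viscosity_moment(
    velocities: np.ndarray,
    mass: float,
    unwrapped_positions: np.ndarray,
) -> np.ndarray:
    """Momentum-position moment sum_i m v_a r_b per off-diagonal pair.

    Returns (n_frames, 3) with components ordered (xy, xz, yz).
    """
    v = np.asarray(velocities, dtype=float)
    r = np.asarray(unwrapped_positions, dtype=float)
    cols = [
        (mass * v[..., a] * r[..., b]).sum(axis=0) for a, b in OFFDIAG_PAIRS
    ]
    return np.stack(cols, axis=-1)


# ---------------------------------------------------------------------------
# store-level dependency resolution
# ---------------------------------------------------------------------------

def ensure_unwrapped(store: TrajectoryStore, species_name: str) -> np.ndarray:
    """Load unwrapped positions, computing and persisting them if absent.

    Prefers image-flag unwrapping (exact) and falls back to box-hop
    detection when no flags were stored.
    """
    if store.has_property(species_name, "unwrapped_positions"):
        return store.load_property(species_name, "unwrapped_positions")
    wrapped = store.load_property(species_name, "positions")
    if store.has_property(species_name, "image_flags"):
        flags = store.load_property(species_name, "image_flags")
        unwrapped = unwrap_images(wrapped, flags, store.box)
    else:
        unwrapped = unwrap_boxhop(wrapped, store.box)
    store.write_property(species_name, "unwrapped_positions", unwrapped)
    return unwrapped


def ensure_observable(store: TrajectoryStore, name: str) -> np.ndarray:
    """Load a global flux series, deriving it from per-species data if absent."""
    if store.has_observable(name):
        return store.load_observable(name)
    builder = _OBSERVABLE_BUILDERS.get(name)
    if builder is None:
        raise MissingInputError(f"no transformation produces observable {name!r}")
    values = builder(store)
    store.write_observable(name, values)
    return values


def _build_ionic_current(store: TrajectoryStore) -> np.ndarray:
    species = store.species_records
    vel = {sp.name: store.load_property(sp.name, "velocities") for sp in species}
    return ionic_current(vel, species)


def _build_translational_dipole(store: TrajectoryStore) -> np.ndarray:
    species = store.species_records
    pos = {sp.name: ensure_unwrapped(store, sp.name) for sp in species}
    return translational_dipole(pos, species)


def _build_thermal_flux(store: TrajectoryStore) -> np.ndarray:
    total = None
    for sp in store.species_records:
        e = store.load_property(sp.name, "per_particle_energy")
        v = store.load_property(sp.name, "velocities")
        flux, _ = thermal_flux(e, v)
        total = flux if total is None else total + flux
    return total


def _build_integrated_heat_current(store: TrajectoryStore) -> np.ndarray:
    total = None
    for sp in store.species_records:
        e = store.load_property(sp.name, "per_particle_energy")
        r = ensure_unwrapped(store, sp.name)
        cur = integrated_heat_current(e, r)
        total = cur if total is None else total + cur
    return total


def _build_helfand_viscosity_moment(store: TrajectoryStore) -> np.ndarray:
    total = None
    for sp in store.species_records:
        v = store.load_property(sp.name, "velocities")
        r = ensure_unwrapped(store, sp.name)
        cur = helfand_viscosity_moment(v, sp.mass, r)
        total = cur if total is None else total + cur
    return total


_OBSERVABLE_BUILDERS = {
    "ionic_current": _build_ionic_current,
    "translational_dipole": _build_translational_dipole,
    "thermal_flux": _build_thermal_flux,
    "integrated_heat_current": _build_integrated_heat_current,
    "helfand_viscosity_moment": _build_helfand_viscosity_moment,
}
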