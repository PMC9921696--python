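"""Species/property-partitioned trajectory store.

Layout (an H5MD-flavoured hierarchy, documented here as the on-disk
contract):

* ``/<species>/<property>`` — float64 dataset of shape
  ``(n_atoms_of_species, n_frames, n_components)``, chunked
  ``(min(64, n_atoms), min(256, n_frames), n_components)``, gzip level 4,
  extendable along the frame axis.
* ``/Observables/<name>`` — global time series, shape ``(n_frames, n_comp)``.
* ``/Molecules/<label>`` — persisted molecule-group membership.
* root attributes — box edge lengths (m), periodic flags, timestep (s),
  temperature (K), unit-system name, ``version`` and ``n_frames``.
* per-species attributes — particle indices, mass (kg), charge number,
  mass fraction.

All values are SI.  The store version is a monotone counter bumped once
per :meth:`TrajectoryStore.ingest` call; results keyed to an older
version are stale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import h5py
import numpy as np

from .errors import (
    BatchPlanError,
    MDPostError,
    ShapeMismatchError,
    StoreExistsError,
    TransformationRequired,
)
from .units import get_unit_system

OBSERVABLES_GROUP = "Observables"
MOLECULES_GROUP = "Molecules"

#: components per property; 3 for vectors, 6 for symmetric stress, 1 for scalars
PROPERTY_COMPONENTS = {
    "positions": 3,
    "unwrapped_positions": 3,
    "velocities": 3,
    "forces": 3,
    "image_flags": 3,
    "per_particle_energy": 1,
    "stress": 6,
}


@dataclass(frozen=True)
class BoxMetadata:
    """Simulation cell and thermodynamic metadata, SI units."""

    edge_lengths: tuple[float, float, float]
    periodic_flags: tuple[bool, bool, bool] = (True, True, True)
    timestep: float = 1.0
    temperature: float = 0.0
    unit_system: str = "si"

    def __post_init__(self):
        if len(self.edge_lengths) != 3 or any(L <= 0 for L in self.edge_lengths):
            raise ValueError(f"box edge lengths must be three positive values, got {self.edge_lengths}")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")

    @property
    def volume(self) -> float:
        return math.prod(self.edge_lengths)

    @property
    def edges(self) -> np.ndarray:
        return np.asarray(self.edge_lengths, dtype=float)


@dataclass
class SpeciesRecord:
    """One particle species: membership, mass and charge metadata."""

    name: str
    particle_indices: tuple[int, ...]
    mass: float = 0.0  # kg
    charge_number: int = 0
    mass_fraction: float = 0.0

    def __post_init__(self):
        self.particle_indices = tuple(sorted(int(i) for i in self.particle_indices))

    @property
    def count(self) -> int:
        return len(self.particle_indices)


@dataclass
class ConfigurationBatch:
    """A contiguous block of frames, already converted to SI.

    ``species_data`` maps species name -> property name -> array of shape
    ``(n_atoms_of_species, n_frames_in_batch, n_components)``.
    """

    species_data: dict[str, dict[str, np.ndarray]]
    n_frames: int = field(default=0)

    def __post_init__(self):
        if not self.n_frames:
            for props in self.species_data.values():
                for arr in props.values():
                    self.n_frames = arr.shape[1]
                    return


@dataclass(frozen=True)
class StoreVersion:
    version: int
    n_frames_at_version: int


@dataclass(frozen=True)
class BatchPlan:
    """How to sweep a property array under a memory budget."""

    mode: str  # 'frame_batched' | 'atom_minibatched'
    batch_boundaries: tuple[tuple[int, int], ...]  # half-open ranges
    estimated_bytes_per_batch: int


def plan_batches(
    n_atoms: int,
    n_frames: int,
    n_components: int = 3,
    bytes_per_value: int = 8,
    overhead_factor: float = 3.0,
    memory_budget_bytes: int = 2 * 1024**3,
) -> BatchPlan:
    """Partition a (atoms, frames, components) sweep to fit a memory budget.

    Frames are batched first; when even a single frame exceeds the budget
    the plan falls back to atom-wise mini-batching.  The overhead factor
    accounts for intermediate copies made during computation.
    """
    if min(n_atoms, n_frames, n_components, bytes_per_value) <= 0:
        raise ValueError("all sizes must be positive")
    if overhead_factor <= 0 or memory_budget_bytes <= 0:
        raise ValueError("overhead factor and budget must be positive")

    per_frame = n_atoms * n_components * bytes_per_value * overhead_factor
    frames_per_batch = int(memory_budget_bytes // per_frame)
    if frames_per_batch >= 1:
        frames_per_batch = min(frames_per_batch, n_frames)
        bounds = tuple(
            (lo, min(lo + frames_per_batch, n_frames))
            for lo in range(0, n_frames, frames_per_batch)
        )
        return BatchPlan("frame_batched", bounds, int(per_frame * frames_per_batch))

    # one frame of all atoms does not fit: mini-batch over atoms instead
    per_atom = n_frames * n_components * bytes_per_value * overhead_factor
    # a single frame of one atom is the irreducible unit
    if n_components * bytes_per_value * overhead_factor > memory_budget_bytes:
        raise BatchPlanError(
            "a single atom-frame exceeds the memory budget; data unprocessable"
        )
    atoms_per_batch = max(1, int(memory_budget_bytes // (n_components * bytes_per_value * overhead_factor * n_frames)))
    if atoms_per_batch * per_atom > memory_budget_bytes * n_atoms:  # pragma: no cover - guard
        atoms_per_batch = 1
    bounds = tuple(
        (lo, min(lo + atoms_per_batch, n_atoms)) for lo in range(0, n_atoms, atoms_per_batch)
    )
    est = int(min(per_atom * atoms_per_batch, memory_budget_bytes))
    return BatchPlan("atom_minibatched", bounds, est)


def _validate_species(species: Sequence[SpeciesRecord]) -> None:
    seen: set[int] = set()
    for sp in species:
        idx = set(sp.particle_indices)
        if len(idx) != sp.count:
            raise ValueError(f"species {sp.name!r} has duplicate particle indices")
        if seen & idx:
            raise ValueError(f"species {sp.name!r} shares particle indices with another species")
        seen |= idx


def _fill_mass_fractions(species: Sequence[SpeciesRecord]) -> None:
    total = sum(sp.mass * sp.count for sp in species)
    for sp in species:
        sp.mass_fraction = (sp.mass * sp.count / total) if total > 0 else 0.0


class TrajectoryStore:
    """Versioned, partitioned container of per-frame property arrays.

    Use :meth:`create` / :meth:`open`; ``path=None`` creates a purely
    in-memory store (h5py core driver), convenient for synthetic
    fixtures and tests.
    """

    def __init__(self, h5: h5py.File):
        self._h5 = h5

    # -- lifecycle ---------------------------------------------------------

    @classmethod
    def create(
        cls,
        path: str | Path | None,
        box: BoxMetadata,
        species: Sequence[SpeciesRecord],
    ) -> "TrajectoryStore":
        _validate_species(species)
        _fill_mass_fractions(list(species))
        if path is None:
            h5 = h5py.File(f"mem-{id(box)}-{np.random.randint(1 << 30)}", "w",
                           driver="core", backing_store=False)
        else:
            path = Path(path)
            if path.exists():
                raise StoreExistsError(f"trajectory store already exists at {path}")
            path.parent.mkdir(parents=True, exist_ok=True)
            h5 = h5py.File(path, "w")
        h5.attrs["edge_lengths"] = np.asarray(box.edge_lengths, dtype=float)
        h5.attrs["periodic_flags"] = np.asarray(box.periodic_flags, dtype=bool)
        h5.attrs["timestep"] = float(box.timestep)
        h5.attrs["temperature"] = float(box.temperature)
        h5.attrs["unit_system"] = box.unit_system
        h5.attrs["version"] = 0
        h5.attrs["n_frames"] = 0
        for sp in species:
            g = h5.create_group(sp.name)
            g.attrs["particle_indices"] = np.asarray(sp.particle_indices, dtype=np.int64)
            g.attrs["mass"] = float(sp.mass)
            g.attrs["charge_number"] = int(sp.charge_number)
            g.attrs["mass_fraction"] = float(sp.mass_fraction)
        h5.create_group(OBSERVABLES_GROUP)
        h5.create_group(MOLECULES_GROUP)
        return cls(h5)

    @classmethod
    def open(cls, path: str | Path, mode: str = "r+") -> "TrajectoryStore":
        return cls(h5py.File(path, mode))

    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "TrajectoryStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- metadata ----------------------------------------------------------

    @property
    def box(self) -> BoxMetadata:
        a = self._h5.attrs
        return BoxMetadata(
            tuple(float(x) for x in a["edge_lengths"]),
            tuple(bool(x) for x in a["periodic_flags"]),
            float(a["timestep"]),
            float(a["temperature"]),
            str(a["unit_system"]),
        )

    @property
    def version(self) -> int:
        return int(self._h5.attrs["version"])

    @property
    def n_frames(self) -> int:
        return int(self._h5.attrs["n_frames"])

    @property
    def species_names(self) -> list[str]:
        return [k for k in self._h5.keys() if k not in (OBSERVABLES_GROUP, MOLECULES_GROUP)]

    def species(self, name: str) -> SpeciesRecord:
        g = self._h5[name]
        return SpeciesRecord(
            name=name,
            particle_indices=tuple(int(i) for i in g.attrs["particle_indices"]),
            mass=float(g.attrs["mass"]),
            charge_number=int(g.attrs["charge_number"]),
            mass_fraction=float(g.attrs["mass_fraction"]),
        )

    @property
    def species_records(self) -> list[SpeciesRecord]:
        return [self.species(n) for n in self.species_names]

    @property
    def n_atoms(self) -> int:
        return sum(self.species(n).count for n in self.species_names)

    # -- ingestion ---------------------------------------------------------

    def _extend_dataset(self, group: h5py.Group, prop: str, arr: np.ndarray) -> None:
        if prop in group:
            ds = group[prop]
            old = ds.shape[1]
            ds.resize(old + arr.shape[1], axis=1)
            ds[:, old:, :] = arr
        else:
            n_at, _, n_comp = arr.shape
            chunks = (min(64, n_at), min(256, max(1, arr.shape[1])), n_comp)
            dtype = np.int64 if prop == "image_flags" else np.float64
            group.create_dataset(
                prop,
                data=arr.astype(dtype),
                maxshape=(n_at, None, n_comp),
                chunks=chunks,
                compression="gzip",
                compression_opts=4,
            )

    def ingest(self, batches: Iterable[ConfigurationBatch]) -> StoreVersion:
        """Append frames from a batch stream; bumps the version once."""
        added = 0
        per_species_added: dict[str, int] = {}
        for batch in batches:
            for sp_name, props in batch.species_data.items():
                if sp_name not in self._h5:
                    raise ShapeMismatchError(f"unknown species {sp_name!r} in batch")
                sp = self.species(sp_name)
                for prop, arr in props.items():
                    arr = np.asarray(arr)
                    if arr.ndim != 3 or arr.shape[0] != sp.count:
                        raise ShapeMismatchError(
                            f"species {sp_name!r} property {prop!r}: got shape "
                            f"{arr.shape}, expected ({sp.count}, n_frames, n_components)"
                        )
                    want = PROPERTY_COMPONENTS.get(prop)
                    if want is not None and arr.shape[2] != want:
                        raise ShapeMismatchError(
                            f"species {sp_name!r} property {prop!r}: "
                            f"{arr.shape[2]} components, expected {want}"
                        )
                    self._extend_dataset(self._h5[sp_name], prop, arr)
                per_species_added[sp_name] = per_species_added.get(sp_name, 0) + batch.n_frames
            added += batch.n_frames
        self._h5.attrs["n_frames"] = self.n_frames + added
        self._h5.attrs["version"] = self.version + 1
        self._h5.flush()
        return StoreVersion(self.version, self.n_frames)

    # -- access ------------------------------------------------------------

    def has_property(self, species_name: str, property_name: str) -> bool:
        return species_name in self._h5 and property_name in self._h5[species_name]

    def load_property(
        self,
        species_name: str,
        property_name: str,
        frame_range: tuple[int, int] | None = None,
        atom_range: tuple[int, int] | None = None,
    ) -> np.ndarray:
        """Load a (atoms, frames, components) slab; half-open ranges.

        Raises :class:`TransformationRequired` for derivable properties
        that are not yet stored.
        """
        if species_name not in self._h5:
            raise KeyError(f"no species group {species_name!r}")
        g = self._h5[species_name]
        if property_name not in g:
            raise TransformationRequired(species_name, property_name)
        ds = g[property_name]
        f0, f1 = frame_range if frame_range is not None else (0, ds.shape[1])
        a0, a1 = atom_range if atom_range is not None else (0, ds.shape[0])
        if not (0 <= f0 <= f1 <= ds.shape[1] and 0 <= a0 <= a1 <= ds.shape[0]):
            raise IndexError(
                f"range out of bounds for {species_name}/{property_name} with shape {ds.shape}"
            )
        return ds[a0:a1, f0:f1, :]

    def write_property(self, species_name: str, property_name: str, values: np.ndarray) -> None:
        """Write (or overwrite) a full derived per-species property array."""
        g = self._h5[species_name]
        if property_name in g:
            del g[property_name]
        self._extend_dataset(g, property_name, np.asarray(values))
        self._h5.flush()

    # -- global observables ------------------------------------------------

    def has_observable(self, name: str) -> bool:
        return name in self._h5[OBSERVABLES_GROUP]

    def write_observable(self, name: str, values: np.ndarray,
                         sample_interval: float | None = None) -> None:
        g = self._h5[OBSERVABLES_GROUP]
        if name in g:
            del g[name]
        values = np.atleast_2d(np.asarray(values, dtype=float))
        ds = g.create_dataset(name, data=values, compression="gzip", compression_opts=4)
        ds.attrs["sample_interval"] = (
            float(sample_interval) if sample_interval is not None else self.box.timestep
        )
        self._h5.flush()

    def load_observable(self, name: str) -> np.ndarray:
        g = self._h5[OBSERVABLES_GROUP]
        if name not in g:
            raise TransformationRequired(None, name)
        return g[name][...]

    @property
    def observable_names(self) -> list[str]:
        return sorted(self._h5[OBSERVABLES_GROUP].keys())

    # -- molecule groups ---------------------------------------------------

    def write_molecule_group(self, label: str, member_indices: list[list[int]],
                             composition: Mapping[str, int]) -> None:
        g = self._h5[MOLECULES_GROUP]
        if label in g:
            del g[label]
        sub = g.create_group(label)
        arr = np.asarray(member_indices, dtype=np.int64)
        sub.create_dataset("members", data=arr)
        sub.attrs["composition"] = json.dumps(dict(composition), sort_keys=True)
        self._h5.flush()

    def load_molecule_group(self, label: str) -> tuple[np.ndarray, dict[str, int]]:
        sub = self._h5[MOLECULES_GROUP][label]
        return sub["members"][...], json.loads(sub.attrs["composition"])


def create_store(
    path: str | Path | None,
    box: BoxMetadata,
    species: Sequence[SpeciesRecord],
) -> TrajectoryStore:
    """Create an empty store at version 0 (module-level convenience)."""
    return TrajectoryStore.create(path, box, species)


def batched_frame_ranges(n_frames: int, plan: BatchPlan) -> Iterator[tuple[int, int]]:
    if plan.mode != "frame_batched":
        raise MDPostError("plan is not frame-batched")
    yield from plan.batch_boundaries
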