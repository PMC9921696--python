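"""Trajectory and flux-table readers/writers.

Two text trajectory dialects are supported:

* LAMMPS ``dump ... custom`` files with the block structure
  ``ITEM: TIMESTEP / ITEM: NUMBER OF ATOMS / ITEM: BOX BOUNDS /
  ITEM: ATOMS <columns>``.  An ``id`` column is mandatory; atoms are
  sorted by id within each frame, so scrambled dumps parse identically
  to sorted ones.  Wrapped coordinates are ``x y z``, unwrapped are
  ``xu yu zu``; image flags are ``ix iy iz``.
* Extended XYZ with a ``Lattice="..."`` and ``Properties=...`` comment
  line (the ase/OVITO convention, subset).

All values are converted from the declared unit system to SI on read;
writers convert back.  Particle index convention: LAMMPS ids are 1-based
in the file and stored 0-based; XYZ files carry no ids, so row order in
the first frame defines the particle index.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .elements import default_charge_number, element_mass, is_known_element
from .errors import MDPostError, TruncatedFileError
from .store import (
    BoxMetadata,
    ConfigurationBatch,
    SpeciesRecord,
    TrajectoryStore,
)
from .units import UnitSystem, get_unit_system

# column-name triplets/singletons -> canonical property names
_LAMMPS_VECTOR_COLS = {
    ("x", "y", "z"): "positions",
    ("xu", "yu", "zu"): "unwrapped_positions",
    ("vx", "vy", "vz"): "velocities",
    ("fx", "fy", "fz"): "forces",
    ("ix", "iy", "iz"): "image_flags",
}

_XYZ_PROP_NAMES = {
    "pos": "positions",
    "pos_u": "unwrapped_positions",
    "vel": "velocities",
    "velo": "velocities",
    "forces": "forces",
    "force": "forces",
    "image": "image_flags",
    "energy": "per_particle_energy",
}
_XYZ_NAMES_OUT = {v: k for k, v in _XYZ_PROP_NAMES.items() if k not in ("velo", "force")}


def _species_record(name: str, indices: Sequence[int],
                    overrides: Mapping[str, dict] | None = None) -> SpeciesRecord:
    ov = (overrides or {}).get(name, {})
    mass = ov.get("mass", element_mass(name) if is_known_element(name) else 0.0)
    charge = ov.get("charge_number", default_charge_number(name))
    return SpeciesRecord(name=name, particle_indices=tuple(indices),
                         mass=mass, charge_number=charge)


# ---------------------------------------------------------------------------
# LAMMPS dump
# ---------------------------------------------------------------------------

def _parse_lammps_frame(lines: list[str], offset: int):
    """Parse one dump frame; returns (natoms, box_lo, box_hi, columns, rows)."""
    it = iter(enumerate(lines))
    try:
        while True:
            i, line = next(it)
            if line.startswith("ITEM: TIMESTEP"):
                break
        next(it)  # timestep value
        i, line = next(it)
        if not line.startswith("ITEM: NUMBER OF ATOMS"):
            raise TruncatedFileError("expected 'ITEM: NUMBER OF ATOMS'", offset)
        _, natoms_line = next(it)
        natoms = int(natoms_line)
        i, line = next(it)
        if not line.startswith("ITEM: BOX BOUNDS"):
            raise TruncatedFileError("expected 'ITEM: BOX BOUNDS'", offset)
        lo, hi = np.empty(3), np.empty(3)
        for ax in range(3):
            _, b = next(it)
            parts = b.split()
            lo[ax], hi[ax] = float(parts[0]), float(parts[1])
        i, line = next(it)
        if not line.startswith("ITEM: ATOMS"):
            raise TruncatedFileError("expected 'ITEM: ATOMS'", offset)
        columns = line.split()[2:]
        rows = []
        for _ in range(natoms):
            _, r = next(it)
            rows.append(r.split())
    except StopIteration:
        raise TruncatedFileError("dump file truncated mid-frame", offset) from None
    return natoms, lo, hi, columns, rows


def _iter_lammps_blocks(path: Path) -> Iterator[tuple[list[str], int]]:
    """Yield (lines_of_one_frame, byte_offset) per frame."""
    text = path.read_text()
    starts = [m.start() for m in re.finditer(r"^ITEM: TIMESTEP", text, re.M)]
    if not starts:
        raise TruncatedFileError("no 'ITEM: TIMESTEP' blocks found", 0)
    starts.append(len(text))
    for s, e in zip(starts[:-1], starts[1:]):
        yield [ln for ln in text[s:e].splitlines() if ln.strip()], s


def peek_lammps_dump(
    path: str | Path,
    unit_system: str | UnitSystem = "lammps_metal",
    type_names: Mapping[int, str] | None = None,
    species_overrides: Mapping[str, dict] | None = None,
) -> tuple[BoxMetadata, list[SpeciesRecord]]:
    """Inspect the first frame: box and species layout (SI)."""
    path = Path(path)
    u = get_unit_system(unit_system)
    lines, off = next(_iter_lammps_blocks(path))
    natoms, lo, hi, columns, rows = _parse_lammps_frame(lines, off)
    edges = tuple(float(x) * u.length for x in (hi - lo))
    id_col = columns.index("id")
    label_col = _label_column(columns)
    by_species: dict[str, list[int]] = {}
    for row in rows:
        pid = int(row[id_col]) - 1
        by_species.setdefault(_row_label(row, label_col, columns, type_names), []).append(pid)
    species = [_species_record(name, idx, species_overrides)
               for name, idx in sorted(by_species.items())]
    box = BoxMetadata(edges, unit_system=u.name)
    return box, species


def _label_column(columns: list[str]) -> int:
    for cand in ("element", "type"):
        if cand in columns:
            return columns.index(cand)
    raise MDPostError(f"no element/type column in dump columns {columns}")


def _row_label(row, label_col, columns, type_names) -> str:
    raw = row[label_col]
    if columns[label_col] == "type":
        t = int(raw)
        return type_names[t] if type_names else f"type{t}"
    return raw


def read_lammps_dump(
    path: str | Path,
    unit_system: str | UnitSystem = "lammps_metal",
    type_names: Mapping[int, str] | None = None,
    column_map: Mapping[str, Sequence[str]] | None = None,
    batch_frames: int = 256,
) -> Iterator[ConfigurationBatch]:
    """Stream a LAMMPS dump as SI configuration batches.

    ``column_map`` maps property names to dump column names for columns
    the built-in convention does not cover (e.g.
    ``{"per_particle_energy": ["c_pe"]}``); a ``c_*`` column whose name
    contains ``pe`` or ``energy`` is picked up automatically.
    """
    path = Path(path)
    u = get_unit_system(unit_system)
    pending: dict[str, dict[str, list[np.ndarray]]] = {}
    count = 0
    species_order: dict[str, np.ndarray] | None = None

    for lines, off in _iter_lammps_blocks(path):
        natoms, lo, hi, columns, rows = _parse_lammps_frame(lines, off)
        id_col = columns.index("id")
        label_col = _label_column(columns)
        prop_cols = _resolve_lammps_columns(columns, column_map)
        ids = np.array([int(r[id_col]) - 1 for r in rows])
        order = np.argsort(ids, kind="stable")
        rows = [rows[i] for i in order]
        if species_order is None:
            labels = [_row_label(r, label_col, columns, type_names) for r in rows]
            species_order = {}
            for local, lab in enumerate(labels):
                species_order.setdefault(lab, []).append(local)
            species_order = {k: np.asarray(v) for k, v in species_order.items()}
        def _num(v: str) -> float:
            try:
                return float(v)
            except ValueError:
                return np.nan  # label columns; never selected as a property

        data = np.array([[_num(v) for v in r] for r in rows])
        for sp, rows_idx in species_order.items():
            dest = pending.setdefault(sp, {})
            for prop, cols in prop_cols.items():
                vals = data[np.ix_(rows_idx, cols)]
                if prop == "positions":
                    vals = vals - lo[None, : vals.shape[1]]
                factor = 1.0 if prop == "image_flags" else u.factor_for(prop)
                dest.setdefault(prop, []).append(vals * factor)
        count += 1
        if count >= batch_frames:
            yield _flush_pending(pending, count)
            pending, count = {}, 0
    if count:
        yield _flush_pending(pending, count)


def _resolve_lammps_columns(columns, column_map) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for trip, prop in _LAMMPS_VECTOR_COLS.items():
        if all(c in columns for c in trip):
            out[prop] = [columns.index(c) for c in trip]
    for c in columns:
        if c.startswith(("c_", "v_")) and ("pe" in c or "energy" in c):
            out.setdefault("per_particle_energy", [columns.index(c)])
    for prop, cols in (column_map or {}).items():
        out[prop] = [columns.index(c) for c in cols]
    return out


def _flush_pending(pending, n_frames) -> ConfigurationBatch:
    species_data = {}
    for sp, props in pending.items():
        species_data[sp] = {
            prop: np.stack(frames, axis=1) for prop, frames in props.items()
        }
    return ConfigurationBatch(species_data=species_data, n_frames=n_frames)


def write_lammps_dump(
    store: TrajectoryStore,
    path: str | Path,
    unit_system: str | UnitSystem = "lammps_metal",
    properties: Sequence[str] = ("positions",),
) -> None:
    """Export a store to a LAMMPS custom dump (inverse of the reader)."""
    u = get_unit_system(unit_system)
    records = store.species_records
    box = store.box
    cols: list[str] = []
    col_names = {"positions": ("x", "y", "z"),
                 "unwrapped_positions": ("xu", "yu", "zu"),
                 "velocities": ("vx", "vy", "vz"),
                 "forces": ("fx", "fy", "fz"),
                 "image_flags": ("ix", "iy", "iz"),
                 "per_particle_energy": ("c_pe",)}
    for p in properties:
        cols.extend(col_names[p])
    arrays = {
        sp.name: {p: store.load_property(sp.name, p) for p in properties}
        for sp in records
    }
    n_frames = store.n_frames
    with open(path, "w") as fh:
        for f in range(n_frames):
            fh.write(f"ITEM: TIMESTEP\n{f}\n")
            fh.write(f"ITEM: NUMBER OF ATOMS\n{store.n_atoms}\n")
            flags = " ".join("pp" if p else "ff" for p in box.periodic_flags)
            fh.write(f"ITEM: BOX BOUNDS {flags}\n")
            for L in box.edge_lengths:
                fh.write(f"0.0 {L / u.length:.17g}\n")
            fh.write(f"ITEM: ATOMS id element {' '.join(cols)}\n")
            for sp in records:
                props = arrays[sp.name]
                for local, pid in enumerate(sp.particle_indices):
                    vals: list[str] = []
                    for p in properties:
                        a = props[p][local, f, :]
                        if p == "image_flags":
                            vals.extend(str(int(x)) for x in a)
                        else:
                            factor = u.factor_for(p)
                            vals.extend(f"{x / factor:.17g}" for x in a)
                    fh.write(f"{pid + 1} {sp.name} {' '.join(vals)}\n")


# ---------------------------------------------------------------------------
# Extended XYZ
# ---------------------------------------------------------------------------

def _parse_xyz_comment(comment: str):
    lattice = None
    m = re.search(r'Lattice="([^"]+)"', comment)
    if m:
        vals = [float(x) for x in m.group(1).split()]
        lattice = (vals[0], vals[4], vals[8])
    m = re.search(r"Properties=(\S+)", comment)
    props = []
    if m:
        toks = m.group(1).split(":")
        for i in range(0, len(toks), 3):
            props.append((toks[i], toks[i + 1], int(toks[i + 2])))
    return lattice, props


def _iter_xyz_frames(path: Path):
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line:
                return
            if not line.strip():
                continue
            try:
                natoms = int(line.strip())
            except ValueError:
                raise TruncatedFileError(
                    f"expected atom-count line, got {line.strip()!r}") from None
            comment = fh.readline()
            if not comment:
                raise TruncatedFileError("missing comment line")
            rows = []
            for _ in range(natoms):
                r = fh.readline()
                if not r:
                    raise TruncatedFileError("xyz frame truncated")
                rows.append(r.split())
            yield comment, rows


def peek_xyz(
    path: str | Path,
    unit_system: str | UnitSystem = "si",
    species_overrides: Mapping[str, dict] | None = None,
) -> tuple[BoxMetadata, list[SpeciesRecord]]:
    u = get_unit_system(unit_system)
    comment, rows = next(_iter_xyz_frames(Path(path)))
    lattice, props = _parse_xyz_comment(comment)
    if lattice is None:
        raise MDPostError("xyz comment line has no Lattice=\"...\" entry")
    by_species: dict[str, list[int]] = {}
    for i, row in enumerate(rows):
        by_species.setdefault(row[0], []).append(i)
    species = [_species_record(n, idx, species_overrides)
               for n, idx in sorted(by_species.items())]
    edges = tuple(L * u.length for L in lattice)
    return BoxMetadata(edges, unit_system=u.name), species


def read_xyz(
    path: str | Path,
    unit_system: str | UnitSystem = "si",
    batch_frames: int = 256,
) -> Iterator[ConfigurationBatch]:
    """Stream an extended-XYZ file as SI configuration batches."""
    u = get_unit_system(unit_system)
    pending: dict[str, dict[str, list[np.ndarray]]] = {}
    count = 0
    species_rows: dict[str, np.ndarray] | None = None
    for comment, rows in _iter_xyz_frames(Path(path)):
        _, props = _parse_xyz_comment(comment)
        if not props:
            props = [("species", "S", 1), ("pos", "R", 3)]
        if species_rows is None:
            by_sp: dict[str, list[int]] = {}
            for i, row in enumerate(rows):
                by_sp.setdefault(row[0], []).append(i)
            species_rows = {k: np.asarray(v) for k, v in by_sp.items()}
        col = 0
        spans: list[tuple[str, int, int]] = []
        for name, _kind, width in props:
            if name != "species":
                spans.append((name, col, col + width))
            col += width
        data = np.array([[float(v) for v in r[1:]] for r in rows])
        for sp, rows_idx in species_rows.items():
            dest = pending.setdefault(sp, {})
            for name, c0, c1 in spans:
                prop = _XYZ_PROP_NAMES.get(name, name)
                factor = 1.0 if prop == "image_flags" else u.factor_for(prop)
                dest.setdefault(prop, []).append(data[np.ix_(rows_idx, range(c0 - 1, c1 - 1))] * factor)
        count += 1
        if count >= batch_frames:
            yield _flush_pending(pending, count)
            pending, count = {}, 0
    if count:
        yield _flush_pending(pending, count)


def write_xyz(
    store: TrajectoryStore,
    path: str | Path,
    unit_system: str | UnitSystem = "si",
    properties: Sequence[str] = ("positions",),
) -> None:
    u = get_unit_system(unit_system)
    records = store.species_records
    L = [e / u.length for e in store.box.edge_lengths]
    lattice = f'Lattice="{L[0]:.17g} 0 0 0 {L[1]:.17g} 0 0 0 {L[2]:.17g}"'
    prop_decl = ["species:S:1"]
    for p in properties:
        width = 1 if p == "per_particle_energy" else 3
        kind = "I" if p == "image_flags" else "R"
        prop_decl.append(f"{_XYZ_NAMES_OUT[p]}:{kind}:{width}")
    arrays = {
        sp.name: {p: store.load_property(sp.name, p) for p in properties}
        for sp in records
    }
    # row order follows global particle index so round trips preserve layout
    row_order = sorted(
        ((pid, sp.name, local) for sp in records
         for local, pid in enumerate(sp.particle_indices))
    )
    with open(path, "w") as fh:
        for f in range(store.n_frames):
            fh.write(f"{store.n_atoms}\n")
            fh.write(f"{lattice} Properties={':'.join(prop_decl)}\n")
            for _pid, sp_name, local in row_order:
                vals: list[str] = []
                for p in properties:
                    a = arrays[sp_name][p][local, f, :]
                    if p == "image_flags":
                        vals.extend(str(int(x)) for x in a)
                    else:
                        factor = u.factor_for(p)
                        vals.extend(f"{x / factor:.17g}" for x in a)
                fh.write(f"{sp_name} {' '.join(vals)}\n")


# ---------------------------------------------------------------------------
# Flux tables
# ---------------------------------------------------------------------------

def read_flux_table(
    path: str | Path,
    column_map: Mapping[str, Sequence[int]],
    sample_interval: float = 1.0,
    scale: float = 1.0,
) -> dict[str, np.ndarray]:
    """Read a delimited text table of global time series.

    ``column_map`` maps series names to 0-based column index lists, e.g.
    ``{"thermal_flux": [1, 2, 3]}``.  Lines starting with ``#`` are
    comments.  Non-numeric cells raise with the offending row number.
    Returns name -> array of shape (n_rows, n_components), scaled by
    ``scale`` (unit conversion into SI is the caller's responsibility).
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = re.split(r"[,\s]+", s)
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise MDPostError(f"non-numeric cell at row {lineno} of {path}: {exc}") from None
    data = np.asarray(rows)
    out = {}
    for name, cols in column_map.items():
        out[name] = data[:, list(cols)] * scale
    return out


def export_curve(path: str | Path, **columns: np.ndarray) -> None:
    """Write named 1-D series as delimited text with a ``#`` header row.

    The standard export for RDF/ACF/MSD/running-integral curves, e.g.
    ``export_curve("rdf.dat", r=rdf.bin_centres, g=rdf.g_values)``.
    """
    names = list(columns)
    arrs = [np.asarray(columns[n]).ravel() for n in names]
    with open(path, "w") as fh:
        fh.write("# " + " ".join(names) + "\n")
        for row in zip(*arrs):
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def ingest_flux_table(
    store: TrajectoryStore,
    path: str | Path,
    column_map: Mapping[str, Sequence[int]],
    sample_interval: float | None = None,
    scale: float = 1.0,
) -> None:
    """Read a flux table and store each series under the Observables group."""
    series = read_flux_table(path, column_map, scale=scale)
    for name, values in series.items():
        store.write_observable(name, values, sample_interval=sample_interval)
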