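"""Project/Experiment façade with cached, dependency-resolving runs.

A :class:`Project` is a directory holding one results ledger and one
trajectory store per :class:`Experiment`.  ``Project.run`` executes a
registered calculator on selected experiments with three guarantees:

* *freshness* — a ledger record with identical parameters computed at
  the current store version is served without redoing numeric work;
* *staleness* — any ingest bumps the store version, so old records are
  never served after data changes;
* *dependency closure* — every calculator declares the properties it
  needs; missing derivable properties (unwrapped coordinates, flux
  series) are produced by the matching transformation before the
  calculator runs, and underivable ones fail up front, naming the
  missing input.

The calculator registry is open: :func:`register_calculator` adds
third-party calculators with the same caching and dependency handling.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import yaml

from . import dynamic, structural
from .errors import MDPostError, MissingInputError
from .io import peek_lammps_dump, peek_xyz, read_lammps_dump, read_xyz
from .results import ComputationRecord, ResultsLedger
from .store import TrajectoryStore
from .transformations import ensure_observable, ensure_unwrapped

_PROJECT_FILE = "project.yaml"

#: raw inputs each derivable property needs (observables prefixed "obs:")
_DERIVABLE = {
    "unwrapped_positions": ("positions",),
    "obs:ionic_current": ("velocities",),
    "obs:translational_dipole": ("positions",),
    "obs:thermal_flux": ("per_particle_energy", "velocities"),
    "obs:integrated_heat_current": ("per_particle_energy", "positions"),
    "obs:helfand_viscosity_moment": ("velocities", "positions"),
}


@dataclass
class CalculatorSpec:
    name: str
    func: Callable[..., Any]
    #: static tuple of requirements, or callable(params) -> tuple when the
    #: needed inputs depend on the method (Green-Kubo vs Einstein-Helfand)
    requires: tuple[str, ...] | Callable[[Mapping[str, Any]], tuple[str, ...]]
    units: str = ""
    scalar_name: str = "value"

    def requirements(self, params: Mapping[str, Any]) -> tuple[str, ...]:
        return self.requires(params) if callable(self.requires) else self.requires


CALCULATORS: dict[str, CalculatorSpec] = {}


def register_calculator(name: str, func: Callable[..., Any],
                        requires: Sequence[str] | Callable = (), units: str = "",
                        scalar_name: str = "value") -> None:
    req = requires if callable(requires) else tuple(requires)
    CALCULATORS[name] = CalculatorSpec(name, func, req, units, scalar_name)


@dataclass
class Experiment:
    """One simulation's data: a trajectory store plus ledger access."""

    name: str
    store: TrajectoryStore
    ledger: ResultsLedger
    n_executions: int = 0  # numeric runs actually performed

    @property
    def version(self) -> int:
        return self.store.version


class Project:
    """Container of experiments sharing one results ledger."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)
        self.ledger = ResultsLedger(self.path / "results.sqlite")
        self.experiments: dict[str, Experiment] = {}
        self._manifest = self.path / _PROJECT_FILE
        if self._manifest.exists():
            meta = yaml.safe_load(self._manifest.read_text()) or {}
            for name in meta.get("experiments", []):
                store_path = self.path / f"{name}.h5"
                if store_path.exists():
                    self.experiments[name] = Experiment(
                        name, TrajectoryStore.open(store_path), self.ledger
                    )
        else:
            self._save_manifest()

    def _save_manifest(self) -> None:
        self._manifest.write_text(
            yaml.safe_dump({"experiments": sorted(self.experiments)})
        )

    def close(self) -> None:
        for exp in self.experiments.values():
            exp.store.close()
        self.ledger.close()

    # -- experiment management --------------------------------------------

    def add_experiment(
        self,
        name: str,
        files: Sequence[str | Path] = (),
        file_format: str = "lammps",
        unit_system: str = "lammps_metal",
        timestep: float | None = None,
        temperature: float | None = None,
        species_overrides: Mapping[str, dict] | None = None,
        type_names: Mapping[int, str] | None = None,
        store: TrajectoryStore | None = None,
    ) -> Experiment:
        """Create an experiment from trajectory files (or adopt a store).

        Species metadata (masses, default charges) is resolved from the
        bundled element table; ``species_overrides`` wins.  All files
        given in one call are ingested in a single version bump.
        """
        if name in self.experiments:
            raise MDPostError(f"experiment {name!r} already exists")
        if store is None:
            if not files:
                raise MDPostError("add_experiment needs files or a store")
            peek = peek_lammps_dump if file_format == "lammps" else peek_xyz
            reader = read_lammps_dump if file_format == "lammps" else read_xyz
            kwargs = {"unit_system": unit_system}
            if file_format == "lammps":
                kwargs["type_names"] = type_names
            box, species = peek(files[0], species_overrides=species_overrides, **kwargs)
            if timestep is not None or temperature is not None:
                from .store import BoxMetadata

                box = BoxMetadata(box.edge_lengths, box.periodic_flags,
                                  timestep or box.timestep,
                                  temperature if temperature is not None else box.temperature,
                                  box.unit_system)
            store = TrajectoryStore.create(self.path / f"{name}.h5", box, species)

            def batches():
                for f in files:
                    yield from reader(f, **{k: v for k, v in kwargs.items()
                                            if k != "species_overrides"})

            store.ingest(batches())
        exp = Experiment(name, store, self.ledger)
        self.experiments[name] = exp
        self._save_manifest()
        return exp

    def remove_experiment(self, name: str) -> None:
        exp = self.experiments.pop(name)
        exp.store.close()
        p = self.path / f"{name}.h5"
        if p.exists():
            p.unlink()
        self._save_manifest()

    # -- execution ---------------------------------------------------------

    def _check_dependencies(self, exp: Experiment, spec: CalculatorSpec,
                            params: Mapping[str, Any]) -> None:
        store = exp.store
        for req in spec.requirements(params):
            if req == "stress":
                if store.has_observable("stress_offdiag") or any(
                    store.has_property(s, "stress") for s in store.species_names
                ):
                    continue
                raise MissingInputError(
                    f"calculator {spec.name!r} needs a 'stress_offdiag' "
                    "observable or per-atom 'stress'"
                )
            if req.startswith("obs:"):
                if store.has_observable(req[4:]):
                    continue
                raws = _DERIVABLE.get(req)
                if raws is None or not all(
                    all(store.has_property(s, r) or
                        (r in _DERIVABLE and all(store.has_property(s, rr)
                                                 for rr in _DERIVABLE[r]))
                        for r in raws)
                    for s in store.species_names
                ):
                    raise MissingInputError(
                        f"calculator {spec.name!r} needs observable {req[4:]!r}, "
                        f"which requires {raws or 'an external table'} for every species"
                    )
            else:
                for s in store.species_names:
                    if store.has_property(s, req):
                        continue
                    raws = _DERIVABLE.get(req)
                    if raws is None or not all(store.has_property(s, r) for r in raws):
                        raise MissingInputError(
                            f"calculator {spec.name!r} needs property {req!r} "
                            f"for species {s!r} and no transformation can provide it"
                        )

    def _resolve_dependencies(self, exp: Experiment, spec: CalculatorSpec,
                              params: Mapping[str, Any]) -> None:
        for req in spec.requirements(params):
            if req == "unwrapped_positions":
                for s in exp.store.species_names:
                    ensure_unwrapped(exp.store, s)
            elif req.startswith("obs:"):
                ensure_observable(exp.store, req[4:])

    def run(
        self,
        calculator_name: str,
        params: Mapping[str, Any] | None = None,
        experiments: Sequence[str] | None = None,
    ) -> dict[str, ComputationRecord]:
        """Run a calculator on selected experiments, serving fresh cached
        records where available; returns records keyed by experiment."""
        if calculator_name not in CALCULATORS:
            raise MDPostError(f"unknown calculator {calculator_name!r}; "
                              f"registered: {sorted(CALCULATORS)}")
        spec = CALCULATORS[calculator_name]
        params = dict(params or {})
        names = list(experiments) if experiments is not None else list(self.experiments)
        out: dict[str, ComputationRecord] = {}
        for name in names:
            exp = self.experiments[name]
            cached = self.ledger.find_fresh(calculator_name, params,
                                            exp.version, experiment=name)
            if cached is not None:
                out[name] = cached
                continue
            self._check_dependencies(exp, spec, params)
            self._resolve_dependencies(exp, spec, params)
            result = spec.func(exp.store, **params)
            exp.n_executions += 1
            record = _to_record(calculator_name, spec, result, params, exp)
            self.ledger.put_record(record)
            out[name] = record
        return out

    # -- comparison --------------------------------------------------------

    def compare(
        self,
        calculator_name: str,
        result_field: str = "value",
        across_parameter: str = "temperature",
    ):
        """Tabulate one result across experiments vs a parameter.

        The across value is taken from box metadata when it names a box
        attribute (temperature, volume, timestep), else from the stored
        run parameters.  Experiments without a matching record get an
        explicit gap marker (NaN).  Units are always SI.
        """
        import pandas as pd

        spec = CALCULATORS.get(calculator_name)
        rows = []
        for name, exp in self.experiments.items():
            if across_parameter in ("temperature", "volume", "timestep"):
                across = getattr(exp.store.box, across_parameter)
            else:
                across = None
            recs = self.ledger.query(calculator_name, experiment=name)
            if recs:
                rec = recs[-1]
                try:
                    value, unc = rec.scalar(result_field)
                except KeyError:
                    value, unc = np.nan, np.nan
                if across is None:
                    across = rec.parameters.get(across_parameter)
            else:
                value, unc = np.nan, np.nan
            rows.append({"experiment": name, across_parameter: across,
                         result_field: value, "uncertainty": unc,
                         "units": spec.units if spec else ""})
        return pd.DataFrame(rows)


def _to_record(name: str, spec: CalculatorSpec, result: Any,
               params: Mapping[str, Any], exp: Experiment) -> ComputationRecord:
    rec = ComputationRecord(
        calculator_name=name,
        parameters=dict(params),
        store_version_at_run=exp.version,
        experiment=exp.name,
        timestamp=time.time(),
    )
    if isinstance(result, dynamic.TransportResult):
        rec.scalar_results.append((spec.scalar_name, result.value,
                                   result.uncertainty, spec.units))
        for k, v in result.running_curve.items():
            rec.series_results[k] = np.asarray(v)
    elif isinstance(result, structural.RDFResult):
        rec.series_results["r"] = result.bin_centres
        rec.series_results["g"] = result.g_values
        rec.scalar_results.append(("number_density_beta",
                                   result.number_density_beta, 0.0, "m^-3"))
    elif isinstance(result, structural.ADFResult):
        rec.series_results["theta_deg"] = result.bin_centres_deg
        rec.series_results["density"] = result.density
    elif isinstance(result, tuple) and len(result) == 2 and np.isscalar(result[0]):
        rec.scalar_results.append((spec.scalar_name, float(result[0]),
                                   float(result[1]), spec.units))
    else:
        rec.series_results["result"] = np.asarray(result)
    return rec


# -- built-in calculator registrations --------------------------------------

def _diffusion_requires(params: Mapping[str, Any]) -> tuple[str, ...]:
    method = params.get("method", "einstein_helfand")
    return ("velocities",) if method == "green_kubo" else ("unwrapped_positions",)


def _conductivity_requires(params: Mapping[str, Any]) -> tuple[str, ...]:
    method = params.get("method", "green_kubo")
    if method == "green_kubo":
        return ("obs:ionic_current",)
    if method == "einstein_helfand":
        return ("obs:translational_dipole",)
    return ("unwrapped_positions",)  # Nernst-Einstein routes via diffusion


def _viscosity_requires(params: Mapping[str, Any]) -> tuple[str, ...]:
    method = params.get("method", "green_kubo")
    return ("stress",) if method == "green_kubo" else ("obs:helfand_viscosity_moment",)


def _thermal_requires(params: Mapping[str, Any]) -> tuple[str, ...]:
    method = params.get("method", "green_kubo")
    return (("obs:thermal_flux",) if method == "green_kubo"
            else ("obs:integrated_heat_current",))


def _rdf(store, pair, **kw):
    return structural.compute_rdf(store, tuple(pair), **kw)


def _adf(store, species_triple, cutoff, n_bins=180, zeta=0.0, frame_selection=None):
    p = structural.ADFParams(tuple(species_triple), cutoff, n_bins, zeta)
    return structural.compute_adf(store, p, frame_selection)


register_calculator("rdf", _rdf, requires=("positions",))
register_calculator("adf", _adf, requires=("positions",))
register_calculator("self_diffusion", dynamic.self_diffusion,
                    requires=_diffusion_requires, units="m^2/s", scalar_name="D")
register_calculator("distinct_diffusion", dynamic.distinct_diffusion,
                    requires=_diffusion_requires, units="m^2/s", scalar_name="D")
register_calculator("ionic_conductivity", dynamic.ionic_conductivity,
                    requires=_conductivity_requires, units="S/m", scalar_name="sigma")
register_calculator("viscosity", dynamic.viscosity,
                    requires=_viscosity_requires, units="Pa s", scalar_name="eta")
register_calculator("thermal_conductivity", dynamic.thermal_conductivity,
                    requires=_thermal_requires, units="W/(m K)", scalar_name="lambda")


def create_project(path: str | Path) -> Project:
    """Create (or reopen) a project directory."""
    return Project(path)
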