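# Methods

This note documents the models, estimators, defaults and numerical
choices behind mdpost, and what the synthetic test systems do and do
not demonstrate about real simulation data.

## Data model and units

Everything inside a trajectory store is strict SI. Unit-system presets
(`si`, `lammps_metal`, `lammps_real`) carry multiplicative factors for
length, time, mass, energy, charge and pressure; derived dimensions
(velocity, force) are composed from these. Conversion happens once at
ingest, so calculators never see engine units and experiments recorded
with different engines are directly comparable.

Per-species property arrays are stored as `(atoms, frames, components)`
HDF5 datasets, chunked `(min(64, n_atoms), min(256, n_frames),
n_components)` with gzip, extendable along the frame axis. Indexing is
0-based with half-open ranges throughout. The store version is bumped
exactly once per `ingest()` call — also when one call covers several
files — and every ledger record carries the version it was computed at;
records from older versions are never served from cache.

A memory planner (`plan_batches`) chooses the largest frame block whose
estimated footprint `n_atoms × frames × components × bytes ×
overhead_factor` fits a budget, falling back to atom-wise mini-batching
when a single frame does not fit. The overhead factor defaults to 3.0,
a deliberate allowance for the transient copies numpy operations make;
it is a tunable, not a measurement.

Species metadata (masses, default ion charge numbers) comes from a
bundled element table; user-supplied values override it. Unknown labels
get zero mass/charge and must be overridden for mass- or
charge-dependent observables.

## Structural estimators

**RDF.** Pair distances use the minimum-image convention for
orthorhombic boxes, valid up to half the shortest edge (larger cutoffs
are rejected). The histogram is normalised per bin by
`N_a · ρ_b · (4π/3)(r_out³ − r_in³) · n_frames` with
`ρ_b = (N_b − δ_ab)/V`, so an ideal gas has expectation exactly 1 for
every pairing, self pairs excluded. A per-bin counting (Poisson)
standard error `g/√counts` accompanies the curve and is propagated into
the derived quantities below. Defaults: 500 bins, cutoff = half box
edge.

**ADF.** For each centre atom, every neighbour pair within the cutoff
(both legs ≤ cutoff; the third side unconstrained) contributes its
angle with weight `1/(r_ij^ζ r_ik^ζ)`. Because the distance weighting
destroys any natural normalisation, the histogram is renormalised to
unit area over [0°, 180°] and the raw weighted counts are kept
alongside. ζ = 0 reduces to the plain angle histogram.

**Shell boundaries.** The RDF is smoothed with a Savitzky–Golay filter
(window 9, order 3 by default, runtime-tunable), peaks are located on
the smoothed curve, and each inter-peak minimum is refined by
golden-section search on a cubic-spline interpolant to an absolute
tolerance of one tenth of a bin width. The golden-section routine is
implemented in-package because the contract is an absolute radius
tolerance on a bounded interval.

**Coordination number.** `4πρ ∫ r² g dr` over `[r_{i−1}, r_i]`
(`r_0 = 0`), trapezoid rule on the bin-centre grid with interpolated
endpoints; ρ is the same density used to normalise the RDF, which makes
the integral reproduce the raw neighbour count up to quadrature error.
Uncertainty: per-bin Poisson errors through the trapezoid weights.

**PMF.** `w = −k_B T ln g` where `g > 0`; zero-count bins are masked
(NaN), and the minimum is located with the same smoothing +
golden-section machinery on the largest contiguous valid run.

**Kirkwood–Buff.** The running integral `G(r) = 4π ∫₀^r s²(g−1) ds` is
reported to the RDF cutoff; extrapolation of the infinite upper limit
is left to the user. CN, PMF and KB are pure functions of a stored RDF
result — they never touch the trajectory again.

## Correlation machinery

The ACF estimator is multi-origin and FFT-based with the unbiased
`1/(n − lag)` normalisation; the MSD is single-origin per window.
Ensembles are windows of length `data_range` starting every
`correlation_time` frames; for per-particle series every particle
contributes a member per window. Windows may overlap when
`correlation_time < data_range`; the standard error uses the raw member
count with no overlap correction, which understates errors for heavily
overlapped windows — with disjoint windows the reported ±1 SE interval
covers the truth at roughly the nominal rate (checked empirically at
55–85% over 50 seeds in the test suite).

Uncertainties of derived scalars are *whole-curve* ensemble statistics:
the Green–Kubo value is the trapezoid integral of the mean ACF, with
the standard error of the per-member integrals; the Einstein–Helfand
slope is a weighted least-squares fit to the mean MSD (weights
1/SEM², uniform where SEMs vanish), with the standard error of
per-member slopes. Lags within one member are strongly correlated, so
propagating per-lag SEMs as if independent would be badly
over-confident; ensembling the functional avoids that. For
deterministic inputs (exact lines) the residual-based error is used and
is zero.

Global flux series (ionic current, dipole, stress, heat flux) are
correlated per Cartesian component, treating each component as an
ensemble member. The isotropic average over components has the same
expectation as the dot-product form divided by the component count
(this is how the 1/3 in the Green–Kubo prefactors is realised) and
triples the statistics behind the error bar.

Defaults: `data_range` = half the series, `correlation_time` =
`data_range/10`, integration range = `data_range`, MSD fit window =
[10%, 50%] of `data_range`, trapezoid integration, d = 3 fixed
(lower-dimensional systems out of scope).

## Transport conventions

- Self-diffusion: GK `D = (1/3)⟨∫ v_i(t)·v_i(0) dt⟩_i`; EH
  `D = slope/(2d)` of the per-atom MSD.
- Distinct diffusion uses the printed `1/(N_a N_b)` normalisation
  (recorded in the result parameters, since per-particle conventions
  also circulate). The double sum is evaluated through
  `Σ_ij x_i·x_j = (Σx)·(Σx) − Σ_i x_i·x_i`, with self terms subtracted
  only when the two species coincide.
- Ionic conductivity: GK `σ = β/(3V) ∫⟨J·J⟩`; EH applies the same 1/V
  to the dipole MSD so both routes estimate the same physical σ.
  The Nernst–Einstein form is implemented as
  `σ_NE = q²β/V · Σ_a N_a z_a² D_a`, and the corrected form adds
  `q²β/V · Σ_bg N_b N_g z_b z_g D_bg`. With these weights NE equals the
  Green–Kubo value exactly for uncorrelated ions (the package's
  consistency tests rely on this); a `convention="printed"` switch
  reproduces the mass-fraction variant `q²β/(3V) Σ x_a z_a² D_a` found
  in parts of the literature, which differs by a species-dependent
  scale.
- Viscosity: GK `η = (V/3k_BT) Σ_pairs ∫⟨P_ab P_ab⟩` over the xy, xz,
  yz stress components; EH uses the summed momentum–position moment
  `L_ab = Σ_i m v_a r_b` with `η = β·slope/(2dV)` per component
  averaged. Off-diagonal stress comes from a global `stress_offdiag`
  observable (Pa) or per-atom symmetric stress (Voigt order, Pa·m³)
  summed and divided by V.
- Thermal conductivity: the stored heat flux is *extensive*
  (`Σ e_i v_i` minus the optional pair term, no 1/V), so the GK
  prefactor is `1/(3Vk_BT²)`; the EH route uses the integrated heat
  current `Σ e_i r_i` with `λ = slope/(2dVk_BT²)` per component.
  Keeping fluxes extensive makes exact system replication double every
  stored flux, which the tests exploit. The pair-interaction term
  contracts the printed force expression as `(F_ij·(v_i+v_j)) r_ij`
  (scalar product with the velocity sum); the alternative outer-product
  reading would produce a rank-2 object incompatible with a vector
  flux. It is only computed when per-pair forces and separations are
  supplied — the package makes no assumption about interaction models —
  and the result records which terms were included.

## Transformations and dependency resolution

Unwrapping either applies stored image flags exactly
(`r + n·L`) or detects box hops (a per-frame displacement beyond L/2 on
any axis is read as a crossing; first frame is the reference, axes are
processed independently). The hop detector silently mis-unwraps if the
true displacement between stored frames ever exceeds L/2 — this is
undetectable from wrapped data alone and is the documented price of not
storing flags. On data where both apply they agree to the bit.

Calculators declare their required inputs per method. `Project.run`
serves a fresh ledger record if one exists, otherwise checks that every
requirement is present or derivable, runs the needed transformations
(writing derived series back to the store under `Observables/` or the
species group), executes, and persists the record. Underivable inputs
fail before any numeric work, naming the missing quantity. Parameter
matching for the cache is exact on a canonicalised serialisation
(sorted keys, floats via `float.hex`, so bitwise); presentation-only
options under `plot_options` are excluded from the key.

## Molecule mapping

Bonds are edges of a distance graph (all-pairs minimum-image search,
O(N²), accepted for the reference configuration; mapping fixed groups
over the trajectory is O(N)). Connected components grouped by
composition form molecule groups; membership is built on one reference
frame with an optional second-frame cross-check that warns on changes
(reactive systems are out of scope). Reference graphs from SMILES are
heavy-atom by default since trajectories often omit hydrogens. The
approximate isomorphism score is `1 − GED_bound/max(|E|,|V|)` using the
first upper bound from networkx's edit-distance optimiser with a 0.95
threshold — a pragmatic choice; "approximately isomorphic" has no
canonical metric. COM trajectories are mass-weighted means of member
unwrapped positions, members first made whole across the boundary
relative to an anchor atom, and are written back as a new species group
so every calculator applies to the coarse-grained system unchanged.

## Synthetic fixtures: what they show and what they don't

The generators produce *statistical* systems whose observables are
exact in expectation: i.i.d. uniform gases (g ≡ 1), Gaussian random
walks (MSD = 6Dt; the white-noise velocity integral equals 3D exactly
under the trapezoid's half-weight at lag 0), Ornstein–Uhlenbeck
velocities and fluxes generated with the exact AR(1) transition (ACF =
σ²e^{−t/τ} at any timestep, integral σ²τ), simple-cubic lattices (6
first neighbours), rigid dimers on jittered grids with random-walking
centres (grid placement guarantees distinct dimers never sit within
bonding distance in the reference frame; the configuration is shifted
so molecules straddle the periodic boundary), and independent charged
walkers (zero cross-correlation, so Nernst–Einstein is exact). All
randomness flows through one generator family (`numpy.random.default_rng`,
PCG64) and a fixed seed is bitwise-reproducible.

Passing against these fixtures validates the estimators, the
normalisations, the unit and storage plumbing, and the uncertainty
calibration. It does **not** validate physics the fixtures lack:
interatomic forces, momentum conservation, hydrodynamic long-time
tails, finite-size effects, or cross-correlations between real ions.
Problem sizes in the tests and the acceptance script (500-atom gases,
100-walker fluids with 5000 frames, 216-atom lattices, 50-dimer
fluids, 10⁶-sample flux series for the 5%-level Green–Kubo oracles)
were chosen so each closed form is resolved several standard errors
inside its tolerance.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- Overlapping correlation windows understate reported errors (no
  overlap correction).
- The box-hop unwrapper's undersampling failure mode is silent.
- The Nernst–Einstein printed (mass-fraction) convention and the
  default particle-count convention differ by a species-dependent
  factor; results record which was used.
- Kirkwood–Buff integrals are reported to the cutoff without
  finite-size or tail corrections; structure factors are out of scope.
- No GROMACS/AMBER binary formats; the HDF5 layout is H5MD-flavoured,
  not standard-compliant.
- Reactive (time-varying) bonding is unsupported in molecule mapping.
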