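"""Time-correlation machinery and transport-coefficient calculators.

Transport coefficients are computed two ways:

* Green-Kubo: the running time integral of an equilibrium flux
  autocorrelation function (ACF), with a user-set integration range;
* Einstein-Helfand: the long-time slope of the mean square displacement
  (MSD) of the integrated flux, fitted by weighted least squares.

Statistics come from *ensembling*: the series is cut into windows of
length ``data_range`` starting every ``correlation_time`` frames (and,
for per-particle series, every particle is a member), the per-window
ACF/MSD is averaged and a standard error per lag is reported.  Windows
may overlap when ``correlation_time < data_range``; the SEM uses the
raw member count with no overlap correction (documented limitation).

The ACF estimator is multi-origin and FFT-based with the unbiased
1/(n - lag) normalisation; the MSD is single-origin per window.
All quantities SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import MDPostError, MissingInputError
from .store import TrajectoryStore
from .transformations import ensure_observable, ensure_unwrapped
from .units import BOLTZMANN, ELEMENTARY_CHARGE

DIMENSION = 3  # spatial dimension; lower-dimensional systems out of scope


@dataclass
class CorrelationResult:
    lags: np.ndarray  # s, starting at 0
    mean_values: np.ndarray
    sem_values: np.ndarray
    n_ensembles: int
    kind: str  # 'acf' | 'msd'
    single_ensemble: bool = False
    #: per-member curves (n_ensembles, n_lags); kept so downstream error
    #: estimates can ensemble whole-curve functionals (integral, slope)
    #: instead of assuming independent lags
    members: np.ndarray | None = None


@dataclass
class TransportResult:
    property: str
    method: str
    value: float  # SI
    uncertainty: float  # SI
    running_curve: dict[str, np.ndarray] = field(default_factory=dict)
    parameters: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# correlation engine
# ---------------------------------------------------------------------------

def autocorrelation_fft(x: np.ndarray) -> np.ndarray:
    """Multi-origin ACF of a (n, c) series, summed over components:
    acf[k] = 1/(n-k) * sum_t x(t+k).x(t)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, n=nfft, axis=0)
    power = (f * f.conj()).real.sum(axis=1)
    raw = np.fft.irfft(power, n=nfft)[:n]
    return raw / (n - np.arange(n))


def crosscorrelation_fft(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """c[k] = 1/(n-k) * sum_t a(t+k).b(t) for (n, c) series a, b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fa = np.fft.rfft(a, n=nfft, axis=0)
    fb = np.fft.rfft(b, n=nfft, axis=0)
    raw = np.fft.irfft((fa * fb.conj()).sum(axis=1), n=nfft)[:n]
    return raw / (n - np.arange(n))


def _windows(n_frames: int, data_range: int, correlation_time: int) -> list[int]:
    if data_range > n_frames:
        raise MDPostError(
            f"data_range {data_range} exceeds series length {n_frames}; "
            f"need at least {data_range} frames"
        )
    if correlation_time < 1:
        raise ValueError("correlation_time must be at least 1 frame")
    return list(range(0, n_frames - data_range + 1, correlation_time))


def ensemble_correlate(
    series: np.ndarray,
    data_range: int,
    correlation_time: int,
    kind: str = "acf",
    sample_interval: float = 1.0,
) -> CorrelationResult:
    """Ensemble-averaged ACF or MSD of a global (frames, c) or
    per-particle (atoms, frames, c) series."""
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if series.ndim == 2:
        series = series[None, :, :]
    n_atoms, n_frames, _ = series.shape
    starts = _windows(n_frames, data_range, correlation_time)

    members = []
    for a in range(n_atoms):
        for s in starts:
            w = series[a, s:s + data_range, :]
            if kind == "acf":
                members.append(autocorrelation_fft(w))
            elif kind == "msd":
                d = w - w[0]
                members.append((d * d).sum(axis=1))
            else:
                raise ValueError(f"unknown correlation kind {kind!r}")
    stack = np.stack(members)
    n_ens = stack.shape[0]
    mean = stack.mean(axis=0)
    if n_ens > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n_ens)
    else:
        sem = np.zeros_like(mean)
    return CorrelationResult(
        lags=np.arange(data_range) * sample_interval,
        mean_values=mean,
        sem_values=sem,
        n_ensembles=n_ens,
        kind=kind,
        single_ensemble=(n_ens == 1),
        members=stack,
    )


def running_integral(
    corr: CorrelationResult,
    integration_range: int | None = None,
) -> tuple[np.ndarray, float, float]:
    """Cumulative trapezoidal integral of the mean curve over its lags.

    Returns (running series, value at integration_range, uncertainty).
    With per-member curves available the uncertainty is the standard
    error over member integrals (the whole-curve functional, robust to
    correlated lags); otherwise per-lag SEMs are propagated through the
    trapezoid weights under an independent-lag assumption.
    """
    n = len(corr.lags)
    if integration_range is None:
        integration_range = n
    if integration_range > n:
        raise MDPostError(
            f"integration_range {integration_range} exceeds data_range {n}"
        )
    running = cumulative_trapezoid(corr.mean_values, corr.lags, initial=0.0)
    t = corr.lags[:integration_range]
    if corr.members is not None and corr.n_ensembles > 1:
        vals = np.trapezoid(corr.members[:, :integration_range], t, axis=1)
        unc = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    else:
        w = np.zeros(integration_range)
        if integration_range > 1:
            w[1:] += 0.5 * np.diff(t)
            w[:-1] += 0.5 * np.diff(t)
        unc = float(np.sqrt(np.sum((w * corr.sem_values[:integration_range]) ** 2)))
    return running, float(running[integration_range - 1]), unc


def msd_slope(
    corr: CorrelationResult,
    fit_window: tuple[int, int],
) -> tuple[float, float]:
    """Weighted least-squares slope of an MSD over a [lo, hi) lag-index
    window; weights 1/sem^2 (uniform if any sem in the window is 0).

    Returns (slope, standard error).  With per-member curves available
    the error is the standard error over member slopes — lags within a
    window are strongly correlated, so ensembling the whole-curve
    functional is the calibrated estimate; otherwise the error is
    residual-scaled, so an exact line reports 0 either way."""
    lo, hi = fit_window
    n = len(corr.lags)
    if not (0 <= lo < hi <= n):
        raise MDPostError(f"fit_window {fit_window} outside available lags [0, {n})")
    if hi - lo < 2:
        raise MDPostError("fit window needs at least two lags")
    t = corr.lags[lo:hi]
    y = corr.mean_values[lo:hi]
    s = corr.sem_values[lo:hi]
    w = 1.0 / s**2 if np.all(s > 0) else np.ones_like(t)
    W = w.sum()
    tbar = (w * t).sum() / W
    ybar = (w * y).sum() / W
    sxx = (w * (t - tbar) ** 2).sum()
    slope = (w * (t - tbar) * (y - ybar)).sum() / sxx
    if corr.members is not None and corr.n_ensembles > 1:
        tc = t - t.mean()
        member_slopes = (corr.members[:, lo:hi] @ tc) / (tc @ tc)
        err = float(member_slopes.std(ddof=1) / np.sqrt(len(member_slopes)))
    else:
        intercept = ybar - slope * tbar
        resid = y - (intercept + slope * t)
        dof = len(t) - 2
        s2 = (w * resid**2).sum() / dof if dof > 0 else 0.0
        err = float(np.sqrt(s2 / sxx))
    return float(slope), err


def _default_ranges(n_frames: int, data_range, correlation_time,
                    integration_range, fit_window):
    if data_range is None:
        data_range = max(2, n_frames // 2)
    if correlation_time is None:
        correlation_time = max(1, data_range // 10)
    if integration_range is None:
        integration_range = data_range
    if fit_window is None:
        fit_window = (max(1, data_range // 10), max(2, data_range // 2))
    return data_range, correlation_time, integration_range, fit_window


# ---------------------------------------------------------------------------
# transport calculators
# ---------------------------------------------------------------------------

def self_diffusion(
    store: TrajectoryStore,
    species: str,
    method: str = "einstein_helfand",
    data_range: int | None = None,
    correlation_time: int | None = None,
    integration_range: int | None = None,
    fit_window: tuple[int, int] | None = None,
) -> TransportResult:
    """Self-diffusion coefficient of one species.

    Green-Kubo: D = (1/3) ∫ <v_i(t).v_i(0)> dt averaged over atoms;
    Einstein-Helfand: D = slope of the per-atom MSD / (2 d).
    """
    dt = store.box.timestep
    params = dict(species=species, method=method)
    if method == "green_kubo":
        v = store.load_property(species, "velocities")
        dr, ct, ir, fw = _default_ranges(v.shape[1], data_range, correlation_time,
                                         integration_range, fit_window)
        corr = ensemble_correlate(v, dr, ct, "acf", dt)
        running, value, unc = running_integral(corr, ir)
        D, D_unc = value / 3.0, unc / 3.0
        curve = {"lags": corr.lags, "acf": corr.mean_values,
                 "acf_sem": corr.sem_values, "running_integral": running}
        params.update(data_range=dr, correlation_time=ct, integration_range=ir)
    elif method == "einstein_helfand":
        r = ensure_unwrapped(store, species)
        dr, ct, ir, fw = _default_ranges(r.shape[1], data_range, correlation_time,
                                         integration_range, fit_window)
        corr = ensemble_correlate(r, dr, ct, "msd", dt)
        slope, err = msd_slope(corr, fw)
        D, D_unc = slope / (2 * DIMENSION), err / (2 * DIMENSION)
        curve = {"lags": corr.lags, "msd": corr.mean_values,
                 "msd_sem": corr.sem_values}
        params.update(data_range=dr, correlation_time=ct, fit_window=list(fw))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TransportResult("self_diffusion", method, D, D_unc, curve, params)


def distinct_diffusion(
    store: TrajectoryStore,
    species_pair: tuple[str, str],
    method: str = "green_kubo",
    data_range: int | None = None,
    correlation_time: int | None = None,
    integration_range: int | None = None,
    fit_window: tuple[int, int] | None = None,
) -> TransportResult:
    """Distinct (cross) diffusion coefficient of a species pair, with the
    printed 1/(N_a N_b) normalisation recorded in the parameters.

    The distinct double sum is evaluated through the pair-sum identity
    sum_ij x_i.x_j = (sum_i x_i).(sum_j x_j) - sum_i x_i.x_i (self terms
    subtracted only when the species coincide).
    """
    alpha, beta = species_pair
    same = alpha == beta
    dt = store.box.timestep
    n_a = store.species(alpha).count
    n_b = store.species(beta).count
    params = dict(species_pair=list(species_pair), method=method,
                  normalisation="1/(N_alpha N_beta)")

    if method == "green_kubo":
        va = store.load_property(alpha, "velocities")
        vb = va if same else store.load_property(beta, "velocities")
        n_frames = va.shape[1]
        dr, ct, ir, fw = _default_ranges(n_frames, data_range, correlation_time,
                                         integration_range, fit_window)
        Sa, Sb = va.sum(axis=0), vb.sum(axis=0)
        starts = _windows(n_frames, dr, ct)
        members = []
        for s in starts:
            cross = crosscorrelation_fft(Sa[s:s + dr], Sb[s:s + dr])
            if same:
                for i in range(va.shape[0]):
                    cross = cross - autocorrelation_fft(va[i, s:s + dr])
            members.append(cross)
        stack = np.stack(members)
        mean = stack.mean(axis=0)
        sem = (stack.std(axis=0, ddof=1) / np.sqrt(len(members))
               if len(members) > 1 else np.zeros_like(mean))
        corr = CorrelationResult(np.arange(dr) * dt, mean, sem, len(members), "acf", members=stack)
        running, value, unc = running_integral(corr, ir)
        D = value / (3.0 * n_a * n_b)
        D_unc = unc / (3.0 * n_a * n_b)
        curve = {"lags": corr.lags, "acf": mean, "running_integral": running}
        params.update(data_range=dr, correlation_time=ct, integration_range=ir)
    elif method == "einstein_helfand":
        ra = ensure_unwrapped(store, alpha)
        rb = ra if same else ensure_unwrapped(store, beta)
        n_frames = ra.shape[1]
        dr, ct, ir, fw = _default_ranges(n_frames, data_range, correlation_time,
                                         integration_range, fit_window)
        starts = _windows(n_frames, dr, ct)
        members = []
        for s in starts:
            da = ra[:, s:s + dr, :] - ra[:, s:s + dr][:, :1, :]
            db = da if same else rb[:, s:s + dr, :] - rb[:, s:s + dr][:, :1, :]
            Sa, Sb = da.sum(axis=0), db.sum(axis=0)
            prod = (Sa * Sb).sum(axis=1)
            if same:
                prod = prod - (da * da).sum(axis=(0, 2))
            members.append(prod)
        stack = np.stack(members)
        mean = stack.mean(axis=0)
        sem = (stack.std(axis=0, ddof=1) / np.sqrt(len(members))
               if len(members) > 1 else np.zeros_like(mean))
        corr = CorrelationResult(np.arange(dr) * dt, mean, sem, len(members), "msd", members=stack)
        slope, err = msd_slope(corr, fw)
        D = slope / (2 * DIMENSION * n_a * n_b)
        D_unc = err / (2 * DIMENSION * n_a * n_b)
        curve = {"lags": corr.lags, "msd": mean, "msd_sem": sem}
        params.update(data_range=dr, correlation_time=ct, fit_window=list(fw))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TransportResult("distinct_diffusion", method, D, D_unc, curve, params)


def _flux_correlate(
    series: np.ndarray,
    data_range: int,
    correlation_time: int,
    kind: str,
    sample_interval: float,
) -> tuple[CorrelationResult, int]:
    """Correlate a global (frames, c) flux treating each Cartesian
    component as an ensemble member.

    The isotropic average over components has the same expectation as
    the dot-product correlation divided by c, but triples the member
    count, so reported uncertainties are calibrated against the real
    component-to-component scatter.  Returns (result, n_components);
    multiply the mean by c to recover the dot-product convention.
    """
    series = np.asarray(series, dtype=float)
    comps = series.T[:, :, None]  # (c, frames, 1)
    return (ensemble_correlate(comps, data_range, correlation_time, kind,
                               sample_interval), series.shape[1])


def _beta(store: TrajectoryStore) -> float:
    T = store.box.temperature
    if T <= 0:
        raise MissingInputError("store temperature must be positive for transport")
    return 1.0 / (BOLTZMANN * T)


def ionic_conductivity(
    store: TrajectoryStore,
    method: str = "green_kubo",
    data_range: int | None = None,
    correlation_time: int | None = None,
    integration_range: int | None = None,
    fit_window: tuple[int, int] | None = None,
    convention: str = "number",
    diffusion_results: dict | None = None,
) -> TransportResult:
    """Ionic conductivity by Green-Kubo (current ACF), Einstein-Helfand
    (dipole MSD), Nernst-Einstein, or corrected Nernst-Einstein.

    NE conventions: ``"number"`` (default) weights each species by its
    particle count, sigma = q^2 beta / V * sum_a N_a z_a^2 D_a, which is
    exactly consistent with the Green-Kubo current integral for
    uncorrelated ions; ``"printed"`` uses the mass-fraction form
    q^2 beta/(3V) * sum_a x_a z_a^2 D_a found in parts of the
    literature.  ``diffusion_results`` may supply precomputed
    :class:`TransportResult` objects keyed by species (and pair tuples
    for the corrected form); otherwise they are computed on the fly.
    """
    beta = _beta(store)
    V = store.box.volume
    dt = store.box.timestep
    params = dict(method=method, convention=convention)

    if method == "green_kubo":
        J = ensure_observable(store, "ionic_current")
        dr, ct, ir, fw = _default_ranges(J.shape[0], data_range, correlation_time,
                                         integration_range, fit_window)
        corr, c = _flux_correlate(J, dr, ct, "acf", dt)
        running, value, unc = running_integral(corr, ir)
        # beta/(3V) * integral of <J.J> = beta/(3V) * c * per-component mean
        sigma = beta * c / (3.0 * V) * value
        sigma_unc = beta * c / (3.0 * V) * unc
        curve = {"lags": corr.lags, "acf": corr.mean_values, "running_integral": running}
        params.update(data_range=dr, correlation_time=ct, integration_range=ir)
    elif method == "einstein_helfand":
        M = ensure_observable(store, "translational_dipole")
        dr, ct, ir, fw = _default_ranges(M.shape[0], data_range, correlation_time,
                                         integration_range, fit_window)
        corr, c = _flux_correlate(M, dr, ct, "msd", dt)
        slope, err = msd_slope(corr, fw)
        sigma = beta * c * slope / (2 * DIMENSION * V)
        sigma_unc = beta * c * err / (2 * DIMENSION * V)
        curve = {"lags": corr.lags, "msd": corr.mean_values, "msd_sem": corr.sem_values}
        params.update(data_range=dr, correlation_time=ct, fit_window=list(fw))
    elif method in ("nernst_einstein", "corrected_nernst_einstein"):
        species = store.species_records
        diffusion_results = diffusion_results or {}
        total_mass_frac = {sp.name: sp.mass_fraction for sp in species}
        acc, var = 0.0, 0.0
        for sp in species:
            if sp.charge_number == 0:
                continue
            res = diffusion_results.get(sp.name)
            if res is None:
                res = self_diffusion(store, sp.name, "einstein_helfand",
                                     data_range, correlation_time,
                                     integration_range, fit_window)
            weight = (sp.count if convention == "number"
                      else total_mass_frac[sp.name] / 3.0)
            acc += weight * sp.charge_number**2 * res.value
            var += (weight * sp.charge_number**2 * res.uncertainty) ** 2
        if method == "corrected_nernst_einstein":
            names = [sp.name for sp in species if sp.charge_number != 0]
            recs = {sp.name: sp for sp in species}
            for i, a in enumerate(names):
                for b in names[i:]:
                    res = diffusion_results.get((a, b))
                    if res is None:
                        res = distinct_diffusion(store, (a, b), "green_kubo",
                                                 data_range, correlation_time,
                                                 integration_range, fit_window)
                    mult = 1.0 if a == b else 2.0  # ordered-pair sum
                    if convention == "number":
                        weight = recs[a].count * recs[b].count
                    else:
                        weight = total_mass_frac[a] * total_mass_frac[b] / 3.0
                    w = mult * weight * recs[a].charge_number * recs[b].charge_number
                    acc += w * res.value
                    var += (w * res.uncertainty) ** 2
        pref = ELEMENTARY_CHARGE**2 * beta / V
        sigma, sigma_unc = pref * acc, pref * np.sqrt(var)
        curve = {}
    else:
        raise ValueError(f"unknown method {method!r}")
    return TransportResult("ionic_conductivity", method, float(sigma),
                           float(sigma_unc), curve, params)


def _offdiagonal_stress(store: TrajectoryStore) -> np.ndarray:
    """(frames, 3) off-diagonal stress P_xy, P_xz, P_yz in Pa.

    Preferred source is the global ``stress_offdiag`` observable; per-atom
    symmetric stress (Voigt order xx, yy, zz, xy, xz, yz, in Pa·m^3)
    is summed and divided by the box volume otherwise.
    """
    if store.has_observable("stress_offdiag"):
        return store.load_observable("stress_offdiag")
    total = None
    for sp in store.species_records:
        if store.has_property(sp.name, "stress"):
            s = store.load_property(sp.name, "stress")[..., 3:6].sum(axis=0)
            total = s if total is None else total + s
    if total is None:
        raise MissingInputError(
            "viscosity needs a 'stress_offdiag' observable or per-atom 'stress'"
        )
    return total / store.box.volume


def viscosity(
    store: TrajectoryStore,
    method: str = "green_kubo",
    data_range: int | None = None,
    correlation_time: int | None = None,
    integration_range: int | None = None,
    fit_window: tuple[int, int] | None = None,
) -> TransportResult:
    """Shear viscosity from off-diagonal stress (GK) or the momentum-
    position Helfand moment (EH); the 1/3 of the isotropic average is
    realised by summing the xy, xz, yz components inside the ACF/MSD."""
    beta = _beta(store)
    V = store.box.volume
    dt = store.box.timestep
    params = dict(method=method)
    if method == "green_kubo":
        P = _offdiagonal_stress(store)
        dr, ct, ir, fw = _default_ranges(P.shape[0], data_range, correlation_time,
                                         integration_range, fit_window)
        corr, c = _flux_correlate(P, dr, ct, "acf", dt)
        running, value, unc = running_integral(corr, ir)
        # V/(3 k T) * sum over off-diagonal pairs = V beta / 3 * c * mean
        eta = V * beta * c / 3.0 * value
        eta_unc = V * beta * c / 3.0 * unc
        curve = {"lags": corr.lags, "acf": corr.mean_values, "running_integral": running}
        params.update(data_range=dr, correlation_time=ct, integration_range=ir)
    elif method == "einstein_helfand":
        L = ensure_observable(store, "helfand_viscosity_moment")
        dr, ct, ir, fw = _default_ranges(L.shape[0], data_range, correlation_time,
                                         integration_range, fit_window)
        corr, c = _flux_correlate(L, dr, ct, "msd", dt)
        slope, err = msd_slope(corr, fw)
        eta = beta * c * slope / (2 * DIMENSION * V)
        eta_unc = beta * c * err / (2 * DIMENSION * V)
        curve = {"lags": corr.lags, "msd": corr.mean_values, "msd_sem": corr.sem_values}
        params.update(data_range=dr, correlation_time=ct, fit_window=list(fw))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TransportResult("viscosity", method, float(eta), float(eta_unc),
                           curve, params)


def thermal_conductivity(
    store: TrajectoryStore,
    method: str = "green_kubo",
    data_range: int | None = None,
    correlation_time: int | None = None,
    integration_range: int | None = None,
    fit_window: tuple[int, int] | None = None,
) -> TransportResult:
    """Thermal conductivity from the heat-flux ACF (GK) or the integrated
    heat current MSD (EH).  The stored flux is extensive (no 1/V), so the
    GK prefactor is 1/(3 V k_B T^2)."""
    T = store.box.temperature
    V = store.box.volume
    dt = store.box.timestep
    if T <= 0:
        raise MissingInputError("store temperature must be positive")
    params = dict(method=method)
    if method == "green_kubo":
        J = ensure_observable(store, "thermal_flux")
        dr, ct, ir, fw = _default_ranges(J.shape[0], data_range, correlation_time,
                                         integration_range, fit_window)
        corr, c = _flux_correlate(J, dr, ct, "acf", dt)
        running, value, unc = running_integral(corr, ir)
        pref = c / (3.0 * V * BOLTZMANN * T**2)
        lam, lam_unc = pref * value, pref * unc
        curve = {"lags": corr.lags, "acf": corr.mean_values, "running_integral": running}
        params.update(data_range=dr, correlation_time=ct, integration_range=ir)
    elif method == "einstein_helfand":
        Jint = ensure_observable(store, "integrated_heat_current")
        dr, ct, ir, fw = _default_ranges(Jint.shape[0], data_range, correlation_time,
                                         integration_range, fit_window)
        corr, c = _flux_correlate(Jint, dr, ct, "msd", dt)
        slope, err = msd_slope(corr, fw)
        pref = c / (2 * DIMENSION * V * BOLTZMANN * T**2)
        lam, lam_unc = pref * slope, pref * err
        curve = {"lags": corr.lags, "msd": corr.mean_values, "msd_sem": corr.sem_values}
        params.update(data_range=dr, correlation_time=ct, fit_window=list(fw))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TransportResult("thermal_conductivity", method, float(lam),
                           float(lam_unc), curve, params)
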