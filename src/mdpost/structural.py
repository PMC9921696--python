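"""Histogram-based structural calculators.

The radial distribution function g_ab(r) is the ratio of the observed
pair density around a particle of species a to the ideal-gas
expectation.  It is normalised per bin by
``N_a * rho_b * (4pi/3)(r_out^3 - r_in^3) * n_frames`` with
``rho_b = (N_b - delta_ab)/V``, so an ideal gas gives g = 1 in
expectation for every pairing, including a = b (self pairs excluded).

All derived quantities — coordination numbers, potential of mean force,
Kirkwood-Buff integrals — are pure functions of an :class:`RDFResult`;
they never re-read trajectories.

Distances use the minimum-image convention for orthorhombic boxes, valid
for separations up to half the shortest box edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, savgol_filter

from .errors import MDPostError
from .store import BoxMetadata, TrajectoryStore
from .units import BOLTZMANN

_INV_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class RDFResult:
    species_pair: tuple[str, str]
    bin_centres: np.ndarray  # m
    g_values: np.ndarray  # dimensionless
    counts: np.ndarray  # raw pair counts per bin (ordered pairs)
    n_frames_used: int
    number_density_beta: float  # m^-3, the normalisation density
    n_alpha: int
    bin_width: float

    def g_uncertainty(self) -> np.ndarray:
        """Poisson (counting) standard error per bin; 0 where no counts."""
        with np.errstate(divide="ignore", invalid="ignore"):
            sig = np.where(self.counts > 0, self.g_values / np.sqrt(self.counts), 0.0)
        return sig


@dataclass
class ADFParams:
    species_triple: tuple[str, str, str]  # (centre, neighbour1, neighbour2)
    cutoff: float
    n_bins: int = 180
    zeta: float = 0.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("ADF cutoff must be positive")
        if self.zeta < 0:
            raise ValueError("zeta must be non-negative")


@dataclass
class ADFResult:
    params: ADFParams
    bin_centres_deg: np.ndarray
    density: np.ndarray  # normalised to unit area over degrees
    raw_weights: np.ndarray  # un-normalised weighted histogram


@dataclass
class ShellBoundaries:
    minima_radii: list[float]  # increasing, m
    savgol_window: int
    savgol_order: int
    golden_tol: float


@dataclass
class PMFResult:
    bin_centres: np.ndarray
    w_values: np.ndarray  # J; NaN where g = 0
    r_min: float
    w_min: float


# ---------------------------------------------------------------------------
# pair distances under minimum image
# ---------------------------------------------------------------------------

def minimum_image_displacements(
    pos_a: np.ndarray, pos_b: np.ndarray, box: BoxMetadata
) -> np.ndarray:
    """Displacement vectors b - a, (n_a, n_b, 3), nearest periodic image."""
    d = pos_b[None, :, :] - pos_a[:, None, :]
    L = box.edges
    for ax in range(3):
        if box.periodic_flags[ax]:
            d[..., ax] -= L[ax] * np.round(d[..., ax] / L[ax])
    return d


def _frame_indices(n_frames: int, frame_selection) -> np.ndarray:
    if frame_selection is None:
        return np.arange(n_frames)
    if isinstance(frame_selection, tuple):
        return np.arange(*frame_selection)
    return np.asarray(frame_selection)


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def compute_rdf(
    store: TrajectoryStore,
    pair: tuple[str, str],
    n_bins: int = 500,
    cutoff: float | None = None,
    frame_selection=None,
) -> RDFResult:
    box = store.box
    half_min_edge = min(box.edge_lengths) / 2.0
    if cutoff is None:
        cutoff = half_min_edge
    if cutoff > half_min_edge * (1 + 1e-12):
        raise MDPostError(
            f"cutoff {cutoff:g} m exceeds half the shortest box edge "
            f"({half_min_edge:g} m); the minimum-image convention breaks down"
        )
    alpha, beta = pair
    same = alpha == beta
    pos_a = store.load_property(alpha, "positions")
    pos_b = pos_a if same else store.load_property(beta, "positions")
    frames = _frame_indices(pos_a.shape[1], frame_selection)

    edges = np.linspace(0.0, cutoff, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    for f in frames:
        d = minimum_image_displacements(pos_a[:, f, :], pos_b[:, f, :], box)
        r = np.linalg.norm(d, axis=-1)
        if same:
            np.fill_diagonal(r, np.inf)  # exclude self pairs
        h, _ = np.histogram(r, bins=edges)
        counts += h

    n_a, n_b = pos_a.shape[0], pos_b.shape[0]
    rho_b = (n_b - (1 if same else 0)) / box.volume
    shell_vol = (4.0 * np.pi / 3.0) * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = n_a * rho_b * shell_vol * len(frames)
    g = counts / norm
    centres = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(
        species_pair=(alpha, beta),
        bin_centres=centres,
        g_values=g,
        counts=counts,
        n_frames_used=len(frames),
        number_density_beta=rho_b,
        n_alpha=n_a,
        bin_width=float(edges[1] - edges[0]),
    )


# ---------------------------------------------------------------------------
# ADF
# ---------------------------------------------------------------------------

def compute_adf(
    store: TrajectoryStore,
    params: ADFParams,
    frame_selection=None,
) -> ADFResult:
    """Angle distribution at a centre species, distance-weighted by
    ``1/(|r_ij|^zeta |r_ik|^zeta)`` and renormalised to unit area.
    """
    box = store.box
    if params.cutoff > min(box.edge_lengths) / 2.0 * (1 + 1e-12):
        raise MDPostError("ADF cutoff exceeds half the shortest box edge")
    alpha, beta, gamma = params.species_triple
    pos_a = store.load_property(alpha, "positions")
    pos_b = store.load_property(beta, "positions")
    pos_g = pos_b if gamma == beta else store.load_property(gamma, "positions")
    frames = _frame_indices(pos_a.shape[1], frame_selection)

    edges = np.linspace(0.0, 180.0, params.n_bins + 1)
    hist = np.zeros(params.n_bins)
    for f in frames:
        db = minimum_image_displacements(pos_a[:, f, :], pos_b[:, f, :], box)
        dg = db if gamma == beta else minimum_image_displacements(
            pos_a[:, f, :], pos_g[:, f, :], box)
        rb = np.linalg.norm(db, axis=-1)
        rg = np.linalg.norm(dg, axis=-1)
        for i in range(pos_a.shape[0]):
            nb = np.where((rb[i] <= params.cutoff) & (rb[i] > 1e-300))[0]
            ng = np.where((rg[i] <= params.cutoff) & (rg[i] > 1e-300))[0]
            if alpha == beta:
                nb = nb[nb != i]
            if alpha == gamma:
                ng = ng[ng != i]
            for jpos, j in enumerate(nb):
                if gamma == beta:
                    ks = nb[jpos + 1:]  # unordered pairs, no double count
                else:
                    ks = ng
                for k in ks:
                    if gamma == beta and k == j:
                        continue
                    u, w = db[i, j], dg[i, k]
                    cosang = np.dot(u, w) / (rb[i, j] * rg[i, k])
                    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    weight = 1.0 / (rb[i, j] ** params.zeta * rg[i, k] ** params.zeta)
                    b = min(int(theta / 180.0 * params.n_bins), params.n_bins - 1)
                    hist[b] += weight

    width = edges[1] - edges[0]
    total = hist.sum() * width
    density = hist / total if total > 0 else hist
    return ADFResult(
        params=params,
        bin_centres_deg=0.5 * (edges[:-1] + edges[1:]),
        density=density,
        raw_weights=hist,
    )


# ---------------------------------------------------------------------------
# minima machinery: Savitzky-Golay smoothing + golden-section refinement
# ---------------------------------------------------------------------------

def golden_section_minimize(f, a: float, b: float, tol: float) -> float:
    """Classic golden-section search for the minimum of f on [a, b]."""
    x1 = b - _INV_GOLDEN * (b - a)
    x2 = a + _INV_GOLDEN * (b - a)
    f1, f2 = f(x1), f(x2)
    while (b - a) > tol:
        if f1 < f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - _INV_GOLDEN * (b - a)
            f1 = f(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + _INV_GOLDEN * (b - a)
            f2 = f(x2)
    return 0.5 * (a + b)


def find_rdf_minima(
    rdf: RDFResult,
    savgol_window: int = 9,
    savgol_order: int = 3,
    golden_tol: float | None = None,
) -> ShellBoundaries:
    """Locate RDF minima between successive smoothed peaks.

    The curve is smoothed with a Savitzky-Golay filter, peaks are found
    on the smoothed curve, and each inter-peak minimum is refined by
    golden-section search on a cubic-spline interpolant of the smoothed
    curve to an absolute radius tolerance (default: bin width / 10).
    """
    if savgol_window <= savgol_order:
        raise ValueError("savgol window must exceed the polynomial order")
    if len(rdf.g_values) < savgol_window:
        raise MDPostError("RDF has fewer bins than the smoothing window")
    if golden_tol is None:
        golden_tol = rdf.bin_width / 10.0

    smooth = savgol_filter(rdf.g_values, savgol_window, savgol_order)
    span = float(smooth.max() - smooth.min())
    peaks, _ = find_peaks(smooth, prominence=0.01 * span if span > 0 else None)
    if len(peaks) < 2:
        raise MDPostError(
            "no interior RDF minimum found (fewer than two peaks); "
            "consider a larger cutoff"
        )
    spline = CubicSpline(rdf.bin_centres, smooth)
    minima = []
    for p1, p2 in zip(peaks[:-1], peaks[1:]):
        a, b = rdf.bin_centres[p1], rdf.bin_centres[p2]
        minima.append(golden_section_minimize(spline, a, b, golden_tol))
    return ShellBoundaries(
        minima_radii=sorted(minima),
        savgol_window=savgol_window,
        savgol_order=savgol_order,
        golden_tol=golden_tol,
    )


# ---------------------------------------------------------------------------
# RDF-derived observables (pure functions of RDFResult)
# ---------------------------------------------------------------------------

def _shell_grid(rdf: RDFResult, lo: float, hi: float):
    """Integration grid over [lo, hi] on bin centres with interpolated ends."""
    inner = (rdf.bin_centres > lo) & (rdf.bin_centres < hi)
    r = np.concatenate(([lo], rdf.bin_centres[inner], [hi]))
    g = np.concatenate((
        [np.interp(lo, rdf.bin_centres, rdf.g_values)],
        rdf.g_values[inner],
        [np.interp(hi, rdf.bin_centres, rdf.g_values)],
    ))
    sig = np.concatenate(([0.0], rdf.g_uncertainty()[inner], [0.0]))
    return r, g, sig


def coordination_number(
    rdf: RDFResult,
    shells: ShellBoundaries,
    shell_index: int = 1,
) -> tuple[float, float]:
    """Neighbour count in a coordination shell: 4 pi rho ∫ r^2 g dr.

    Shell ``i`` (1-based) spans [r_{i-1}, r_i] where r_0 = 0 and r_i are
    the RDF minima.  Returns (n, uncertainty); the uncertainty is
    propagated from per-bin Poisson counting errors through the
    trapezoid weights.
    """
    if shell_index < 1:
        raise ValueError("shell_index is 1-based")
    if shell_index > len(shells.minima_radii):
        raise MDPostError(f"only {len(shells.minima_radii)} shell boundaries available")
    lo = 0.0 if shell_index == 1 else shells.minima_radii[shell_index - 2]
    hi = shells.minima_radii[shell_index - 1]
    rho = rdf.number_density_beta
    r, g, sig = _shell_grid(rdf, lo, hi)
    integrand = 4.0 * np.pi * rho * r**2
    value = float(np.trapezoid(integrand * g, r))
    # trapezoid weights: w_k = (r_{k+1} - r_{k-1})/2 at interior points
    w = np.zeros_like(r)
    w[1:] += 0.5 * np.diff(r)
    w[:-1] += 0.5 * np.diff(r)
    var = float(np.sum((w * integrand * sig) ** 2))
    return value, np.sqrt(var)


def potential_of_mean_force(
    rdf: RDFResult,
    temperature: float,
    savgol_window: int = 9,
    savgol_order: int = 3,
    golden_tol: float | None = None,
) -> PMFResult:
    """w(r) = -k_B T ln g(r), masked (NaN) where g = 0; the minimum is
    located with the same smoothing + golden-section machinery as the
    RDF minima."""
    if temperature <= 0:
        raise ValueError("temperature must be positive for a PMF")
    if golden_tol is None:
        golden_tol = rdf.bin_width / 10.0
    g = rdf.g_values
    w = np.full_like(g, np.nan, dtype=float)
    valid = g > 0
    w[valid] = -BOLTZMANN * temperature * np.log(g[valid])

    idx = np.where(valid)[0]
    if len(idx) == 0:
        raise MDPostError("g(r) is zero everywhere; PMF undefined")
    # largest contiguous valid run containing the global PMF minimum
    runs = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
    best = min(runs, key=lambda run: w[run].min())
    r_run, w_run = rdf.bin_centres[best], w[best]
    if len(w_run) >= savgol_window:
        w_s = savgol_filter(w_run, savgol_window, savgol_order)
    else:
        w_s = w_run
    k = int(np.argmin(w_s))
    if 0 < k < len(w_run) - 1:
        spline = CubicSpline(r_run, w_s)
        r_min = golden_section_minimize(spline, r_run[k - 1], r_run[k + 1], golden_tol)
        w_min = float(spline(r_min))
    else:
        r_min, w_min = float(r_run[k]), float(w_s[k])
    return PMFResult(rdf.bin_centres, w, r_min, w_min)


def kirkwood_buff(rdf: RDFResult) -> tuple[np.ndarray, np.ndarray]:
    """Running Kirkwood-Buff integral G(r) = 4 pi ∫_0^r s^2 (g(s)-1) ds.

    Returned on the RDF's bin-centre grid up to the cutoff (the infinite
    upper limit of the defining integral is left to the user to
    extrapolate).  Returns (r, G).
    """
    from scipy.integrate import cumulative_trapezoid

    r = rdf.bin_centres
    integrand = 4.0 * np.pi * r**2 * (rdf.g_values - 1.0)
    G = cumulative_trapezoid(integrand, r, initial=0.0)
    return r, G


def kirkwood_buff_uncertainty(rdf: RDFResult) -> float:
    """Propagated sampling error of G at the cutoff (independent bins)."""
    r = rdf.bin_centres
    sig = rdf.g_uncertainty()
    w = np.zeros_like(r)
    w[1:] += 0.5 * np.diff(r)
    w[:-1] += 0.5 * np.diff(r)
    return float(np.sqrt(np.sum((4.0 * np.pi * r**2 * w * sig) ** 2)))
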