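"""Dynamic light scattering: stretched-exponential mode decomposition and sizing.

The intensity autocorrelation of a polyelectrolyte solution that contains both
free chains and aggregates decays as a sum of Kohlrausch–Williams–Watts (KWW)
modes,

    G(t) - 1 = sum_i A_i * exp(-(t / tau_i)^gamma_i),

one mode per diffusing population.  Each relaxation time maps to a diffusion
coefficient through the scattering vector, ``1/tau = D q^2`` with
``q = (4 pi n / lambda) sin(theta / 2)``, and to a hydrodynamic radius through
Stokes–Einstein, ``R_h = k_B T / (6 pi eta D)``.  The stretch exponent gamma
encodes size polydispersity; values near 0.7–0.85 are typical for a polymer
with Mw/Mn ~ 1.2, while gamma = 1 is a monodisperse single exponential.

The fitter seeds a bounded least-squares refinement from a coarse log-grid
search over relaxation times (amplitudes solved by non-negative least squares
at each grid node), because sums of stretched exponentials have strongly
correlated parameters and many local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Optional, Sequence

import lmfit
import numpy as np
from scipy.optimize import nnls
from scipy.stats import linregress

from .errors import (
    DegenerateFitError,
    DegenerateInputError,
    FitFailureError,
    InsufficientDataError,
    InvalidGeometryError,
    InvalidModelError,
)

BOLTZMANN_J_PER_K = 1.380649e-23

#: Stretch-exponent band observed for moderately polydisperse polymers; fits
#: outside it are legal but flagged.
STRETCH_BAND = (0.7, 0.85)

#: A lone relaxation mode sized below this radius is classified as free chains
#: (a 2.5 kDa chain has contour length ~19 nm); above it, as aggregate.
FREE_RADIUS_CUTOFF_NM = 20.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScatteringGeometry:
    """Optical geometry of a DLS experiment.

    wavelength_nm: in-vacuo laser wavelength, nm.
    angle_deg: scattering angle, degrees, strictly between 0 and 180.
    refractive_index: solvent refractive index (>= 1).
    """

    wavelength_nm: float = 633.0
    angle_deg: float = 173.0
    refractive_index: float = 1.33

    def __post_init__(self):
        if not self.wavelength_nm > 0:
            raise InvalidGeometryError(f"wavelength must be positive, got {self.wavelength_nm}")
        if not 0.0 < self.angle_deg < 180.0:
            raise InvalidGeometryError(f"angle must lie in (0, 180) degrees, got {self.angle_deg}")
        if self.refractive_index < 1.0:
            raise InvalidGeometryError(f"refractive index must be >= 1, got {self.refractive_index}")


@dataclass(frozen=True)
class SolventSpec:
    """Thermodynamic state of the solvent.

    temperature_k: absolute temperature, K.
    nacl_molarity: added NaCl, mol/L.
    viscosity_pa_s: dynamic viscosity, Pa s.
    """

    temperature_k: float = 298.15
    nacl_molarity: float = 0.0
    viscosity_pa_s: float = 8.90e-4

    def __post_init__(self):
        if not self.temperature_k > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature_k}")
        if self.nacl_molarity < 0:
            raise ValueError(f"NaCl molarity must be non-negative, got {self.nacl_molarity}")
        if not self.viscosity_pa_s > 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity_pa_s}")


@dataclass
class CorrelationCurve:
    """One DLS trace: lag times (s) against G(t)-1, with its geometry and solvent."""

    lag_times: np.ndarray
    g_minus_1: np.ndarray
    geometry: ScatteringGeometry
    solvent: SolventSpec
    label: str = ""

    def __post_init__(self):
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.g_minus_1 = np.asarray(self.g_minus_1, dtype=float)
        if self.lag_times.size < 20:
            raise ValueError("a correlation curve needs at least 20 points")
        if self.lag_times.shape != self.g_minus_1.shape:
            raise ValueError("lag_times and g_minus_1 must have the same length")
        if not np.all(self.lag_times > 0) or not np.all(np.diff(self.lag_times) > 0):
            raise ValueError("lag times must be positive and strictly increasing")
        if not np.all(np.isfinite(self.g_minus_1)):
            raise ValueError("g_minus_1 must be finite")


@dataclass(frozen=True)
class RelaxationMode:
    """A single KWW mode: amplitude A, relaxation time tau (s), stretch gamma."""

    amplitude: float
    relaxation_time: float
    stretch: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise InvalidModelError(f"amplitude must be non-negative, got {self.amplitude}")
        if not self.relaxation_time > 0:
            raise InvalidModelError(f"relaxation time must be positive, got {self.relaxation_time}")
        if not 0.0 < self.stretch <= 1.0:
            raise InvalidModelError(f"stretch must lie in (0, 1], got {self.stretch}")


@dataclass
class ModeFit:
    """Result of fitting 1 or 2 KWW modes, sorted by increasing relaxation time."""

    modes: list
    residual_norm: float
    n_modes: int
    converged: bool
    aicc: float = math.nan
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if not 1 <= self.n_modes <= 2:
            raise ValueError("only 1- or 2-mode fits are supported")
        self.modes = sorted(self.modes, key=lambda m: m.relaxation_time)


@dataclass(frozen=True)
class SizedMode:
    """A relaxation mode with its diffusion coefficient (m^2/s) and R_h (nm)."""

    mode: RelaxationMode
    diffusion_coefficient: float
    hydrodynamic_radius_nm: float

    def __post_init__(self):
        if not self.diffusion_coefficient > 0:
            raise ValueError("diffusion coefficient must be positive")
        if not self.hydrodynamic_radius_nm > 0:
            raise ValueError("hydrodynamic radius must be positive")


# ---------------------------------------------------------------------------
# scattering vector and model evaluation
# ---------------------------------------------------------------------------

def scattering_vector(geometry: ScatteringGeometry) -> float:
    """Magnitude of the scattering vector, q = (4 pi n / lambda) sin(theta/2), in 1/m."""
    lam_m = geometry.wavelength_nm * 1e-9
    theta = math.radians(geometry.angle_deg)
    return 4.0 * math.pi * geometry.refractive_index / lam_m * math.sin(theta / 2.0)


def kww_model(lag_times: Sequence[float], modes: Sequence[RelaxationMode]) -> np.ndarray:
    """Evaluate sum_i A_i exp(-(t/tau_i)^gamma_i) on a lag-time grid."""
    modes = list(modes)
    if not modes:
        raise InvalidModelError("at least one relaxation mode is required")
    t = np.asarray(lag_times, dtype=float)
    if np.any(t < 0):
        raise InvalidModelError("lag times must be non-negative")
    out = np.zeros_like(t)
    for m in modes:
        out += m.amplitude * np.exp(-np.power(t / m.relaxation_time, m.stretch))
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _kww_basis(t: np.ndarray, taus: Sequence[float], gammas: Sequence[float]) -> np.ndarray:
    cols = [np.exp(-np.power(t / tau, g)) for tau, g in zip(taus, gammas)]
    return np.column_stack(cols)


def _grid_seed(t, y, n_modes, tau_lo, tau_hi, n_tau=14, gammas=(0.7, 0.85, 1.0)):
    """Coarse (tau, gamma) grid search with NNLS amplitudes; returns best seeds."""
    tau_grid = np.geomspace(max(tau_lo, 1e-12), tau_hi, n_tau)
    if n_modes == 1:
        tau_sets = [(tau,) for tau in tau_grid]
    else:
        tau_sets = list(combinations(tau_grid, 2))
    candidates = []
    for taus in tau_sets:
        for gset in product(gammas, repeat=n_modes):
            basis = _kww_basis(t, taus, gset)
            amps, rnorm = nnls(basis, y)
            candidates.append((rnorm, taus, gset, amps))
    candidates.sort(key=lambda c: c[0])
    return candidates


def _refine(t, y, taus, gammas, amps, tau_lo, tau_hi):
    params = lmfit.Parameters()
    amp_scale = max(np.max(np.abs(y)), 1e-12)
    for i, (tau, g, a) in enumerate(zip(taus, gammas, amps)):
        params.add(f"amp{i}", value=max(a, 1e-6 * amp_scale), min=0.0, max=10.0 * amp_scale)
        params.add(f"logtau{i}", value=math.log10(tau),
                   min=math.log10(tau_lo), max=math.log10(tau_hi))
        # gamma in (0.5, 1]: wider than the observed 0.7-0.85 band to avoid biasing recovery
        params.add(f"gamma{i}", value=g, min=0.500001, max=1.0)

    n_modes = len(taus)

    def residual(p):
        model = np.zeros_like(t)
        for i in range(n_modes):
            model += p[f"amp{i}"].value * np.exp(
                -np.power(t / 10.0 ** p[f"logtau{i}"].value, p[f"gamma{i}"].value))
        return model - y

    return lmfit.minimize(residual, params, method="least_squares")


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2.0 * k * (k + 1) / (n - k - 1)
    return aic


def fit_correlation(curve: CorrelationCurve, n_modes: int,
                    init: Optional[ModeFit] = None, n_restarts: int = 3) -> ModeFit:
    """Least-squares fit of ``n_modes`` KWW modes to a correlation curve.

    A coarse log-grid search over relaxation times (with amplitudes solved by
    NNLS) seeds up to ``n_restarts`` bounded refinements.  Modes are returned
    sorted by relaxation time; stretch exponents outside the 0.7-0.85 band are
    reported in ``warnings`` rather than rejected.
    """
    if n_modes not in (1, 2):
        raise ValueError("n_modes must be 1 or 2")
    t = curve.lag_times
    y = curve.g_minus_1
    if np.ptp(y) == 0.0:
        raise DegenerateInputError("correlation trace is constant; nothing to fit")
    if t.size <= 3 * n_modes:
        raise InsufficientDataError("curve has fewer points than free parameters")

    tau_lo = 0.01 * t[0]
    tau_hi = 100.0 * t[-1]

    seeds = []
    if init is not None and len(init.modes) == n_modes:
        seeds.append((math.inf,
                      tuple(m.relaxation_time for m in init.modes),
                      tuple(m.stretch for m in init.modes),
                      np.array([m.amplitude for m in init.modes])))
    seeds.extend(_grid_seed(t, y, n_modes, tau_lo, tau_hi))

    best = None
    best_rss = math.inf
    converged = False
    for rnorm, taus, gammas, amps in seeds[: n_restarts + (init is not None)]:
        try:
            res = _refine(t, y, taus, gammas, amps, tau_lo, tau_hi)
        except Exception:
            continue
        rss = float(np.sum(res.residual ** 2))
        if rss < best_rss:
            best_rss = rss
            best = res
            converged = bool(res.success)

    if best is None:
        raise FitFailureError("all fit attempts failed", best=None)

    p = best.params
    modes = [RelaxationMode(amplitude=p[f"amp{i}"].value,
                            relaxation_time=10.0 ** p[f"logtau{i}"].value,
                            stretch=p[f"gamma{i}"].value)
             for i in range(n_modes)]
    warn = []
    for m in modes:
        if not STRETCH_BAND[0] <= m.stretch <= STRETCH_BAND[1]:
            warn.append(f"stretch {m.stretch:.3f} outside the typical band "
                        f"[{STRETCH_BAND[0]}, {STRETCH_BAND[1]}]")
    if n_modes == 2:
        taus = sorted(m.relaxation_time for m in modes)
        if taus[1] / taus[0] < 1.5:
            warn.append("the two relaxation times nearly coalesce; "
                        "a single mode may suffice")
        total = sum(m.amplitude for m in modes)
        if total > 0 and min(m.amplitude for m in modes) < 0.02 * total:
            warn.append("one amplitude is below 2% of the total; "
                        "a single mode may suffice")

    fit = ModeFit(modes=modes, residual_norm=math.sqrt(best_rss), n_modes=n_modes,
                  converged=converged, aicc=_aicc(best_rss, t.size, 3 * n_modes),
                  warnings=warn)
    if not converged:
        raise FitFailureError("fit did not converge within bounded restarts", best=fit)
    return fit


def select_mode_count(curve: CorrelationCurve, delta_aicc: float = 10.0,
                      amplitude_floor: float = 0.02) -> int:
    """Choose 1 or 2 relaxation modes by corrected Akaike comparison.

    Returns 2 only when the two-mode fit improves AICc by at least
    ``delta_aicc`` AND both amplitudes exceed ``amplitude_floor`` of the total.
    """
    errors = []
    fit1 = fit2 = None
    try:
        fit1 = fit_correlation(curve, 1)
    except FitFailureError as exc:
        errors.append(exc)
        fit1 = exc.best
    try:
        fit2 = fit_correlation(curve, 2)
    except FitFailureError as exc:
        errors.append(exc)
        fit2 = exc.best
    if fit1 is None and fit2 is None:
        raise FitFailureError("both the 1- and 2-mode fits failed")
    if fit2 is None:
        return 1
    if fit1 is None:
        return 2
    total = sum(m.amplitude for m in fit2.modes)
    amps_ok = total > 0 and all(m.amplitude >= amplitude_floor * total for m in fit2.modes)
    return 2 if (fit1.aicc - fit2.aicc >= delta_aicc and amps_ok) else 1


# ---------------------------------------------------------------------------
# sizing
# ---------------------------------------------------------------------------

def mode_to_radius(mode: RelaxationMode, geometry: ScatteringGeometry,
                   solvent: SolventSpec) -> SizedMode:
    """Size a relaxation mode: D = 1/(tau q^2), then R_h = k_B T / (6 pi eta D)."""
    if not mode.relaxation_time > 0:
        raise InvalidModelError("relaxation time must be positive")
    q = scattering_vector(geometry)
    diff = 1.0 / (mode.relaxation_time * q * q)
    r_m = BOLTZMANN_J_PER_K * solvent.temperature_k / (6.0 * math.pi * solvent.viscosity_pa_s * diff)
    return SizedMode(mode=mode, diffusion_coefficient=diff, hydrodynamic_radius_nm=r_m * 1e9)


def radius_to_relaxation_time(radius_nm: float, geometry: ScatteringGeometry,
                              solvent: SolventSpec) -> float:
    """Inverse of :func:`mode_to_radius`: relaxation time (s) of a sphere of given R_h."""
    if not radius_nm > 0:
        raise ValueError("radius must be positive")
    q = scattering_vector(geometry)
    diff = BOLTZMANN_J_PER_K * solvent.temperature_k / (
        6.0 * math.pi * solvent.viscosity_pa_s * radius_nm * 1e-9)
    return 1.0 / (diff * q * q)


def intensity_fractions(fit: ModeFit, geometry: Optional[ScatteringGeometry] = None,
                        solvent: Optional[SolventSpec] = None,
                        free_radius_cutoff_nm: float = FREE_RADIUS_CUTOFF_NM):
    """Intensity share of the free-chain and aggregate populations.

    For a two-mode fit the faster mode is the free polymer and the slower the
    aggregate; fractions are A_i / sum(A).  A lone mode is classified by its
    hydrodynamic radius (free below ``free_radius_cutoff_nm``), which requires
    ``geometry`` and ``solvent``.
    """
    if not fit.converged:
        raise ValueError("intensity fractions require a converged fit")
    total = sum(m.amplitude for m in fit.modes)
    if total <= 0:
        raise DegenerateFitError("all amplitudes are zero")
    if fit.n_modes == 2:
        return (fit.modes[0].amplitude / total, fit.modes[1].amplitude / total)
    if geometry is None or solvent is None:
        raise ValueError("classifying a single mode requires geometry and solvent")
    sized = mode_to_radius(fit.modes[0], geometry, solvent)
    if sized.hydrodynamic_radius_nm < free_radius_cutoff_nm:
        return (1.0, 0.0)
    return (0.0, 1.0)


# ---------------------------------------------------------------------------
# diffusive scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiffusiveScaling:
    slope: float          # m^2/s -- the diffusion coefficient if diffusive
    intercept: float      # 1/s
    r_squared: float
    diffusive: bool


def diffusive_scaling_check(fits, geometry_base: ScatteringGeometry,
                            solvent: SolventSpec, r2_threshold: float = 0.9) -> DiffusiveScaling:
    """Regress 1/tau of the fastest mode against q^2 over several angles.

    A diffusive mode satisfies 1/tau = D q^2; the OLS slope is then the
    diffusion coefficient.  ``fits`` is a sequence of (angle_deg, ModeFit).
    """
    fits = list(fits)
    angles = {round(a, 9) for a, _ in fits}
    if len(angles) < 3:
        raise InsufficientDataError("diffusive scaling needs at least 3 distinct angles")
    q2 = []
    inv_tau = []
    for angle, fit in fits:
        geom = ScatteringGeometry(wavelength_nm=geometry_base.wavelength_nm,
                                  angle_deg=angle,
                                  refractive_index=geometry_base.refractive_index)
        q = scattering_vector(geom)
        q2.append(q * q)
        inv_tau.append(1.0 / fit.modes[0].relaxation_time)
    res = linregress(np.asarray(q2), np.asarray(inv_tau))
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 0.0
    return DiffusiveScaling(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=r2, diffusive=r2 >= r2_threshold)
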