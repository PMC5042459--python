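"""Forward simulation of DLS, titration, and osmometry measurements.

Every analysis stage in this package is validated by parameter recovery:
a generator forward-simulates the instrument readout from explicit ground
truth, and the corresponding analysis must recover that truth.  The central
ground-truth object is the protonation isotherm P(pH) of the polymer,
modeled as a sum of logistic steps between stalled charge levels:

    P(pH) = sum_k (L_{k+1} - L_k) / (1 + 10^((pH - c_k) / w_k))

with plateau levels L, transition centers c (the apparent pKa values) and
per-transition widths w (pH units).  The defaults encode the charging
behavior of 2.5 kDa linear PEI: an uncharged polymer above pH ~11, a 44%
plateau across the neutral range, a weak-acid transition centered at pH 4.5
to a ~70% stall between pH ~4 and ~3, and a rapid, near-discontinuous jump
just below pH 3 to ~95% protonation.

Titration samples are generated by solving electroneutrality for pH at each
acid/base dose; DLS correlation curves from Stokes-Einstein relaxation times
of a free-chain and an aggregate population; osmotic series from the virial
expansion blended into an association plateau.  With zero noise every
generator is exact, so recovery tolerances test the analyses, not the data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .dls import (
    CorrelationCurve,
    RelaxationMode,
    ScatteringGeometry,
    SolventSpec,
    kww_model,
    radius_to_relaxation_time,
)
from .errors import UnsolvableDesignError
from .titration import KW_25C, TitrationSample

# Default ground truth for the PEI charging profile (see module docstring).
DEFAULT_PLATEAU_LEVELS = (0.0, 0.44, 0.70, 0.95)
DEFAULT_TRANSITION_CENTERS = (10.0, 4.5, 2.75)
DEFAULT_TRANSITION_WIDTHS = (0.6, 0.2, 0.08)


@dataclass(frozen=True)
class ProtonationIsotherm:
    """Ground-truth protonated fraction vs pH as logistic steps between plateaus.

    ``plateau_levels`` are ordered from the high-pH (uncharged) end down;
    ``transition_centers[k]`` is the pH at which the step from level k to
    level k+1 is half complete, and ``transition_widths[k]`` its width.
    """

    plateau_levels: tuple = DEFAULT_PLATEAU_LEVELS
    transition_centers: tuple = DEFAULT_TRANSITION_CENTERS
    transition_widths: tuple = DEFAULT_TRANSITION_WIDTHS

    def __post_init__(self):
        levels = tuple(self.plateau_levels)
        centers = tuple(self.transition_centers)
        widths = tuple(self.transition_widths)
        object.__setattr__(self, "plateau_levels", levels)
        object.__setattr__(self, "transition_centers", centers)
        object.__setattr__(self, "transition_widths", widths)
        if len(centers) != len(levels) - 1 or len(widths) != len(levels) - 1:
            raise ValueError("need one transition center and width per plateau step")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("plateau levels must increase toward low pH")
        if not all(0.0 <= l <= 1.0 for l in levels):
            raise ValueError("plateau levels must lie in [0, 1]")
        if any(c2 >= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("transition centers must decrease with increasing charge")
        if any(w <= 0 for w in widths):
            raise ValueError("transition widths must be positive")

    def __call__(self, ph):
        ph_arr = np.asarray(ph, dtype=float)
        p = np.full_like(ph_arr, self.plateau_levels[0])
        for lo, hi, c, w in zip(self.plateau_levels, self.plateau_levels[1:],
                                self.transition_centers, self.transition_widths):
            p = p + (hi - lo) / (1.0 + 10.0 ** ((ph_arr - c) / w))
        return float(p) if np.isscalar(ph) else p


@dataclass(frozen=True)
class TitrationDesign:
    """Separate-sample dose plan: signed mol/L (HCl positive, NaOH negative).

    ``dissolution_hcl`` is the acid already present in every sample (and its
    control partner) from dissolving the polymer stock; it charges the polymer
    to its neutral-pH plateau and is excluded from the dose bookkeeping, just
    as the experimental x-axis excludes it.  ``None`` resolves to the acid
    that charges the amines to 44% (stock at pH ~7.5); pass 0 for a pristine
    acid-free design.
    """

    doses: tuple
    amine_total: float = 4.08e-3
    nacl: float = 0.150
    include_controls: bool = True
    dissolution_hcl: Optional[float] = None

    def __post_init__(self):
        doses = tuple(sorted(self.doses))
        object.__setattr__(self, "doses", doses)
        if self.amine_total < 0:
            raise ValueError("amine concentration must be non-negative")
        if self.dissolution_hcl is None:
            object.__setattr__(self, "dissolution_hcl", 0.44 * self.amine_total)
        elif self.dissolution_hcl < 0:
            raise ValueError("dissolution acid must be non-negative")

    @staticmethod
    def logarithmic(max_acid: float = 0.05, max_base: float = 0.01,
                    min_dose: float = 1e-6, n_per_side: int = 120,
                    amine_total: float = 4.08e-3, nacl: float = 0.150,
                    include_controls: bool = True,
                    dissolution_hcl: Optional[float] = None) -> "TitrationDesign":
        """Log-spaced acid and base doses on separate samples, plus a zero dose."""
        acid = np.geomspace(min_dose, max_acid, n_per_side)
        base = -np.geomspace(min_dose, max_base, n_per_side)
        doses = np.concatenate([base[::-1], [0.0], acid])
        return TitrationDesign(doses=tuple(doses), amine_total=amine_total,
                               nacl=nacl, include_controls=include_controls,
                               dissolution_hcl=dissolution_hcl)


@dataclass(frozen=True)
class PopulationSpec:
    """Free-chain / aggregate scattering populations for DLS simulation."""

    free_radius_nm: float = 5.0
    aggregate_radius_nm: float = 140.0
    free_intensity_fraction: float = 0.5
    stretch_free: float = 0.8
    stretch_aggregate: float = 0.8

    def __post_init__(self):
        if self.free_radius_nm <= 0 or self.aggregate_radius_nm <= 0:
            raise ValueError("radii must be positive")
        if not 0.0 <= self.free_intensity_fraction <= 1.0:
            raise ValueError("intensity fraction must lie in [0, 1]")
        for s in (self.stretch_free, self.stretch_aggregate):
            if not 0.5 < s <= 1.0:
                raise ValueError("stretch exponents must lie in (0.5, 1]")


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------

def _electroneutrality_residual(ph, amine_total, isotherm, hcl, naoh, kw):
    """LHS - RHS of [A]0 P(pH) + [H+] + [Na+] - [OH-] - [Cl-], mol/L."""
    protonated = amine_total * isotherm(ph) if amine_total > 0 else 0.0
    return protonated + 10.0 ** (-ph) + naoh - kw * 10.0 ** ph - hcl


def solve_titration_ph(dose: float, amine_total: float,
                       isotherm: Optional[ProtonationIsotherm],
                       kw: float = KW_25C,
                       bracket=(0.5, 13.5),
                       baseline_hcl: float = 0.0) -> float:
    """pH satisfying electroneutrality at a signed dose (HCl positive).

    ``baseline_hcl`` is chloride present before the dose (dissolution acid).
    """
    hcl = max(dose, 0.0) + baseline_hcl
    naoh = max(-dose, 0.0)
    iso = isotherm if isotherm is not None else (lambda ph: 0.0)
    f = lambda ph: _electroneutrality_residual(ph, amine_total, iso, hcl, naoh, kw)
    lo, hi = bracket
    if f(lo) * f(hi) > 0:
        raise UnsolvableDesignError(
            f"no electroneutral pH in ({lo}, {hi}) for dose {dose:g} mol/L")
    # xtol tight enough that the charge residual stays below 1e-12 mol/L even
    # at 0.1 M doses where d(residual)/d(pH) ~ 0.2 mol/L per pH unit
    return brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)


def simulate_titration(isotherm: ProtonationIsotherm, design: TitrationDesign,
                       ph_noise_sd: float = 0.0, seed: Optional[int] = None,
                       kw: float = KW_25C):
    """Forward-simulate a separate-sample titration.

    Returns ``(samples, controls)``; ``controls`` is empty unless requested by
    the design.  ``ph_noise_sd`` (pH units; 0.02 is a typical meter figure)
    adds Gaussian noise to the reported pH only — the underlying solution
    state remains exactly electroneutral.

    The design's ``dissolution_hcl`` enters the solved chemistry of every
    sample *and* its control but not the recorded dose fields, mirroring the
    experimental bookkeeping (the titration x-axis excludes dissolution acid;
    the control, having received the same acid treatment, cancels it during
    analysis).
    """
    rng = np.random.default_rng(seed)
    samples = []
    controls = []
    for dose in design.doses:
        ph = solve_titration_ph(dose, design.amine_total, isotherm, kw,
                                baseline_hcl=design.dissolution_hcl)
        noise = rng.normal(0.0, ph_noise_sd) if ph_noise_sd > 0 else 0.0
        samples.append(TitrationSample(added_hcl=max(dose, 0.0),
                                       added_naoh=max(-dose, 0.0),
                                       measured_ph=ph + noise,
                                       amine_total=design.amine_total,
                                       nacl=design.nacl))
        if design.include_controls:
            ph_c = solve_titration_ph(dose, 0.0, None, kw,
                                      baseline_hcl=design.dissolution_hcl)
            noise_c = rng.normal(0.0, ph_noise_sd) if ph_noise_sd > 0 else 0.0
            controls.append(TitrationSample(added_hcl=max(dose, 0.0),
                                            added_naoh=max(-dose, 0.0),
                                            measured_ph=ph_c + noise_c,
                                            amine_total=0.0, nacl=design.nacl,
                                            is_control=True))
    return samples, controls


# ---------------------------------------------------------------------------
# DLS
# ---------------------------------------------------------------------------

def simulate_correlation(spec: PopulationSpec, geometry: ScatteringGeometry,
                         solvent: SolventSpec, lag_grid: Sequence[float],
                         noise_sd: float = 0.0, seed: Optional[int] = None,
                         label: str = "") -> CorrelationCurve:
    """Forward-simulate a (possibly bimodal) DLS correlation curve.

    Relaxation times come from the population radii via Stokes-Einstein and
    the scattering vector; amplitudes from the intensity fractions.  Noise is
    multiplicative Gaussian with relative standard deviation ``noise_sd``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    lag = np.asarray(lag_grid, dtype=float)
    modes = []
    if spec.free_intensity_fraction > 0:
        tau_f = radius_to_relaxation_time(spec.free_radius_nm, geometry, solvent)
        modes.append(RelaxationMode(spec.free_intensity_fraction, tau_f,
                                    spec.stretch_free))
    if spec.free_intensity_fraction < 1:
        tau_a = radius_to_relaxation_time(spec.aggregate_radius_nm, geometry, solvent)
        modes.append(RelaxationMode(1.0 - spec.free_intensity_fraction, tau_a,
                                    spec.stretch_aggregate))
    taus = [m.relaxation_time for m in modes]
    if lag[0] > 0.1 * min(taus) or lag[-1] < 10.0 * max(taus):
        warnings.warn("lag grid does not cover all relaxation times by a factor of 10")
    g = kww_model(lag, modes)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g = g * (1.0 + rng.normal(0.0, noise_sd, size=g.shape))
    return CorrelationCurve(lag_times=lag, g_minus_1=g, geometry=geometry,
                            solvent=solvent, label=label)


# ---------------------------------------------------------------------------
# osmometry
# ---------------------------------------------------------------------------

def simulate_osmometry(molar_mass: float, b2: float, association_onset: float,
                       c_grid: Sequence[float], noise_sd: float = 0.0,
                       seed: Optional[int] = None, nacl: float = 0.0,
                       monomer_mass: float = 43.07,
                       onset_width: Optional[float] = None,
                       plateau_tol: float = 0.1):
    """Forward-simulate a reduced osmotic series with optional association.

    Below ``association_onset`` (mol/L amine) the signal follows the virial
    expansion c_mass/M + B2 c_mass^2 (reduced units, mol/L); above it the
    slope is smoothly quenched by a logistic blend so the signal saturates
    into the plateau characteristic of an associating solution.  The
    ``association_onset`` is defined operationally: it is the concentration
    at which the local slope has fallen to ``plateau_tol`` of the dilute
    slope (matching the plateau detector's threshold), and the logistic
    center is placed accordingly.  ``association_onset = inf`` gives a pure
    virial series.  Noise is multiplicative Gaussian, relative sd ``noise_sd``.
    """
    from .osmometry import OsmoticSeries

    c = np.asarray(c_grid, dtype=float)
    if not np.all(np.diff(c) > 0):
        raise ValueError("concentration grid must be strictly increasing")

    def ideal_slope(conc):
        cm = conc * monomer_mass
        return monomer_mass * (1.0 / molar_mass + 2.0 * b2 * cm)

    if math.isinf(association_onset):
        c_mass = c * monomer_mass
        signal = c_mass / molar_mass + b2 * c_mass ** 2
    else:
        width = onset_width if onset_width is not None else association_onset / 8.0
        # slope at c: ideal'(c) * (1 - sigma(c)); place the logistic center so
        # the normalized slope equals plateau_tol exactly at the onset
        r = ideal_slope(association_onset) / ideal_slope(0.0)
        if r <= plateau_tol:
            raise ValueError("virial slope already below the plateau threshold "
                             "at the requested onset")
        center = association_onset - width * math.log(r / plateau_tol - 1.0)
        fine = np.linspace(0.0, float(c[-1]), 4001)
        suppressed = ideal_slope(fine) / (1.0 + np.exp((fine - center) / width))
        from scipy.integrate import cumulative_trapezoid
        s_fine = cumulative_trapezoid(suppressed, fine, initial=0.0)
        signal = np.interp(c, fine, s_fine)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal * (1.0 + rng.normal(0.0, noise_sd, size=signal.shape))
    return OsmoticSeries(concentrations=c, signals=signal, nacl=nacl)


# ---------------------------------------------------------------------------
# solvent properties
# ---------------------------------------------------------------------------

#: Jones-Dole viscosity coefficients for NaCl at 25 C (L^1/2 mol^-1/2, L/mol).
JONES_DOLE_A_NACL = 0.0062
JONES_DOLE_B_NACL = 0.0793


def water_viscosity(temperature_k: float) -> float:
    """Dynamic viscosity of pure water, Pa s, Vogel-type correlation.

    eta = 2.414e-5 * 10^(247.8 / (T - 140)); accurate to ~1% over 0-100 C.
    """
    if not 273.0 < temperature_k < 373.0:
        raise ValueError(f"temperature {temperature_k} K outside the liquid range")
    return 2.414e-5 * 10.0 ** (247.8 / (temperature_k - 140.0))


def solvent_properties(temperature_k: float = 298.15,
                       nacl_molarity: float = 0.0) -> SolventSpec:
    """SolventSpec with water viscosity at T, Jones-Dole-corrected for NaCl.

    eta(c) = eta_water(T) * (1 + A sqrt(c) + B c); monotone increasing in c
    for NaCl (B > 0).
    """
    if nacl_molarity < 0:
        raise ValueError("NaCl molarity must be non-negative")
    eta0 = water_viscosity(temperature_k)
    rel = 1.0 + JONES_DOLE_A_NACL * math.sqrt(nacl_molarity) \
        + JONES_DOLE_B_NACL * nacl_molarity
    return SolventSpec(temperature_k=temperature_k, nacl_molarity=nacl_molarity,
                       viscosity_pa_s=eta0 * rel)
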