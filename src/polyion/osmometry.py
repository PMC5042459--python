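"""Osmotic virial analysis and association detection for polymer solutions.

In a molecularly dispersed (dilute) solution the osmotic pressure follows the
virial expansion

    Pi = (R T / V_1) (c/M + B_2 c^2 + B_3 c^3 + ...)

with c the polymer mass concentration, M the molar mass, B_2 and B_3 the
second and third virial coefficients, and V_1 the partial molar volume of the
solvent.  An associating solution violates this form: as chains join into
aggregates the number of osmotically active particles saturates, and the
signal exhibits a plateau or even a maximum as c grows.  Vapor-pressure
osmometers report a microvolt imbalance proportional to osmolality, so an
uncalibrated series yields *apparent* (proportionally scaled) parameters,
flagged as such.

Concentrations are carried in mol/L of amine monomer and converted to mass
concentration with the repeat-unit mass at the fit boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AssociationDominatedError, InsufficientDataError

#: Molar mass of the PEI repeat unit (-CH2-CH2-NH-), g/mol.
MONOMER_MASS_G_PER_MOL = 43.07


@dataclass
class OsmoticSeries:
    """Osmotic readout vs amine concentration at fixed NaCl."""

    concentrations: np.ndarray   # mol/L amine, strictly increasing
    signals: np.ndarray          # reduced osmotic signal Pi*V1/(R T) (mol/L) if
                                 # calibrated, else instrument-proportional units
    nacl: float = 0.0
    signal_is_calibrated: bool = True

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.concentrations.size < 4:
            raise ValueError("an osmotic series needs at least 4 points")
        if self.concentrations.shape != self.signals.shape:
            raise ValueError("concentrations and signals must have the same length")
        if not np.all(np.diff(self.concentrations) > 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals must be finite")


@dataclass(frozen=True)
class VirialFit:
    molar_mass: float            # g/mol (apparent if uncalibrated)
    b2: float                    # L mol / g^2 in reduced-signal units
    b3: Optional[float]
    fit_range: tuple             # (start, stop) index window used
    apparent: bool               # True when fitted on an uncalibrated signal

    def __post_init__(self):
        if not self.molar_mass > 0:
            raise ValueError("molar mass must be positive")


@dataclass(frozen=True)
class AssociationProfile:
    is_associating: bool
    plateau_onset: Optional[float]   # mol/L amine
    peak_location: Optional[float]   # mol/L amine


def association_profile(series: OsmoticSeries, slope_tol: float = 0.1,
                        persistence: int = 2) -> AssociationProfile:
    """Scan for the plateau/maximum signature of chain association.

    The finite-difference slope is normalized to the initial slope; the
    plateau onset is the first concentration where it stays below
    ``slope_tol`` for ``persistence`` consecutive intervals.  A maximum
    followed by decreasing signal marks ``peak_location``.
    """
    c = series.concentrations
    s = series.signals
    if c.size < 5:
        raise InsufficientDataError("association profile needs at least 5 points")
    slopes = np.diff(s) / np.diff(c)
    ref = slopes[0]
    if ref == 0:
        ref = np.max(np.abs(slopes)) or 1.0
    norm = slopes / ref

    plateau_onset = None
    run = 0
    for i, v in enumerate(norm):
        if abs(v) < slope_tol:
            run += 1
            if run >= persistence:
                plateau_onset = float(c[i - persistence + 1])
                break
        else:
            run = 0

    peak_location = None
    imax = int(np.argmax(s))
    if 0 < imax < s.size - 1 and s[-1] < s[imax]:
        peak_location = float(c[imax])

    return AssociationProfile(is_associating=plateau_onset is not None
                              or peak_location is not None,
                              plateau_onset=plateau_onset,
                              peak_location=peak_location)


def virial_fit(series: OsmoticSeries, degree: int = 2,
               fit_range: Optional[tuple] = None,
               monomer_mass: float = MONOMER_MASS_G_PER_MOL,
               slope_tol: float = 0.1) -> VirialFit:
    """Zero-intercept polynomial fit of the reduced osmotic signal.

    Fits signal = c/M + B2 c^2 (+ B3 c^3) against mass concentration
    c = monomer_mass * molarity over ``fit_range`` (default: the points below
    the detected plateau onset, since the virial form only holds for a
    molecularly dispersed solution).

    Raises :class:`AssociationDominatedError` when the requested range is
    itself association-dominated (plateau/maximum inside the range, or a
    non-positive linear coefficient).
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    c_mass = series.concentrations * monomer_mass   # g/L
    y = series.signals

    if fit_range is None:
        try:
            prof = association_profile(series, slope_tol=slope_tol)
        except InsufficientDataError:
            prof = AssociationProfile(False, None, None)
        if prof.plateau_onset is not None:
            stop = int(np.searchsorted(series.concentrations, prof.plateau_onset))
            fit_range = (0, max(stop, degree + 1))
        else:
            fit_range = (0, c_mass.size)
    start, stop = fit_range
    if stop - start < degree + 1:
        raise InsufficientDataError("fit range must contain at least degree+1 points")

    sub = OsmoticSeries(series.concentrations[start:stop], y[start:stop],
                        nacl=series.nacl,
                        signal_is_calibrated=series.signal_is_calibrated) \
        if stop - start >= 5 else None
    if sub is not None and association_profile(sub, slope_tol=slope_tol).is_associating:
        raise AssociationDominatedError(
            "osmotic signal plateaus or peaks inside the fit range; the dilute "
            "virial expansion does not apply there")

    cm = c_mass[start:stop]
    ys = y[start:stop]
    cols = np.column_stack([cm ** k for k in range(1, degree + 1)])
    coef, *_ = np.linalg.lstsq(cols, ys, rcond=None)
    if coef[0] <= 0:
        raise AssociationDominatedError(
            "non-positive linear virial coefficient; association dominates")
    return VirialFit(molar_mass=float(1.0 / coef[0]),
                     b2=float(coef[1]) if degree >= 2 else 0.0,
                     b3=float(coef[2]) if degree >= 3 else None,
                     fit_range=(start, stop),
                     apparent=not series.signal_is_calibrated)
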