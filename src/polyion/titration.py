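"""Charge-balance analysis of constant-concentration weak-base titrations.

A weak-base polyelectrolyte such as linear PEI takes up H+ at its backbone
amines.  When acid or base is added to *separate* samples so that polymer and
salt concentrations stay constant, the protonated-amine concentration follows
directly from electroneutrality:

    [AH+] + [H+] + [Na+] = [OH-] + [Cl-]
    [AH+] = [OH-]_free + [Cl-]_HCl - [H+]_free - [Na+]_NaOH

with [H+] = 10^-pH and [OH-] = kw/[H+] (ideal-solution convention,
kw = 1e-14 at 25 C; added NaCl cancels on both sides).  The protonated
fraction is P = [AH+] / [A]_0 for total amine concentration [A]_0.

Polymer-free controls run through the same arithmetic estimate the spurious
proton bookkeeping (dissolved CO2, electrode bias) and are subtracted dose by
dose.  The module also derives the buffering capacity beta = |dC/dpH|, the
apparent pKa values (maxima of beta), pH windows where protonation stalls,
and a predicted ninhydrin signal proportional to the unprotonated amines.

Fractions outside [0, 1] are reported with a flag rather than clamped: in the
basic region the same bookkeeping legitimately drives the apparent charge
negative when OH- uptake is attributed to the polymer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError

KW_25C = 1e-14  # (mol/L)^2, water ion product at 25 C


@dataclass(frozen=True)
class TitrationSample:
    """One separate-sample titration point at fixed polymer and salt content."""

    added_hcl: float          # mol/L
    added_naoh: float         # mol/L
    measured_ph: float
    amine_total: float        # mol/L (0 for polymer-free controls)
    nacl: float = 0.0         # mol/L
    is_control: bool = False

    def __post_init__(self):
        if self.added_hcl < 0 or self.added_naoh < 0:
            raise ValueError("added acid/base concentrations must be non-negative")
        if self.added_hcl > 0 and self.added_naoh > 0:
            raise ValueError("a sample receives either HCl or NaOH, not both")
        if self.amine_total < 0:
            raise ValueError("amine concentration must be non-negative")
        if not 0.0 < self.measured_ph < 14.0:
            raise ValueError(f"pH {self.measured_ph} outside (0, 14)")

    @property
    def signed_dose(self) -> float:
        """Added HCl minus added NaOH, mol/L (acid positive)."""
        return self.added_hcl - self.added_naoh


@dataclass(frozen=True)
class ProtonationResult:
    protonated_amine: float   # [AH+], mol/L
    fraction: float           # P = [AH+]/[A]_0, NOT clamped to [0, 1]
    out_of_range: bool


@dataclass
class ProtonationCurve:
    """Protonated fraction vs pH with its derived buffering diagnostics."""

    points: list                      # (pH, fraction), sorted by pH
    buffering_capacity: list          # (pH, beta)
    pkas: list                        # apparent pKa locations (pH)
    stalls: list                      # (fraction_level, (ph_lo, ph_hi))
    flags: list = field(default_factory=list)


def free_ion_concentrations(ph: float, kw: float = KW_25C):
    """([H+], [OH-]) in mol/L at the given pH, ideal-solution convention."""
    h = 10.0 ** (-ph)
    return h, kw / h


def protonated_fraction(sample: TitrationSample, kw: float = KW_25C) -> ProtonationResult:
    """Protonated amine concentration and fraction from charge balance."""
    if sample.amine_total <= 0:
        raise ZeroDivisionError(
            "protonated fraction is undefined for a polymer-free sample; "
            "use the control pathway in analyze_titration")
    h, oh = free_ion_concentrations(sample.measured_ph, kw)
    ah = oh + sample.added_hcl - h - sample.added_naoh
    frac = ah / sample.amine_total
    return ProtonationResult(protonated_amine=ah, fraction=frac,
                             out_of_range=not 0.0 <= frac <= 1.0)


def spurious_protonation(control: TitrationSample, kw: float = KW_25C) -> float:
    """Apparent [AH+] of a polymer-free control (CO2 / bookkeeping signal), mol/L."""
    h, oh = free_ion_concentrations(control.measured_ph, kw)
    return oh + control.added_hcl - h - control.added_naoh


def analyze_titration(series: Sequence[TitrationSample],
                      controls: Sequence[TitrationSample] = (),
                      baseline_offset: float = 0.0,
                      kw: float = KW_25C,
                      slope_tol: float = 0.02,
                      min_span: float = 1.0,
                      n_pkas: int = 2) -> ProtonationCurve:
    """Full charge-balance analysis of a constant-concentration titration.

    Controls are matched to samples by exact acid/base dose; the control's
    apparent [AH+] is subtracted point by point.  ``baseline_offset`` adds the
    H+ spent at stock dissolution (mol/L) to every sample, if tracked.
    Returns the protonation curve with buffering capacity, apparent pKa
    locations, and detected stalled charge states.
    """
    series = list(series)
    if not series:
        raise InsufficientDataError("empty titration series")
    ctrl_by_dose = {}
    for c in controls:
        ctrl_by_dose[(c.added_hcl, c.added_naoh)] = c

    flags = []
    raw = []
    dose_ph = []
    for s in series:
        res = protonated_fraction(s, kw)
        key = (s.added_hcl, s.added_naoh)
        ctrl = ctrl_by_dose.get(key)
        if ctrl is None and ctrl_by_dose:
            flags.append(f"no control for dose HCl={s.added_hcl:g}, "
                         f"NaOH={s.added_naoh:g}; point left uncorrected")
            correction = 0.0
        elif ctrl is None:
            correction = 0.0
        else:
            correction = spurious_protonation(ctrl, kw)
        ah = res.protonated_amine - correction + baseline_offset
        frac = ah / s.amine_total
        raw.append((s.measured_ph, frac))
        dose_ph.append((s.signed_dose, s.measured_ph))
        if not 0.0 <= frac <= 1.0:
            flags.append(f"fraction {frac:.4f} out of [0, 1] at pH {s.measured_ph:.3f}")

    # average duplicate pH readings
    by_ph = {}
    for ph, frac in raw:
        by_ph.setdefault(ph, []).append(frac)
    points = []
    for ph in sorted(by_ph):
        vals = by_ph[ph]
        if len(vals) > 1:
            flags.append(f"averaged {len(vals)} samples at duplicate pH {ph:.3f}")
        points.append((ph, float(np.mean(vals))))

    beta = buffering_capacity(dose_ph)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pkas = apparent_pkas(beta, n_peaks=n_pkas)
    curve = ProtonationCurve(points=points, buffering_capacity=beta,
                             pkas=pkas, stalls=[], flags=flags)
    curve.stalls = detect_stalls(curve, slope_tol=slope_tol, min_span=min_span)
    return curve


def buffering_capacity(curve_inputs: Sequence[tuple]) -> list:
    """Buffering capacity beta(pH) = |d(added acid - base)/dpH| by finite differences.

    ``curve_inputs`` is a sequence of (signed dose mol/L, pH).  Points are
    sorted by dose; the derivative is taken with second-order differences.
    """
    pts = sorted(curve_inputs, key=lambda p: p[0])
    if len(pts) < 4:
        raise InsufficientDataError("buffering capacity needs at least 4 points")
    dose = np.array([p[0] for p in pts], dtype=float)
    ph = np.array([p[1] for p in pts], dtype=float)
    dph = np.diff(ph)
    if np.any(dph > 0) and np.any(dph < -1e-9):
        warnings.warn("pH is not monotone in dose; data may be inconsistent")
    grad = np.gradient(dose, ph)
    beta = np.abs(grad)
    order = np.argsort(ph)
    return [(float(ph[i]), float(beta[i])) for i in order]


def _moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    if x.size < window:
        return x.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def apparent_pkas(beta_curve: Sequence[tuple], n_peaks: int = 2,
                  window: int = 5) -> list:
    """pH locations of the ``n_peaks`` largest local maxima of smoothed beta.

    Ties are broken toward lower pH; returns fewer values (with a warning)
    when the curve has fewer interior maxima.
    """
    pts = sorted(beta_curve, key=lambda p: p[0])
    if not pts:
        raise InsufficientDataError("empty buffering-capacity curve")
    ph = np.array([p[0] for p in pts], dtype=float)
    beta = _moving_average(np.array([p[1] for p in pts], dtype=float), window)
    peaks = []
    for i in range(1, beta.size - 1):
        if beta[i] > beta[i - 1] and beta[i] >= beta[i + 1]:
            peaks.append((beta[i], ph[i]))
    peaks.sort(key=lambda p: (-p[0], p[1]))
    if len(peaks) < n_peaks:
        warnings.warn(f"requested {n_peaks} buffering maxima but found {len(peaks)}")
    return sorted(ph for _, ph in peaks[:n_peaks])


def detect_stalls(curve: ProtonationCurve, slope_tol: float = 0.02,
                  min_span: float = 1.0) -> list:
    """Stalled charge states: pH windows of span >= ``min_span`` with |dP/dpH| < tol.

    Returns (mean fraction, (ph_lo, ph_hi)) for each window, in pH order.
    """
    pts = sorted(curve.points, key=lambda p: p[0])
    if len(pts) < 5:
        raise InsufficientDataError("stall detection needs at least 5 points")
    ph = np.array([p[0] for p in pts], dtype=float)
    frac = np.array([p[1] for p in pts], dtype=float)
    slopes = np.diff(frac) / np.diff(ph)
    flat = np.abs(slopes) < slope_tol

    stalls = []
    i = 0
    n = flat.size
    while i < n:
        if flat[i]:
            j = i
            while j + 1 < n and flat[j + 1]:
                j += 1
            lo, hi = ph[i], ph[j + 1]
            if hi - lo >= min_span:
                level = float(np.mean(frac[i:j + 2]))
                stalls.append((level, (float(lo), float(hi))))
            i = j + 1
        i += 1
    return stalls


def ninhydrin_signal(fraction, scale: float = 1.0):
    """Predicted ninhydrin absorbance proxy: scale * (1 - P), floored at zero.

    The assay derivatizes only unprotonated secondary amines, so the signal
    tracks 1 - P along the protonation profile.
    """
    if not scale > 0:
        raise ValueError("scale must be positive")
    p = np.asarray(fraction, dtype=float)
    sig = scale * np.clip(1.0 - p, 0.0, None)
    return float(sig) if np.isscalar(fraction) or p.ndim == 0 else sig
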