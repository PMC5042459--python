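"""CSV readers/writers, run configuration, and the synthetic reproduction pipeline.

All unit conversion happens here: files carry the field's customary units
(nm, degrees, mM, Kelvin); in-memory objects are SI / molar.  CSV files are
comma-separated UTF-8 with ``#``-prefixed metadata lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import dls as _dls
from . import osmometry as _osmo
from . import synthetic as _syn
from . import titration as _tit
from .errors import SchemaError

log = logging.getLogger("polyion")

CORRELATION_COLUMNS = ["lag_time_s", "g_minus_1"]
TITRATION_COLUMNS = ["sample_id", "added_hcl_M", "added_naoh_M", "ph",
                     "amine_total_M", "nacl_M", "is_control"]
OSMOMETRY_COLUMNS = ["conc_mM", "signal", "nacl_mM"]


# ---------------------------------------------------------------------------
# low-level CSV with # metadata headers
# ---------------------------------------------------------------------------

def _read_metadata(path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _read_csv(path, required_columns) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in required_columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    numeric = [c for c in required_columns if c not in ("sample_id", "is_control")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"{path}: non-numeric value in column '{col}' at data row {row}")
        df[col] = coerced
    return df


# ---------------------------------------------------------------------------
# typed readers / writers
# ---------------------------------------------------------------------------

def read_correlation_csv(path) -> _dls.CorrelationCurve:
    """Read a DLS trace with geometry/solvent metadata header lines."""
    meta = _read_metadata(path)
    df = _read_csv(path, CORRELATION_COLUMNS)
    geometry = _dls.ScatteringGeometry(
        wavelength_nm=float(meta.get("wavelength_nm", 633.0)),
        angle_deg=float(meta.get("angle_deg", 173.0)),
        refractive_index=float(meta.get("refractive_index", 1.33)))
    nacl = float(meta.get("nacl_mM", 0.0)) * 1e-3
    if "viscosity_Pa_s" in meta:
        solvent = _dls.SolventSpec(temperature_k=float(meta.get("temperature_K", 298.15)),
                                   nacl_molarity=nacl,
                                   viscosity_pa_s=float(meta["viscosity_Pa_s"]))
    else:
        solvent = _syn.solvent_properties(float(meta.get("temperature_K", 298.15)), nacl)
    return _dls.CorrelationCurve(lag_times=df["lag_time_s"].to_numpy(),
                                 g_minus_1=df["g_minus_1"].to_numpy(),
                                 geometry=geometry, solvent=solvent,
                                 label=meta.get("label", str(path)))


def write_correlation_csv(path, curve: _dls.CorrelationCurve) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# wavelength_nm={curve.geometry.wavelength_nm}\n")
        fh.write(f"# angle_deg={curve.geometry.angle_deg}\n")
        fh.write(f"# refractive_index={curve.geometry.refractive_index}\n")
        fh.write(f"# temperature_K={curve.solvent.temperature_k}\n")
        fh.write(f"# nacl_mM={curve.solvent.nacl_molarity * 1e3}\n")
        fh.write(f"# viscosity_Pa_s={curve.solvent.viscosity_pa_s}\n")
        pd.DataFrame({"lag_time_s": curve.lag_times,
                      "g_minus_1": curve.g_minus_1}).to_csv(fh, index=False,
                                                     float_format="%.17g")


def read_titration_csv(path):
    """Read a titration table; returns (samples, controls) lists."""
    df = _read_csv(path, TITRATION_COLUMNS)
    samples, controls = [], []
    for _, row in df.iterrows():
        is_ctrl = bool(row["is_control"]) if not isinstance(row["is_control"], str) \
            else row["is_control"].strip().lower() in ("1", "true", "yes")
        s = _tit.TitrationSample(added_hcl=float(row["added_hcl_M"]),
                                 added_naoh=float(row["added_naoh_M"]),
                                 measured_ph=float(row["ph"]),
                                 amine_total=float(row["amine_total_M"]),
                                 nacl=float(row["nacl_M"]), is_control=is_ctrl)
        (controls if is_ctrl else samples).append(s)
    return samples, controls


def write_titration_csv(path, samples, controls=()) -> None:
    rows = []
    for i, s in enumerate(list(samples) + list(controls)):
        rows.append({"sample_id": f"{'C' if s.is_control else 'S'}{i:04d}",
                     "added_hcl_M": s.added_hcl, "added_naoh_M": s.added_naoh,
                     "ph": s.measured_ph, "amine_total_M": s.amine_total,
                     "nacl_M": s.nacl, "is_control": int(s.is_control)})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_osmometry_csv(path) -> _osmo.OsmoticSeries:
    meta = _read_metadata(path)
    df = _read_csv(path, OSMOMETRY_COLUMNS)
    calibrated = meta.get("signal_is_calibrated", "1").strip().lower() in ("1", "true", "yes")
    nacl = float(df["nacl_mM"].iloc[0]) * 1e-3 if len(df) else 0.0
    return _osmo.OsmoticSeries(concentrations=df["conc_mM"].to_numpy() * 1e-3,
                               signals=df["signal"].to_numpy(), nacl=nacl,
                               signal_is_calibrated=calibrated)


def write_osmometry_csv(path, series: _osmo.OsmoticSeries) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# signal_is_calibrated={int(series.signal_is_calibrated)}\n")
        pd.DataFrame({"conc_mM": series.concentrations * 1e3,
                      "signal": series.signals,
                      "nacl_mM": np.full(series.concentrations.size,
                                         series.nacl * 1e3)}).to_csv(fh, index=False,
                                                            float_format="%.17g")


def read_table(path, schema_name: str):
    """Dispatch by schema name: 'correlation' | 'titration' | 'osmometry'."""
    readers = {"correlation": read_correlation_csv,
               "titration": read_titration_csv,
               "osmometry": read_osmometry_csv}
    if schema_name not in readers:
        raise SchemaError(f"unknown schema '{schema_name}'")
    return readers[schema_name](path)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

class DlsConfig(BaseModel):
    wavelength_nm: float = 633.0
    angle_deg: float = 173.0
    refractive_index: float = 1.33
    free_radius_nm: float = 5.0
    aggregate_radius_nm: float = 140.0
    free_intensity_fraction: float = 0.5
    stretch: float = 0.8
    noise_sd: float = Field(default=0.01, ge=0)
    lag_min_s: float = 1e-7
    lag_max_s: float = 0.1
    n_lags: int = 240


class TitrationConfig(BaseModel):
    amine_total_M: float = 4.08e-3
    nacl_M: float = 0.150
    max_acid_M: float = 0.05
    max_base_M: float = 0.01
    n_per_side: int = 240
    baseline_offset_M: float = 0.0
    ph_noise_sd: float = Field(default=0.0, ge=0)
    slope_tol: float = Field(default=0.02, gt=0)
    min_span: float = Field(default=1.0, gt=0)


class OsmometryConfig(BaseModel):
    molar_mass: float = 2500.0
    b2: float = 1e-3
    association_onset_mM: float = 3.0
    c_max_mM: float = 8.0
    n_points: int = 40
    noise_sd: float = Field(default=0.0, ge=0)
    osmometer_calibration: float = 1.0


class RunConfig(BaseModel):
    """Validated configuration for the synthetic reproduction pipeline."""

    seed: int = 0
    temperature_k: float = 298.15
    dls: DlsConfig = DlsConfig()
    titration: TitrationConfig = TitrationConfig()
    osmometry: OsmometryConfig = OsmometryConfig()
    output_dir: Optional[str] = None


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _stage_log(stage: str, payload: dict, seed: int, elapsed: float) -> None:
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True,
                                       default=str).encode()).hexdigest()[:12]
    log.info("stage=%s input_hash=%s seed=%d elapsed_s=%.3f", stage, digest, seed, elapsed)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> analyze -> report for all three measurements.

    Stage failures are recorded in the report; independent stages still run.
    """
    import polyion

    report = {"seed": config.seed,
              "versions": {"polyion": polyion.__version__,
                           "numpy": np.__version__},
              "stages": {}}

    # DLS
    t0 = time.perf_counter()
    try:
        cfg = config.dls
        geometry = _dls.ScatteringGeometry(cfg.wavelength_nm, cfg.angle_deg,
                                           cfg.refractive_index)
        solvent = _syn.solvent_properties(config.temperature_k,
                                          config.titration.nacl_M)
        spec = _syn.PopulationSpec(cfg.free_radius_nm, cfg.aggregate_radius_nm,
                                   cfg.free_intensity_fraction, cfg.stretch, cfg.stretch)
        lag = np.geomspace(cfg.lag_min_s, cfg.lag_max_s, cfg.n_lags)
        curve = _syn.simulate_correlation(spec, geometry, solvent, lag,
                                          noise_sd=cfg.noise_sd, seed=config.seed)
        n_modes = _dls.select_mode_count(curve)
        fit = _dls.fit_correlation(curve, n_modes)
        sized = [_dls.mode_to_radius(m, geometry, solvent) for m in fit.modes]
        fractions = _dls.intensity_fractions(fit, geometry, solvent)
        report["stages"]["dls"] = {
            "status": "ok", "n_modes": n_modes,
            "radii_nm": [s.hydrodynamic_radius_nm for s in sized],
            "true_radii_nm": sorted([cfg.free_radius_nm, cfg.aggregate_radius_nm])
            if 0 < cfg.free_intensity_fraction < 1 else [cfg.free_radius_nm],
            "intensity_fractions": list(fractions),
            "warnings": fit.warnings}
    except Exception as exc:  # stage isolation: later stages must still run
        report["stages"]["dls"] = {"status": "failed", "error": str(exc)}
    _stage_log("dls", config.dls.model_dump(), config.seed, time.perf_counter() - t0)

    # titration
    t0 = time.perf_counter()
    try:
        cfg = config.titration
        iso = _syn.ProtonationIsotherm()
        design = _syn.TitrationDesign.logarithmic(
            max_acid=cfg.max_acid_M, max_base=cfg.max_base_M,
            n_per_side=cfg.n_per_side, amine_total=cfg.amine_total_M,
            nacl=cfg.nacl_M)
        samples, controls = _syn.simulate_titration(iso, design,
                                                    ph_noise_sd=cfg.ph_noise_sd,
                                                    seed=config.seed)
        curve = _tit.analyze_titration(samples, controls,
                                       baseline_offset=cfg.baseline_offset_M,
                                       slope_tol=cfg.slope_tol,
                                       min_span=cfg.min_span, n_pkas=3)
        report["stages"]["titration"] = {
            "status": "ok",
            "apparent_pkas": curve.pkas,
            "true_pkas": sorted(iso.transition_centers),
            "stalls": [{"level": lvl, "ph_range": list(rng)}
                       for lvl, rng in curve.stalls],
            "warnings": curve.flags}
    except Exception as exc:
        report["stages"]["titration"] = {"status": "failed", "error": str(exc)}
    _stage_log("titration", config.titration.model_dump(), config.seed,
               time.perf_counter() - t0)

    # osmometry
    t0 = time.perf_counter()
    try:
        cfg = config.osmometry
        c_grid = np.linspace(cfg.c_max_mM / cfg.n_points, cfg.c_max_mM,
                             cfg.n_points) * 1e-3
        series = _syn.simulate_osmometry(cfg.molar_mass, cfg.b2,
                                         cfg.association_onset_mM * 1e-3,
                                         c_grid, noise_sd=cfg.noise_sd,
                                         seed=config.seed)
        profile = _osmo.association_profile(series)
        fit = _osmo.virial_fit(series, degree=2)
        # fitted below the detected onset of an associating series, so the
        # virial parameters are apparent (biased by the pre-plateau bend)
        report["stages"]["osmometry"] = {
            "status": "ok",
            "apparent_molar_mass": fit.molar_mass,
            "true_molar_mass": cfg.molar_mass,
            "apparent_b2": fit.b2, "true_b2": cfg.b2,
            "is_associating": profile.is_associating,
            "plateau_onset_mM": None if profile.plateau_onset is None
            else profile.plateau_onset * 1e3,
            "true_onset_mM": cfg.association_onset_mM,
            "warnings": []}
    except Exception as exc:
        report["stages"]["osmometry"] = {"status": "failed", "error": str(exc)}
    _stage_log("osmometry", config.osmometry.model_dump(), config.seed,
               time.perf_counter() - t0)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
    return report
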