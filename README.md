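# polyion

Solution-state analysis of weak-base hydrophobic polyelectrolytes — the
reference system is 2.5 kDa linear polyethylenimine (PEI), the cationic
polymer used to condense DNA into nanoparticles for transfection.  In
solution PEI coexists as free chains and large aggregates, and its backbone
amines protonate in steps between stalled charge states.  `polyion` provides
the three analyses a polymer-physics lab needs to characterize such a
system, each with a matching forward simulator so every stage is verifiable
by parameter recovery:

- **DLS** (`polyion.dls`): decompose intensity-autocorrelation traces into
  free-chain and aggregate relaxation modes,

      G(t) − 1 = A_f exp(−(t/τ_f)^γ_f) + A_a exp(−(t/τ_a)^γ_a),

  size each mode via `1/τ = D q²` (q = (4πn/λ)·sin(θ/2)) and Stokes–Einstein
  `R_h = k_B T / (6π η D)`, report intensity fractions A_i/ΣA, and verify
  diffusive `1/τ ∝ q²` scaling across angles.
- **Titration** (`polyion.titration`): infer the protonated fraction of the
  polymer from constant-concentration pH titrations by charge balance,

      [AH⁺] = [OH⁻] + [Cl⁻]_HCl − [H⁺] − [Na⁺]_NaOH,    P = [AH⁺]/[A]₀,

  with dose-matched polymer-free controls subtracted point by point; derive
  buffering capacity β(pH) = |dC/dpH|, apparent pKa (maxima of β), stalled
  charge states (plateaus of P), and the predicted ninhydrin signal
  (proportional to unprotonated amines).
- **Osmometry** (`polyion.osmometry`): fit the dilute-solution virial
  expansion Π = (RT/V₁)(c/M + B₂c² + …) and detect the plateau/maximum
  signature of chain association.
- **Synthetic data** (`polyion.synthetic`): forward-simulate all three
  measurements from an explicit ground-truth protonation isotherm
  (logistic steps between stalled charge levels), electroneutral titration
  chemistry solved by root-finding, and Stokes–Einstein relaxation times.

See `docs/methods.md` for the models, numerical choices, and limitations.

## Worked example

```python
import numpy as np
import polyion as p

# --- titration round trip -------------------------------------------------
isotherm = p.ProtonationIsotherm()                      # ground truth P(pH)
design = p.TitrationDesign.logarithmic(n_per_side=240)  # 4.08 mM amine, 150 mM NaCl
samples, controls = p.simulate_titration(isotherm, design)
curve = p.analyze_titration(samples, controls)

for level, (lo, hi) in curve.stalls:
    print(f"stalled charge state: {level*100:5.1f}%  over pH {lo:.2f}-{hi:.2f}")

beta = curve.buffering_capacity
pka_acid = p.apparent_pkas([b for b in beta if 3.5 < b[0] < 7.0], n_peaks=1)[0]
pka_basic = p.apparent_pkas([b for b in beta if 8.0 < b[0] < 12.5], n_peaks=1)[0]
print(f"apparent pKa (weak-acid / basic): {pka_acid:.2f} / {pka_basic:.2f}")

# --- DLS sizing -----------------------------------------------------------
geometry = p.ScatteringGeometry(633.0, 173.0, 1.33)
solvent = p.solvent_properties(298.15, nacl_molarity=0.010)
lag = np.geomspace(1e-7, 1e-1, 240)
spec = p.PopulationSpec(free_radius_nm=5.0, aggregate_radius_nm=140.0,
                        free_intensity_fraction=0.5)
trace = p.simulate_correlation(spec, geometry, solvent, lag, noise_sd=0.01, seed=1)
fit = p.fit_correlation(trace, n_modes=p.select_mode_count(trace))
for mode in fit.modes:
    sized = p.mode_to_radius(mode, geometry, solvent)
    print(f"mode: tau = {mode.relaxation_time*1e6:7.1f} us   "
          f"R_h = {sized.hydrodynamic_radius_nm:6.1f} nm   gamma = {mode.stretch:.3f}")
print("intensity fractions (free, aggregate):",
      tuple(round(f, 3) for f in p.intensity_fractions(fit)))
```

prints

```
stalled charge state:  95.0%  over pH 1.32-2.54
stalled charge state:  70.0%  over pH 2.94-3.96
stalled charge state:  43.9%  over pH 4.93-8.85
apparent pKa (weak-acid / basic): 4.50 / 10.04
mode: tau =    29.8 us   R_h =    5.1 nm   gamma = 0.790
mode: tau =   834.6 us   R_h =  142.0 nm   gamma = 0.806
intensity fractions (free, aggregate): (0.506, 0.494)
```

Reading it: the charge-balance analysis of the simulated titration recovers
the three stalled charge states of the generating isotherm — 44% across the
neutral window, the ~70% stall between pH ~4 and ~3, and ~95% below pH 2.5 —
and places the two buffering maxima (apparent pKa) at 4.50 and 10.04.  The
two-mode KWW fit of a 1%-noise correlation trace recovers the 5 nm free
chain and 140 nm aggregate within ~1.5%, with stretch exponents in the
0.7–0.85 polydispersity band and an even intensity split, as constructed.

## Command line

```
polyion simulate {dls|titration|osmo} --seed N --out file.csv [--config cfg.yaml]
polyion dls fit.csv --modes auto          # KWW fit + Stokes-Einstein sizing
polyion titrate titration.csv             # charge-balance analysis
polyion osmo osmometry.csv --degree 2     # virial fit + association profile
polyion reproduce --seed N --out outdir   # full simulate -> analyze -> report
```

CSV schemas are documented in `polyion/io.py` (comma-separated, UTF-8,
`#`-prefixed metadata lines).

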