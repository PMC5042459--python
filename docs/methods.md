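# Methods

`polyion` analyses the solution state of a weak-base, hydrophobic
polyelectrolyte — the reference system is 2.5 kDa linear polyethylenimine
(PEI) — from three measurement channels: dynamic light scattering (DLS),
constant-concentration pH titration, and vapor-pressure osmometry.  Every
analysis has a matching forward simulator, so the package validates itself by
parameter recovery: simulate from known ground truth, analyze, compare.

## DLS: mode decomposition and sizing

### Model

The intensity autocorrelation of a solution containing free chains (f) and
aggregates (a) decays as a sum of stretched exponentials (KWW modes):

    G(t) − 1 = Σᵢ Aᵢ exp(−(t/τᵢ)^γᵢ),   i ∈ {f, a}

`A` is the intensity contribution of each population, `τ` its relaxation
time, and `γ ∈ (0, 1]` the stretch exponent encoding size polydispersity
(γ ≈ 0.7–0.85 is typical of a polymer with Mw/Mn ≈ 1.2; fitted values outside
that band are allowed but flagged).  A diffusive mode satisfies
`1/τ = D q²` with scattering vector `q = (4π n/λ) sin(θ/2)`, and
Stokes–Einstein gives the hydrodynamic radius `R_h = k_B T / (6π η D)`.
`diffusive_scaling_check` verifies the `1/τ ∝ q²` law by ordinary least
squares over ≥ 3 scattering angles; a coefficient of determination below 0.9
flags a non-diffusive relaxation.

### Fitting

Sums of stretched exponentials are ill-conditioned and multi-modal, so the
fit is seeded by a coarse search on a log grid of relaxation times
(14 nodes spanning 0.01·t_min to 100·t_max, γ ∈ {0.7, 0.85, 1.0}), with
amplitudes solved by non-negative least squares at each node.  The best
seeds start up to three bounded least-squares refinements (via lmfit) with
γ constrained to (0.5, 1] — wider than the observed 0.7–0.85 band so the
bound does not bias recovery — and amplitudes ≥ 0.  Residuals are
unweighted.  If the two fitted relaxation times cross during optimization
the modes are re-sorted at output and labeled by final order.

The number of modes (1 or 2) is chosen by corrected Akaike information
criterion: two modes are accepted only when AICc improves by ≥ 10 *and* both
amplitudes exceed 2% of the total.  A lone mode is classified free vs
aggregate by its radius: below 20 nm it is a free chain (a 2.5 kDa chain has
contour length ~19 nm and cannot exceed it; aggregates are ≥ 100 nm).

Intensity fractions are `Aᵢ / Σ Aⱼ`, invariant to the overall normalization
of G(t) − 1, so the analysis does not assume the correlogram was normalized
to 1 at t → 0.

### Acquisition model in the simulator

`simulate_correlation` evaluates the KWW model on the lag grid (exact at
zero noise) and applies multiplicative Gaussian noise of relative standard
deviation `noise_sd`.  A single 240-channel trace at 1% noise leaves ~2–3%
statistical scatter on recovered radii at the least-squares optimum; a DLS
instrument integrating over a long collection accumulates many sub-runs, so
recovery tests at 1% noise fit the mean of 10 simulated sub-run acquisitions.
At the reference geometry (633 nm, 173°, water at 25 °C) the radii 5 nm and
140 nm map to τ ≈ 29 µs and 0.83 ms; the default lag grid spans 0.1 µs to
0.1 s (240 log-spaced points).

### Solvent

Water viscosity uses the Vogel-type correlation
`η = 2.414e−5 · 10^(247.8/(T−140))` Pa·s (≈ 1% accurate over 0–100 °C;
8.90e−4 Pa·s at 25 °C), with a Jones–Dole correction for NaCl,
`η(c)/η₀ = 1 + A√c + B c`, A = 0.0062, B = 0.0793 L/mol — monotone
increasing in salt.  Refractive index defaults to 1.33 and temperature to
25 °C, both overridable.

## Titration: protonation from charge balance

Acid or base of logarithmically increasing molarity is added to *separate*
samples so the polymer ([A]₀, default 4.08 mM amine) and salt (default
150 mM NaCl) concentrations stay constant.  Electroneutrality then fixes
the protonated-amine concentration at each measured pH:

    [AH⁺] = [OH⁻] + [Cl⁻]_HCl − [H⁺] − [Na⁺]_NaOH,    P = [AH⁺]/[A]₀

with `[H⁺] = 10^(−pH)`, `[OH⁻] = k_w/[H⁺]`, `k_w = 1e−14` (ideal-solution
convention: pH read as −log₁₀ concentration, no activity corrections, no
temperature dependence of k_w; the added NaCl cancels on both sides).

Values of P outside [0, 1] are reported with a flag, never clamped — in the
basic region this bookkeeping legitimately drives the apparent charge
negative, because OH⁻ uptake is attributed to the polymer.  The simulator's
isotherm keeps P ∈ [0, 1]; negative recovered charge in real basic-region
data is an artifact of the same accounting, not of the analysis here.

**Controls.** A polymer-free control matched to each dose is run through the
same arithmetic; its apparent [AH⁺] (dissolved CO₂, electrode bias — and the
dissolution acid, below) is subtracted dose by dose.  A missing control
yields a flagged, uncorrected point.

**Dissolution acid.** The polymer stock is dissolved with HCl that charges
the amines to their neutral-pH plateau (44%, stock at pH ≈ 7.5).  This acid
is excluded from the dose bookkeeping (the titration x-axis), but it is
physically present in every sample *and* its control, so the control
subtraction cancels it exactly.  The simulator mirrors this:
`TitrationDesign.dissolution_hcl` (default 0.44·[A]₀) enters the solved
chemistry but not the recorded doses.  For analyses without controls, a
constant `baseline_offset` (mol/L) can be supplied instead.

**Buffering capacity and apparent pKa.** β(pH) = |d(added acid − base)/dpH|
is estimated by second-order finite differences on dose-sorted samples.
This includes the water term ln10·([H⁺]+[OH⁻]); against the closed-form
expression for an ideal weak base the numerical β agrees to ≤ 2% wherever
the dose grid resolves the curve locally — near titration endpoints
(equivalence regions) the sharp minimum of β cannot be resolved by finite
differences on any realistic dose grid, and those points are excluded from
oracle comparisons.  Apparent pKa values are the largest local maxima of β
after a centered 5-point moving-average smoothing, ties broken toward lower
pH.

**Stalled charge states.** Contiguous pH windows of span ≥ 1 pH unit where
|dP/dpH| < 0.02 per pH unit.  The defaults match plateaus at least one pH
unit wide; the reported level is the mean P over the window.

**Ninhydrin prediction.** The assay derivatizes unprotonated secondary
amines, so the predicted signal is `scale·(1 − P)`, floored at zero.

### Forward simulation

For each signed dose the simulator solves the scalar electroneutrality
equation `[A]₀·P(pH) + 10^(−pH) + [Na⁺] = k_w·10^(pH) + [Cl⁻]` for pH by
Brent bracketing on (0.5, 13.5), `xtol = 1e−14` — tight enough that the
charge residual stays below 1e−12 mol/L even at 0.1 M doses where
d(residual)/d(pH) ≈ 0.2 mol/L per pH unit.  An unbracketable dose raises an
error.  Optional Gaussian pH noise (a typical meter reads to ±0.02 pH)
perturbs only the reported pH; the default is zero so the generator is
exact.  The pipeline's default dose plan is 240 log-spaced doses per branch
(1e−6 to 0.05 M acid, to 0.01 M base, plus a zero dose): plateau-boundary
detection needs the pH axis resolved to ~0.1 unit in the sparsely buffered
regions, which coarser log grids do not guarantee.

### Ground-truth isotherm

The protonation isotherm is a sum of logistic steps between stalled charge
levels:

    P(pH) = Σₖ (Lₖ₊₁ − Lₖ) / (1 + 10^((pH − cₖ)/wₖ))

Defaults encode the charging profile of 2.5 kDa linear PEI: levels
(0, 0.44, 0.70, 0.95), centers (10, 4.5, 2.75), widths (0.6, 0.2, 0.08) pH
units.  The widths are per-transition because the three transitions have
qualitatively different characters: the basic transition is broad (buffering
spread over pH ~9–11), the weak-acid transition completes by pH ≈ 4 so that
a ≥ 1-unit stall at 70% separates it from the low-pH rise, and the final
transition is the near-discontinuous jump that completes within a few tenths
of a pH unit below pH 3, reaching ~95% protonation by pH 2.5.  A single
shared width cannot reproduce both the 70% stall and the rapid low-pH rise.
With levels (0, 1) and width 1.0 the form reduces exactly to
Henderson–Hasselbalch, which is how the ideal-weak-base oracle is built.

## Osmometry: virial analysis and association

In a molecularly dispersed solution the osmotic pressure follows
`Π = (RT/V₁)(c/M + B₂c² + B₃c³)`.  The package works in reduced signal
units `Π·V₁/(RT)` (mol/L); concentrations are carried as amine molarity and
converted to mass concentration with the repeat-unit mass (43.07 g/mol for
-CH₂CH₂NH-) at the fit boundary, so the fitted M is in g/mol.  A
vapor-pressure osmometer reports a microvolt imbalance proportional to
osmolality; uncalibrated series yield proportionally scaled *apparent*
parameters, flagged as such.

Association (chains joining into osmotically inactive aggregates) makes the
signal plateau or peak.  `association_profile` scans finite-difference
slopes normalized to the initial slope: the plateau onset is the first
concentration where the normalized slope stays below 0.1 for two consecutive
intervals; a maximum followed by decline is reported as a peak.  The virial
fit defaults its range to the points below the detected onset and refuses
(association-dominated error) a range that itself plateaus or yields a
non-positive linear coefficient.

The simulator defines the constructed onset *operationally*: the ideal
virial slope is quenched by a logistic factor whose center is placed so the
normalized slope equals the detector's threshold (0.1) exactly at the
requested onset, and the signal is the integral of that slope (smooth,
monotone).  This makes "constructed onset" and "detected onset" the same
quantity for any sufficiently fine grid.  Note that even below the onset the
bend depresses the local slope, so a virial fit on an associating series is
biased (apparent M low by ~20% at the default settings); the strict ≤ 0.1%
recovery contract applies to non-associating series, and quantitative virial
work requires the dilute branch well below the onset.

## What the generators do and do not emulate

The simulators reproduce: bimodal KWW decays with polydispersity exponents,
multiplicative intensity noise, electroneutral titration chemistry with
matched controls and dissolution acid, pH-meter noise, virial osmotic
response with an association plateau, and seeded determinism (identical
inputs and seed give identical datasets).

They do not emulate: activity coefficients or ionic-strength corrections
(everything is ideal-solution), CO₂ uptake drift (controls are simulated
clean; the correction path is exercised by construction in tests),
aggregation kinetics or the salt dependence of free/aggregate partitioning
(no quantitative model exists for it), multi-neighbor statistical-mechanical
protonation, electrode junction potentials, or instrument baselines.
Passing recovery tests therefore demonstrates the correctness of the
analysis chain under the stated physical model, not robustness to every
non-ideality of real data.

## Problem sizes and runtime

Default validation sizes: 240-channel DLS traces (10 sub-run averages for
noisy recovery), 481-sample titrations (240 doses per branch plus zero, each
with a control), 40-point osmotic series.  The full test suite and the
reproduction script each run in a few seconds on one CPU.
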