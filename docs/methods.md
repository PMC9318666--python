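# Methods

`vesiscope` analyzes the standard multiscale characterization suite for
lipid-vesicle/polymer solutions: dynamic light scattering (DLS),
small-angle X-ray scattering (SAXS), differential scanning calorimetry
(DSC), steady-shear rheology, and time-correlated single photon
counting (TCSPC) of a membrane-embedded molecular rotor. This note
records the models, the conventions and defaults, and the design
choices that were genuinely open.

## DLS (`vesiscope.dls`)

A dilute monodisperse suspension gives an intensity autocorrelation

    g2(q, tau) − 1 = A exp(−2 Γ tau),      Γ = D_T q²,

with `q = 4π n sin(θ/2)/λ` the scattering wave vector. The fit is a
nonlinear least squares of `A·exp(−2Γτ)` on the baseline-subtracted
correlogram (raw exports containing the +1 baseline are handled by a
reader option that subtracts the long-delay plateau). Initialization:
A₀ from the first point, Γ₀ from the delay where the amplitude falls to
A₀/e. The relaxation rate is taken positive by convention. Traces that
do not decay are flagged `converged=False`, never coerced.

The hydrodynamic radius follows from Stokes–Einstein,
`D = k_B T/(6π η R_h)`, using the water-viscosity model below (or any
user-supplied solvent viscosity). The adsorbed-polymer layer thickness
is `δ = (d_mix − d_neat)/2`; negative values are reported, not clamped.
The molar-mass scaling of δ is an ordinary least-squares line in
(log₁₀ Mw, log₁₀ δ), excluding non-positive δ; its slope is the
solvent-quality exponent (0.5 at theta conditions, ≈0.588 in good
solvent). On the measured diameter table the least-squares slope is
0.56; the published fit reports 0.58 (the exact points/baseline of that
fit are not stated), and both values are within the uncertainty a
four-point log–log fit supports.

**Water viscosity.** A Vogel correlation
`η(T) = exp(a + b/(T − c))` (Pa·s, T in K) with constants fitted by
least squares to standard reference viscosities at 10–40 °C in 5 °C
steps; every node is reproduced to better than 0.05%. Valid range
273–373 K, enforced. All I/O temperatures are Celsius; internals use
kelvin.

## SAXS (`vesiscope.saxs`)

Multilamellar vesicles produce Bragg peaks at q*, 2q*, …; the repeat
distance is `d = 2π/q*` (bilayer plus interlamellar water). Detection
runs on the background-detrended profile:

1. fit `c·q^(−p)` in log–log space, iteratively excluding >2σ-high
   outliers (the peaks) — the profiles ride on form-factor/polymer
   scattering;
2. divide it out and smooth the ratio with a Gaussian kernel of 3 grid
   points (matched filtering: Bragg peaks span several grid points,
   shot noise is white);
3. accept local maxima whose prominence exceeds 3× (configurable) the
   local noise sd, estimated from a rolling robust MAD of first
   differences (counting noise grows toward high q);
4. refine each accepted position by parabolic interpolation (sub-grid).

Lamellarity: *multilamellar* iff a second-order companion lies within
5% of 2q₁* (ratio in [1.9, 2.1]); *unilamellar* iff no peak at all;
*indeterminate* otherwise. The result is invariant to positive
intensity rescaling. Temperature is carried as metadata only. q is in
nm⁻¹ at all file boundaries.

## DSC (`vesiscope.dsc`)

Traces are specific heat flow (W/g of sample) versus temperature at a
fixed scan rate, exotherm stored positive (a reader flag absorbs vendor
"exo up/down" conventions). The transition temperature is the extremum
of the baseline-subtracted trace, refined by a quadratic fit over the
top 20% of the peak; the width is the interpolated FWHM. A peak must
exceed 5× a robust noise estimate (MAD of second differences) or a
no-transition result is returned.

Specific enthalpy: `ΔH = |∫ (heat_flow − baseline) dT| / β` with β the
scan rate in °C/s, over a window that should contain the peak plus
flanking baseline (default T_c ± 4·FWHM). The baseline is a line
anchored on the averages of the outer 10% of the window on each side:
anchoring on averages rather than single points keeps point noise out
of the anchor, and the signed integral avoids the positive bias that
rectifying noise with an absolute value inside the integral would add
(~1.5% at realistic noise). Adding any linear function of T to the
trace leaves ΔH unchanged to machine precision. A warning flags windows
whose detrended flanks are steep relative to the peak height (an edge
inside the peak). Enthalpies are per gram of solution, matching how the
measured table is normalized (per-lipid normalization is left to the
caller; the ~0.3 J/g values correspond to ~2 wt% lipid).

## Rheology (`vesiscope.rheology`)

Relative viscosity is the pointwise ratio of a sample ramp to a
reference (water or polymer solution) ramp, with the reference linearly
interpolated onto the sample's temperatures.

Two parameter-free hard-sphere references:
Einstein `η_r = 1 + 2.5φ`, and Krieger–Dougherty
`η_r = (1 − φ/φ_max)^(−A·φ_max)` with A = 2.7, φ_max = 0.71
(submicron spheres). No fitting is performed anywhere in the model
comparison: φ comes from geometry.

**Volume fraction from bilayer geometry.** For a vesicle of outer
radius R_out and bilayer thickness t (R_in = R_out − t), the lipid
count is `N = 4π(R_out² + R_in²)/a_L`; with lipid molar mass M and mass
concentration c, the vesicle number density is `c/(N·M/N_A)` and
`φ = density · (4/3)πR_out³` — enclosed water counts. Defaults: bilayer
thickness 4.4 nm (fluid) / 4.8 nm (gel) — deliberately the bare bilayer,
not the SAXS repeat distance (6.28/6.82 nm), which includes
interlamellar water; area per lipid 0.60 nm² (fluid) / 0.47 nm² (gel),
standard DMPC values; molar mass 678 g/mol; all config-overridable. At
the study's nominal composition (119.9 nm, 17 g/L) this gives φ ≈ 0.097,
consistent with the published 9.2% given the uncertainty of the
geometry inputs.

Interparticle geometry: face-to-face distance of randomly distributed
spheres `L = d[(2/(πφ))^(1/3) − 1]` (clamped to 0 with a contact flag at
φ ≥ 2/π), and the bound-chain gap `L − 2·(2R_g)`, negative values
flagged as overlap.

**Thermal-thickening metrics.** The relative-viscosity step at the
gel–fluid transition is quantified by plateau medians over
[T_m + 2, T_m + 6] °C and the mirrored window below (configurable; for
transitions broader than ~4 °C the windows must be pushed outward, e.g.
±4–10 °C, or they sample the transition itself). The jump is the
plateau-to-plateau change in percent of the lower plateau (the peak
excursion is reported separately, since for overshooting transitions
peak-to-baseline and plateau-to-plateau differ). The transition width
is defined as the 5–95% rise span of a logistic fitted to the
transition region — a fit rather than raw threshold crossings because
point noise makes first-crossing estimators erratic, and 5–95% because
it corresponds to the visually complete transition (for a logistic of
scale s it equals 5.89·s).

## TCSPC / microviscosity (`vesiscope.fls`)

Decays are tail-fitted from the peak bin with
`a₁e^(−t/τ₁) + a₂e^(−t/τ₂) + bg`, weighted least squares with Poisson
weights evaluated from the model (`1/√max(m,1)`; weighting by observed
counts biases lifetimes low at moderate counts). Two starts
(background-free and tail-level background) guard against the strong
bg–τ correlation of short windows. A single-exponential null model is
always fitted as well, and the second component is kept only when the
F statistic exceeds 10 — a pure tail fit otherwise absorbs baseline
noise into a spurious ~10⁻³-amplitude slow component that measurably
inflates the intensity-weighted mean. Components are ordered τ₁ ≤ τ₂;
amplitudes are reported as fractions plus a scale. The mean lifetime is
intensity-weighted: `τ_avg = Σaᵢτᵢ²/Σaᵢτᵢ`. Optional IRF convolution is
off unless an instrument response is supplied.

The Förster–Hoffmann relation `ln τ = A + B ln η` (natural logs; the
inversion is exact algebra, so the base cancels if used consistently)
is calibrated by ordinary least squares on (τ, η) pairs — a measured
solvent series (methanol–glycerol) or printed anchors; with exactly two
pairs the exact two-point line is used. Microviscosity is the inversion
`η = exp((ln τ − A)/B)`. Note the sensitivity: a relative lifetime
error ε maps to a viscosity error `exp(ε/B) − 1`; at B ≈ 0.046 (35 °C)
a 0.2% lifetime error is ~4% in viscosity, and at B ≈ 0.0145 (15 °C)
~15%. Reported microviscosities inherit this amplification, which is
why the pipeline tests pin the lifetime accuracy and check the
inversion as exact algebra.

## Synthetic data (`vesiscope.synthetic`)

Each generator is the forward model of its analysis stage, with an
explicit integer seed and a private `numpy.random.Generator` (no global
state; fixed seed ⇒ byte-identical output):

- **Correlogram**: log-spaced delays over 0.01/Γ–10/Γ, multiplicative
  Gaussian noise (default 1%).
- **SAXS**: `c·q^(−p)` background plus Gaussian peaks at 2π/d and 4π/d
  (second order 0.4× the first, configurable), noise ∝ √I.
- **DSC**: Gaussian exotherm whose area equals `enthalpy·β`, on a
  linear baseline, additive noise (default 2×10⁻⁵ W/g, ≈0.2% of the
  default peak height).
- **Viscosity ramp**: solvent curve × base relative viscosity × a
  logistic step of given fractional jump and width (scale width/6) at
  T_m, multiplicative noise (default 0.3%).
- **TCSPC**: per-bin Poisson draws around a multi-exponential
  expectation normalized to the requested total counts (default 10⁶),
  optional Gaussian IRF; counts are integers.

`gen_study` composes these into one bare-vesicle condition plus four
polymer conditions (1.5, 20, 100, 400 kg/mol) at 15 and 35 °C, with
per-condition diameters `d_neat + 2δ(Mw)`, `δ = 0.0106·Mw^0.58` nm
(anchored so δ(400 kg/mol) = 18.9 nm), transition at 22.84 °C with
0.335 J/g, rotor lifetimes equal to the measured mean-lifetime table,
and calibration anchors generated on the exact Förster–Hoffmann lines
(A, B) = (3.0249, 0.045729) at 35 °C and (3.2922, 0.014501) at 15 °C
(the two-point solutions of the measured anchor pairs). It writes one
CSV per condition/instrument, a `manifest.json` of generating
parameters, and a ready-to-run `study.yaml`.

What the generators deliberately do **not** emulate: polydispersity and
cumulant PDI, vesicle form factors and the ripple-phase pretransition,
multimodal size distributions, shear-rate dependence, instrument
afterpulsing or IRF tails. Passing round-trip tests therefore
demonstrates that the estimators are correct and unbiased under each
stage's assumed statistical model, not that those models capture every
feature of real instruments.

## Pipeline (`vesiscope.pipeline`)

`run_study(config, data_dir, out_dir)` validates a YAML config (file
map per condition, geometry, transition temperature, windows), runs
DLS → SAXS → DSC → rheology → FLS per condition, then the
cross-condition steps (δ and its scaling against the reference
condition, enthalpy decreases, geometric volume fraction and
interparticle distances, optional suspension-model comparison,
calibration and microviscosity inversion). Missing inputs mark a stage
absent with a logged reason — never zero-filled. Outputs: `report.json`,
two CSV summary tables (sizes/thermal/diffusion and
lifetimes/microviscosities), and a provenance log mapping every number
to an input file (SHA-256 prefix) and operation. Re-running on
identical inputs is bit-identical. Report units: lengths nm,
viscosities mPa·s (≡ cP), lifetimes ns, diffusion m²/s. PDI is treated
as pass-through metadata (cumulant analysis is out of scope).

## Problem sizes and tolerances in the test suite

Round trips use 200-point correlograms, 400-point SAXS profiles,
701-point thermograms, 371-point viscosity ramps, and 2000-bin decay
histograms at 10⁶ counts — each the size a desk instrument would
produce. Seed-ensemble statistics use 50–100 seeds. Per-stage round-trip
tolerances (seed-7 bundle): diameters and diffusion constants 1%,
T_c 0.05 °C, enthalpy 1.5%, mean lifetimes 1.5%, jump 2 percentage
points, scaling exponent ±0.02; microviscosities are checked as the
exact algebraic inversion of the fitted lifetime (see the sensitivity
note above). Statistical recovery claims are asserted on medians over
seeds, not single draws: at 10⁶ counts the single-seed τ_avg error
distribution has σ ≈ 0.5%, so any fixed seed sits inside a 1% band only
with ~80% probability.

## Known limitations

- Single-exponential DLS only (no cumulants/CONTIN); polydisperse
  samples bias D toward fast modes.
- SAXS background is a single power law per window; structured
  backgrounds (strong form-factor oscillations) would need flank-wise
  configuration.
- The DSC baseline is linear (sigmoidal baselines are not implemented);
  strongly sloped or curved baselines inside the window bias ΔH.
- Tail fitting without IRF deconvolution limits TCSPC accuracy for
  lifetimes comparable to the IRF width; fine here (τ ≈ 20–29 ns,
  sub-ns IRFs).
- The F-test collapse (threshold 10) can suppress a genuine second
  component below ~0.5% intensity fraction; lower the threshold for
  samples where such components are expected.
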