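# vesiscope

Multiscale analysis of lipid-vesicle/polymer solutions: from raw
instrument-style traces to the quantities a membrane-biophysics study
reports.

Extruded phospholipid vesicles (liposomes) mixed with water-soluble
polymers such as PEG are a minimal model for how macromolecular
crowding talks to soft membranes. Characterizing one such system takes
five instruments, each with its own raw data and its own fitting
conventions. `vesiscope` implements that whole chain as a tested
library:

- **DLS** — fit intensity autocorrelations `g₂−1 = A·exp(−2Γτ)` with
  `Γ = D_T q²`, size vesicles via Stokes–Einstein
  `D_T = k_BT/(6πηR_h)`, extract adsorbed-polymer layer thicknesses
  `δ = (d_mix − d_neat)/2` and their molar-mass scaling `δ ∝ Mw^ν`
  (ν ≈ 0.58 in good solvent).
- **SAXS** — detect lamellar Bragg peaks at q*, 2q* on power-law
  backgrounds, compute repeat spacings `d = 2π/q*`, classify vesicles
  as multilamellar / unilamellar / indeterminate.
- **DSC** — locate the gel–fluid transition (T_c, FWHM) and integrate
  specific enthalpies `ΔH = |∫(Φ − baseline)dT|/β`.
- **Rheology** — relative viscosity curves, vesicle volume fractions
  from bilayer geometry, the Einstein (`η_r = 1 + 2.5φ`) and
  Krieger–Dougherty (`η_r = (1 − φ/φ_max)^(−Aφ_max)`, A = 2.7,
  φ_max = 0.71) hard-sphere references, interparticle distances
  `L = d[(2/πφ)^{1/3} − 1]`, and thermal-thickening step metrics.
- **TCSPC** — biexponential decay fits with Poisson weighting,
  intensity-weighted mean lifetimes `τ_avg = Σaτ²/Σaτ`, and bilayer
  microviscosity via the Förster–Hoffmann calibration
  `ln τ = A + B ln η`.
- **Synthetic data** — deterministic forward-model generators for every
  instrument plus a full study bundle with a ground-truth manifest, so
  the entire pipeline is testable without any measurement.
- **Pipeline/CLI** — a YAML-configured runner producing JSON reports,
  CSV summary tables and a provenance log, exposed as the `vesiscope`
  command.

See `docs/methods.md` for models, conventions, defaults, and
limitations.

## Worked example

Generate a synthetic five-condition study (bare vesicles + four PEG
molar masses, measured at 15 and 35 °C) and analyze it:

```sh
vesiscope simulate study --seed 7 --out-dir data/
vesiscope run --config data/study.yaml --data data/ --out report/
```

or in Python:

```python
from vesiscope.synthetic import StudyConfig, gen_study
from vesiscope.pipeline import run_study

manifest = gen_study(StudyConfig(seed=7), "data")
report = run_study("data/study.yaml", "data", "report")

neat = report["conditions"]["neat"]
print(round(neat["dls"]["35"]["diameter_nm"], 1))      # 120.2
print(round(neat["dsc"]["T_c_C"], 2))                  # 22.85
print(round(neat["dsc"]["enthalpy_J_per_g"], 3))       # 0.338
print(round(neat["fls"]["35"]["tau_avg_ns"], 2))       # 23.9
print(round(report["derived"]["layer_scaling"]["slope"], 3))       # 0.574
print(round(report["derived"]["suspension"]["phi"], 3))            # 0.097
```

The bare vesicles come back at 120.2 nm hydrodynamic diameter (ground
truth 119.9 nm, recovered from a 1%-noise correlogram), crystallizing
at 22.85 °C with 0.338 J/g (truth 22.84 °C, 0.335 J/g). The rotor
lifetime of 23.9 ns at 35 °C inverts through the Förster–Hoffmann
calibration to the bilayer microviscosity. Across the four polymer
conditions the adsorbed-layer thicknesses scale with molar mass with
exponent 0.574 (generator truth 0.58, the good-solvent value), and the
vesicle volume fraction from bilayer geometry is 9.7% — the number that
feeds the Einstein/Krieger–Dougherty comparison and the ≈90 nm
face-to-face distance estimate.

Single-instrument commands work on any CSV in the documented formats:

```sh
vesiscope dls fit data/dls_neat_35C.csv
vesiscope saxs peaks data/saxs_unextruded.csv --qmin 0.5 --qmax 3.0
vesiscope dsc analyze data/dsc_neat.csv
vesiscope fls calibrate data/calibration_35C.csv --temp 35
```

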