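# spotqa

Patient-specific quality-assurance (PSQA) toolkit for spot-scanning proton
therapy, exercised end-to-end on synthetic plans, synthetic "measurements"
and synthetic delivery logs. Three components:

* **Independent dose engine** — an analytical pencil-beam dose calculation
  in water: a Bortfeld-style closed-form Bragg curve (parabolic cylinder
  functions) fitted simultaneously across energies through a shared
  power-law range–energy calibration, and a lateral kernel built from two
  Gaussians (multiple Coulomb scattering) plus a normalizable
  Cauchy–Lorentz heavy tail (large-angle scattering). Optional range
  shifter as a water-equivalent depth shift.
* **Gamma-index comparison cascade** — point-dose difference, 2D γ with
  global dose criterion and low-dose threshold, a "2.5D" depth search
  (±3 mm around the nominal plane) for distal-gradient failures, 3D γ on
  plane stacks, and the clinical pass/review/fail disposition at a 90%
  action level (2%/2 mm → 3%/3 mm → 2.5D gates). A brute-force γ search is
  included as an independent oracle.
* **Delivery-log analytics** — per-spot/per-fraction deviation statistics
  (maps, histograms vs X/Y, cross-fraction reproducibility), delivered-dose
  reconstruction from recorded positions and MUs, and periodic-QA pattern
  checks (squares/diagonals with 1/2/3 mm perturbations).

Everything the toolkit consumes can be generated by `spotqa.synthetic_data`
with controlled ground truth; all file formats are plain text (ASCII grids,
CSV, JSON/YAML).

## CLI

```sh
spotqa fixtures --out fx --seed 1        # worked-example directory
spotqa compute-dose --library fx/beam_library.json --field fx/field.csv \
    --depth 12.0 --out plane.txt
spotqa compare --reference fx/measured_plane.txt \
    --evaluated fx/calculated_plane.txt --out report.json --markdown report.md
spotqa gamma25d --measured fx/measured_plane.txt --library fx/beam_library.json \
    --field fx/field.csv --nominal-depth 12.0 --out g25.json
spotqa analyze-log --log fx/spot_log.csv --out deviations.json
spotqa pattern-qa --log fx/pattern_log.csv --pattern fx/pattern_spec.json \
    --out pattern.json
spotqa report --compare report.json --log-summary deviations.json --out psqa.md
```

Exit codes: 0 success, 1 validation failure, 2 usage error. Reports are
byte-deterministic for fixed inputs and seeds.

## Conventions

Depths and ranges are water-equivalent in g/cm² (1 mm water = 0.1 g/cm²);
lateral coordinates in mm at the isocenter plane; dose grids are
corner-origin and row-major with y along axis 0. γ uses a global dose
criterion normalized to the reference maximum, threshold applied to the
reference plane only, and γ ≤ 1 counts as passing.
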