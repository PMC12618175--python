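# fourdct

In-silico comparison of the two acquisition modes of respiratory-correlated
CT (4DCT) for radiotherapy planning: **volume (cine) mode** — the couch is
stationary while data covering at least one breathing cycle are acquired,
then stepped — and **helical mode** — the couch moves continuously at a very
low pitch so every slice is irradiated for a full cycle. The two modes trade
off differently between image quality per unit dose, preservation of target
shape and volume across respiratory phases (*dimensional accuracy*), and
fidelity of the reconstructed motion trajectory (*positional accuracy*).
`fourdct` is written for medical physicists and imaging researchers who want
a reproducible, fully synthetic testbed for those trade-offs.

The package provides:

* a **surrogate-signal module**: sinusoidal and irregular breathing
  generators, cycle detection, period/amplitude/irregularity summaries, and
  retrospective phase sorting under peak or point-to-point gating triggers;
* a **digital motion phantom**: a 3 cm sphere (−40 HU) in low-density
  background (−700 HU) on a clinical-resolution grid, rendered at any
  displacement, with analytic ground truth for volume and trajectory;
* an **acquisition simulator** for both scan modes: couch/beam timing,
  cine-frame versus continuous retrospective phase selection,
  rotation-window temporal blur, seeded HU noise, and a relative dose proxy
  (mAs per mm of scan length);
* a **QA metric suite**: CNR = (M₁ − M₂)/√((SD₁² + SD₂²)/2) from paired
  spherical ROIs, dose-normalised CNR, fixed −200 HU threshold segmentation
  with largest-component retention, per-phase volume / integrated HU volume
  and their coefficients of variation, per-phase centre-of-mass errors
  against the known motion input, and surrogate correlation;
* a **paired TOST equivalence test** (margin = 5% of the pooled mean) for
  respiratory metrics measured under both modes in the same patients;
* a **workflow/CLI layer** that runs the full mode × pattern × replicate
  grid deterministically, reads and writes NIfTI/DICOM phase series and
  surrogate-trace CSVs, and evaluates externally supplied 4DCT data.

## Worked example

Run the default desk-scale experiment — both scan modes under normal
(A = 1 cm, T = 4 s), rapid (A = 2 cm) and 15%-irregular breathing on a
128 × 128 × 120 grid at 0.976 × 0.976 × 1.0 mm:

```python
from fourdct.workflow import ExperimentConfig, run_phantom_experiment

config = ExperimentConfig(replicates=1, base_seed=0)
report = run_phantom_experiment(config)
for key, cond in report.summaries["per_condition"].items():
    print(f"{key:18s} |dV| {cond['mean_abs_volume_diff_cm3']:.2f} cm3   "
          f"|dz| {cond['mean_abs_error_mm']:.2f} mm   "
          f"r {cond['surrogate_correlation']:.3f}   "
          f"dose {cond['dose_proxy_mas_per_mm']:.1f} mAs/mm")
```

```
volume:normal      |dV| 0.77 cm3   |dz| 1.84 mm   r 0.971   dose 3.8 mAs/mm
volume:rapid       |dV| 1.59 cm3   |dz| 3.69 mm   r 0.972   dose 3.8 mAs/mm
volume:irregular   |dV| 0.78 cm3   |dz| 1.77 mm   r 0.975   dose 3.8 mAs/mm
helical:normal     |dV| 0.91 cm3   |dz| 1.19 mm   r 0.983   dose 14.3 mAs/mm
helical:rapid      |dV| 2.54 cm3   |dz| 2.34 mm   r 0.983   dose 14.3 mAs/mm
helical:irregular  |dV| 0.89 cm3   |dz| 1.24 mm   r 0.984   dose 14.3 mAs/mm
```

Reading the columns: `|dV|` is the mean absolute deviation of the segmented
sphere volume from the analytic 14.14 cm³ across the ten phases — it grows
sharply under rapid motion and more for helical than for volume mode (the
sliced acquisition shears the moving target). `|dz|` is the mean absolute
centre-of-mass error against the known sinusoid — consistently smaller for
helical mode, whose continuous acquisition hits each nominal phase more
precisely than the discrete cine image stack. `r` is the Pearson correlation
between the reconstructed trajectory and the external surrogate
(cf. clinical values around 0.97). The dose proxy is higher for helical
mode: its image-quality edge costs dose, so volume mode wins on
dose-normalised CNR.

The same grid runs from a shell:

```sh
fourdct simulate --config my_experiment.yaml --seed 0 --out report.json
fourdct report --in report.json --out-csv report.csv
fourdct evaluate --phases exported_phases/ --trace breathing.csv \
    --ctdi 33.8 --out patient_metrics.json
fourdct fixtures --out fixtures/ --seed 0
```

`evaluate` consumes real scanner exports (one NIfTI per phase with a JSON
sidecar, or one DICOM series directory per phase) plus a two-column
`time_s,amplitude_mm` surrogate CSV, and applies the identical metric suite
— with a console CTDIvol supplied for dose-normalised CNR.

Worked numeric examples from the published paired comparison ship with the
package (`fourdct.reference_data`): the six phantom ROI-statistics rows
reproduce the printed per-pattern CNRs (e.g. M₁ = −40.95, SD₁ = 11.61,
M₂ = −690.71, SD₂ = 61.60 → CNR 14.66), the mode-averaged CNRs over the
console CTDIvol values give dose-normalised CNRs of 0.54 (volume) versus
0.47 (helical), and the ten per-patient respiratory periods are TOST-
equivalent between modes (mean paired difference 0.015 s against a 0.188 s
margin).

## Documentation

`docs/methods.md` describes the signal and phantom models, the acquisition
timing model and its mode asymmetries, the metric definitions, numerical
choices, and what conclusions the synthetic experiments do and do not
support.
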