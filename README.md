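# magbead

Modelling and quantification toolkit for a magnetic-microwire microfluidic
immunoassay. The package covers the computational chain of the device
end-to-end, on synthetic or tabulated inputs:

- **`magbead.magnetics`** — closed-form magnetostatics: charge-sheet field of
  uniformly magnetized cuboid permanent magnets, the two-magnet applicator
  assembly, the dipole-line field of the transversely magnetized microwire,
  and a dipole-grid discretization used as an independent numerical oracle.
- **`magbead.materials`** — single-valued magnetization curves for the soft
  wire core and the superparamagnetic beads, with the bead saturation
  back-calibrated to the design capture force.
- **`magbead.transport`** — rectangular-duct flow, point-dipole bead force,
  overdamped capture trajectories, and drag-vs-holding-force retention.
- **`magbead.protocol`** — pump/valve schedule: duty-cycled multiplexing over
  five channels, per-step volumes/durations and the assay timeline.
- **`magbead.cytometry`** — event-table ingestion (CSV and a minimal FCS 3.0
  reader/writer), boundary-inclusive polygonal gating, doublet-corrected mean
  fluorescence and stock-background subtraction.
- **`magbead.calibration`** — saturation-exponential calibration
  `I(C) = A (1 − e^(−BC))`, full and fixed-B fits, closed-form concentration
  inversion with dilution/mass-ratio scaling, quadrature error budget and
  limit-of-detection logic.
- **`magbead.synthetic_data`** — seeded generators for event clouds
  (noise/singlet/doublet clusters), multi-channel calibration experiments
  with truth records, and bead initial conditions.
- **`magbead.workflow`** — orchestration plus the `magbead` CLI.

## CLI

```sh
magbead design-check                 # field landscape vs design anchors
magbead protocol                     # step table and total assay time
magbead gen-data --seed 42 --out run/    # synthetic 5-channel assay run
magbead quantify --events-dir run/ --out report.csv
magbead report --quantification report.csv
magbead simulate-capture --n-beads 200 --rates 0,25,50,100
```

`--config config.yaml` overrides any subset of the built-in configuration
(magnet geometry/remanence, wire radii, bead parameters, channel geometry,
pump program, gates, calibration constants); see
`magbead.workflow.default_config()` for the full key set.

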