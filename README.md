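# fa-screenkit

Quantitative image analysis and screening statistics for focal-adhesion (FA)
biology, exercised end-to-end on synthetic fluorescence-microscopy data with
exactly known ground truth.  The toolkit covers four analysis families plus
the generators that make them testable offline:

- **`fa_screenkit.synthetic`** — seeded generators for fields (nuclei +
  peripheral FA puncta, optional actin/cytoplasm/membrane channels), whole
  plates with role-based control wells and per-gene effect multipliers, a
  readout-level screen simulator, and time-lapse movies with scheduled FA
  birth/growth/decay events, planted merges and rigid drift.  Every
  generator emits its planted truth (integer pixel areas, counts, effect
  multipliers, event schedules, drift paths) alongside the images.
- **`fa_screenkit.quant`** — per-field FA segmentation (median filter,
  sliding-paraboloid background subtraction, Otsu threshold, inclusive
  50–5000 px size window in `screen` mode or 50–500 px plus a 0.00–0.95
  circularity filter in `percell` mode), nuclei counting by
  prominence-based maxima of the smoothed nucleus channel, a local
  focus-score QC statistic, and field-level exclusion rules
  (out-of-focus, > 20,000 raw objects, ≤ 2 nuclei).
- **`fa_screenkit.screen`** — well aggregation, Z′-factor plate QC,
  plate-wise Z-scores, primary hit calling (Z > 4.2 on FAs per cell or
  Z > 3.5 on FA area, ≥ 50-cell viability filter) and secondary-screen
  confirmation (mean fold vs mock ≥ 1.30 across two replicates).
- **`fa_screenkit.morphology`** — cell-spreading area (Gaussian blur +
  Triangle threshold, ≥ 500 px objects, divided by nuclei) and protrusive
  area per cell (Huang-thresholded membrane outline, marker-controlled
  watershed of the inverted cytoplasm channel, elevated mask subtraction).
- **`fa_screenkit.dynamics`** — time-lapse analysis: masked integer-pixel
  drift correction (±20 px clamp), segmentation-based auto-cropping,
  per-frame FA segmentation with overlap tracking (splitting off,
  merge/split bookkeeping), log-linear assembly/disassembly rate fits, and
  novel-FA counting that excludes first-frame and merge/split tracks.
- **`fa_screenkit.io` / `fa_screenkit.pipeline` / CLI** — TIFF field/stack
  IO, CSV tables with schema versioning and config-hash stamps, YAML run
  configs, and reproducible stage orchestration.

## CLI

The `fa-screenkit` entry point groups the stages:

```sh
fa-screenkit simulate-field --out fields/f0.tif --seed 1
fa-screenkit quantify --input fields/ --out out/ --mode screen
fa-screenkit simulate-screen --out screen_out/ --plates 2 --wells 100 --seed 7
fa-screenkit screen --plate-table plate1.csv --plate-table plate2.csv --out out/
fa-screenkit simulate-movie --out movies/m0.tif --frames 60 --seed 2
fa-screenkit dynamics --input movies/ --out dyn_out/
fa-screenkit protrusion --input cells.tif --out cells.csv
fa-screenkit spreading --input fields/ --out spreading.csv
```

Every pipeline run writes its effective configuration
(`run_config.yaml`) next to its outputs; all tables carry the config hash
and seed, and identical config + seed reproduces byte-identical tables.

## Conventions

- Pixel indices are 0-based `(row, col)` with the origin at the top-left.
- Connected components use 8-connectivity; size-filter bounds are
  inclusive.
- Filter "radius" follows the Fiji convention: median radius defines a
  disc neighbourhood, Gaussian radius is used directly as sigma.
- Circularity is `4π·area/perimeter²` with the `skimage.measure`
  perimeter estimator, clipped to 1.0 before range filtering.
- Assembly/disassembly rates are per-minute magnitudes of the
  least-squares slope of log mean intensity over the growth/decay phase.
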