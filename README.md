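# attnwarp

Tooling for studying how feature-based attention biases the perceived color
of a search target away from distractor colors:

- **`attnwarp.colorspace`** — circular hue arithmetic and the 360-entry
  fixed-luminance CIELab color wheel (L\* = 54, center a\* = 21.5,
  b\* = 11.5, chroma 49).
- **`attnwarp.experiment_design`** — deterministic trial-design generators
  for the four oddball-search + 2AFC experiments (300 / 432 / 288 / 240
  trials), including per-trial stimulus sampling.
- **`attnwarp.synthetic_observer`** — a generative signal-detection
  observer: the internal target representation is shifted `bias` degrees
  away from the distractor with noise `sigma` and lapse rate `lapse`; the
  nearer of target and foil is chosen.  Linearized and fully circular
  (wrapped-normal) variants; single-subject and cohort simulation.
- **`attnwarp.sdt_model`** — 2AFC d′ (`sqrt(2) * Phi^-1(p)` with `1/(2n)`
  clamping), per-cell summaries, maximum-likelihood fitting of the bias
  model (shared or per-distance bias, optional lapse), and the chance-point
  identity `bias = delta / 2`.
- **`attnwarp.population_geometry`** — a bank of color-tuned neurons with
  feature-similarity attentional gain, pattern distance matrices, classical
  (Torgerson) MDS, and warping metrics (embedding radii CV, asymmetry index,
  expansion location).
- **`attnwarp.pipeline`** / **`attnwarp.cli`** — schema validation, search
  accuracy based exclusion filtering (< 0.70 for E1–E3, < 0.40 for E4),
  and a reproducible end-to-end run bundle.

## CLI

```sh
attnwarp design   --experiment E1 --seed 1 --out design.csv
attnwarp simulate --experiment E2 --seed 1 --bias 9 --sigma 9 --out trials.csv
attnwarp analyze  --data trials.csv --out analysis/
attnwarp geometry --amplitude 1.0 --attended-hue 20 --out geometry/
attnwarp run      --config config.yaml --seed 1 --out run_out/
```

A run config is YAML; for example:

```yaml
experiment: E2
seed: 7
n_observers: 30
cohort:
  bias_by_D: {30: 11.5, 60: 5.3, 180: 0.0}
  bias_sd: 2.0
  sigma: 9.0
  search_accuracy: 0.95
geometry:
  gain: {attended_hue: 20.0, amplitude: 1.0}
out_dir: run_out
```

`run` writes `design.csv`, `trials.csv`, `exclusions.csv`, `summaries.csv`,
`fit.json`, geometry tables, and a `run.json` record (package version,
config hash, seed, exclusion counts, convergence flags).  Reruns with the
same config are bit-identical.  Exit codes: 2 for validation errors, 1 for
computation failures.

Real trial exports can be analyzed by pointing `data_path` at a CSV and
supplying a `column_map` from the shared schema names to the file's columns
(see `attnwarp.pipeline.ingest_table`).

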