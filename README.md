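# leanmass

Non-invasive estimation of lean body mass from spot urine samples, with
mixed-model analysis against fruit availability.

Urinary creatinine and specific gravity (SG) both track urine
concentration, but only creatinine scales with muscle mass. This package
implements the residual-creatinine approach as a reusable pipeline:

1. **FAI** — a monthly fruit availability index: the percentage of
   censused stems with dbh > 10 cm that are fruiting, split into
   high/low periods at the series median.
2. **Dilute filter** — samples with SG < 1.003 are excluded (strictly).
3. **Calibration** — a single global least-squares fit of creatinine on
   `(SG − 1)` and `(SG − 1)²` forced through the origin; its residuals
   are the estimated lean body mass (**ELBM**, mg/ml scale).
4. **Models** — an additive mixed model of ELBM on age-sex class
   (treatment-coded), a penalized cubic regression spline of continuous
   FAI (smoothing parameter by REML) and a random intercept per
   individual; relevel-style pairwise class contrasts; and a binary
   high/low-FAI linear mixed model with population-level predictions.
5. **Synthetic data** — a generator with an explicit latent model
   (lognormal hydration, FAI-coupled lean mass, multiplicative assay
   noise) so every stage is testable by parameter recovery.

The mixed models are fitted by a compact profiled-REML engine
(`leanmass.mixed`) in which both the spline's smoothing parameter and
the individual intercepts are variance components; it is validated in
the test suite against statsmodels `MixedLM` and closed-form GLS solves.

## Command line

```sh
# generate a synthetic dataset with known ground truth
leanmass simulate --seed 7 --out-dir synth

# individual stages
leanmass fai --phenology synth/phenology.csv --out fai.csv
leanmass calibrate --samples synth/samples.csv --sg-threshold 1.003 --out-dir out
leanmass analyze --elbm out/elbm.csv --individuals synth/individuals.csv --fai fai.csv --out-dir out
leanmass report --elbm out/elbm.csv --individuals synth/individuals.csv

# or everything from a YAML config
leanmass all --config config.yaml
```

A minimal config:

```yaml
samples_path: synth/samples.csv
individuals_path: synth/individuals.csv
phenology_path: synth/phenology.csv
output_dir: out
sg_threshold: 1.003
seed: 7
```

Every full run writes `manifest.json` (config echo, seed, version, row
counts per stage, fit statistics) so any artifact can be regenerated
byte-identically.

## Layout

- `src/leanmass/synthdata.py` — population, phenology and urine-sample generator
- `src/leanmass/fai.py` — fruit availability index and high/low split
- `src/leanmass/elbm.py` — dilute filter, through-origin calibration, ELBM, class summaries
- `src/leanmass/smoothing.py`, `mixed.py` — penalized spline basis and REML engine
- `src/leanmass/models.py` — additive/binary mixed models, contrasts, predictions
- `src/leanmass/io.py`, `config.py`, `pipeline.py`, `cli.py`, `plots.py` — I/O, config, driver, CLI, figures
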