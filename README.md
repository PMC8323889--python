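# shapeincome

Tools for studying the relationship between body shape and family income on
cohorts of 3D body scans — for economists and biostatisticians who want to
replace sparse, error-prone body proxies (self-reported height, weight, BMI)
with low-dimensional shape parameters learned directly from the scan surface.

The package implements, end to end:

- **Synthetic cohort generation** — fixed-topology template meshes deformed
  by latent stature / adiposity / hip-to-waist factors, with nonclassical
  self-reporting errors, an unobserved ability factor that makes stature
  endogenous, and sizing instruments that satisfy the exclusion restriction.
  Every downstream method is testable without any restricted data.
- **A graphical autoencoder** — an hourglass network whose input neurons are
  the mesh vertices (reference architecture 256–64–16–d–16–64–256 on 45,534
  inputs), trained by reconstruction MSE with RMSprop. The bottleneck gives
  body parameters P1..Pd; a validation-MSE elbow scan selects the intrinsic
  dimension d; decoded ±σ sweeps and linear fits against height/weight/BMI
  give the parameters their anatomical reading. A PCA baseline runs under
  identical preprocessing.
- **Reporting-error diagnostics** — Nadaraya–Watson conditional means of
  `reported − measured` given the truth (Epanechnikov kernel, Silverman
  bandwidth), pointwise bootstrap bands, zero-crossing location, and
  linear-mean / quantile error regressions.
- **Income equations** — statsmodels-style Model/Results objects for

      log FamilyIncome_i = α'X_i + β' BodyShape_i + ε_i

  with robust SEs, subject-bootstrap confidence bands, a control-function
  (two-stage residual inclusion) correction for endogenous stature with an
  exogeneity test, and dollar-effect conversions of log-income coefficients.

## Worked example

```python
from shapeincome import (CohortConfig, generate_cohort, flatten_cohort,
                         GraphicalAutoencoder, EncoderSpec, TrainConfig,
                         IncomeModel, ModelSpec)
from shapeincome.autoencoder import align_to_measurements, correlate_with_measurements

# 1. a 2,000-subject male cohort: two active shape factors, meshes + table
cohort = generate_cohort(CohortConfig(n_subjects=2000, seed=2, male_fraction=1.0))

# 2. embed the meshes: 576 inputs -> 2 body parameters
ds = flatten_cohort(cohort.meshes, center=True, scale=True)
res = GraphicalAutoencoder(
    ds, EncoderSpec(ds.n_inputs, bottleneck_d=2, hidden_widths=(64, 32, 16)),
    TrainConfig(epochs=450, batch_size=100, seed=0)).fit()
print(res.summary())

# 3. name the parameters, then estimate the income equation on them
table = cohort.table.copy()
P, labels = align_to_measurements(res.P, table[["measured_height", "measured_weight"]])
table[["P1", "P2"]] = (P - P.mean(0)) / P.std(0)
print(correlate_with_measurements(table[["P1", "P2"]].to_numpy(),
                                  table[["measured_height", "bmi"]]).round(3))
fit = IncomeModel(table, ModelSpec(body_terms=("P1", "P2"), gender="male")).fit()
print(fit.params[["P1", "P2"]].round(4), fit.tvalues[["P1", "P2"]].round(2))
```

Step 2 prints (this exact run):

```
layers:          576-64-32-16-2-16-32-64-576
subjects:        2000 (train 1600, validation 400)
epochs/batch:    450/100   seed 0
final train MSE: 1.7138e-04
final valid MSE: 2.0061e-04
parameter sd:    P1=0.4201, P2=0.1984
```

The validation MSE is ~1.7% of the input variance: two parameters
reconstruct the mesh cohort nearly to the vertex-noise floor. Step 3 shows
what the parameters are (simple linear fits of the classical measures on
each parameter) and what they earn:

```
parameter     measurement  slope  intercept  r_squared
       P1 measured_height  6.976    175.586      0.997
       P1             bmi -1.039     25.538      0.109
       P2 measured_height  0.192    175.586      0.001
       P2             bmi  2.955     25.538      0.884

P1    0.0759        P1    6.92
P2    0.0042        P2    0.37
```

P1 is the stature parameter (R² = 0.997 against height), P2 the adiposity
parameter (R² = 0.884 against BMI), and they are nearly orthogonal. In the
income equation a one-SD increase in stature is associated with +0.076 log
income (t = 6.9) while adiposity is insignificant — the male pattern the
generator builds in (its true per-SD stature effect is 0.06).

## Command-line pipeline

```sh
shapeincome validate --config configs/demo.json
shapeincome run --config configs/demo.json --out demo_run
```

runs generate → embed → diagnose-errors → estimate and writes a results
bundle (subject CSVs, loss curves, R² tables, kernel curves with bands,
coefficient tables, a summary JSON) plus a manifest with per-stage config
hashes; unchanged stages are reused on rerun. Single stages:
`shapeincome generate|embed|diagnose-errors|estimate`.

## Layout

```
src/shapeincome/
  meshes.py        fixed-topology Mesh, OBJ/PLY io, flattening, ring girths
  synthetic.py     cohort generator: template, deformation, errors, income
  autoencoder.py   GraphicalAutoencoder / AutoencoderResults, dimension scan,
                   measurement correlation, PCA baseline
  reporting.py     KernelRegression / KernelCurve, bootstrap bands,
                   error regressions, zero crossings
  income.py        IncomeModel / ControlFunctionModel, bootstrap bands,
                   dollar-effect conversions
  pipeline.py      config-driven orchestration and results bundles
  cli.py           click commands
docs/methods.md    model and procedure documentation
```
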