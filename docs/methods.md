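# Methods

This note documents the models and procedures implemented in `shapeincome`,
the assumptions behind them, the defaults, and what the synthetic cohorts do
and do not establish.

## The estimation problem

The package estimates the association between body shape and log family
income,

    log FamilyIncome_i = α'X_i + β' BodyShape_i + ε_i,

where `X_i` collects education years, experience and its square, race,
occupation, marital status and number of children, and `BodyShape_i` is
either a classical proxy set (BMI, height, weight, hip-to-waist ratio =
hip circumference / waist circumference × 100) or low-dimensional body
parameters extracted from a 3D body scan. Three obstacles motivate the
pipeline:

1. **Nonclassical reporting error.** Self-reported height and weight are
   not noisy-but-unbiased versions of the truth: heights are over-reported
   (more so by short women) and the weight error's conditional mean crosses
   zero — light people over-report, heavy people under-report. Regressions
   on self-reports are therefore biased in ways classical attenuation
   formulas do not describe.
2. **Sparsity of classical measures.** Height, weight and BMI compress a
   high-dimensional surface into scalars; estimates built on them are
   sensitive to which proxies enter the equation.
3. **Endogeneity of stature.** Unobserved factors (ability) plausibly move
   both stature and income, so even perfectly measured stature carries an
   omitted-variable bias.

## Graphical autoencoder

Subjects are observed as fixed-topology triangle meshes: every subject has
the same vertex count and ordering, so vertex `i` is anatomically
comparable across people. A cohort flattens to an `n × 3·n_v` matrix
(vertex-major, xyz-minor); at the reference 15,178-vertex topology this is
45,534 inputs per subject.

The embedding model is an hourglass multilayer perceptron: encoder widths
256–64–16 to a bottleneck of width `d`, mirrored decoder, trained to
minimize reconstruction mean-squared error with RMSprop (batch 200, 80:20
train/validation split with a floor-rule training count, 5,000 epochs at
reference scale). The bottleneck activations are the subject's body
parameters P1..Pd. Implementation is plain NumPy with explicit
forward/backward passes, making runs exactly reproducible from a seed on a
fixed BLAS configuration.

Numerical choices (the data do not dictate these; they are declared
defaults):

- **Activation.** tanh on the hidden stacks; the bottleneck and output
  layers are linear, because body parameters and vertex coordinates are
  unbounded signed reals and a saturating bottleneck would distort ±3σ
  sweeps.
- **Input normalization.** Columns are centered and the matrix divided by
  its maximum absolute entry, so inputs lie in [−1, 1] and reconstruction
  MSEs are comparable across cohorts.
- **Initialization.** Glorot-uniform weights, zero biases, seeded.
- **Learning-rate schedule.** RMSprop with exponential decay from 3e-3 to
  1e-4 over training. The decay matters: with a constant rate the final
  validation MSE wanders in a "noise ball" whose run-to-run spread is
  larger than the gains the dimension scan must resolve.
- **Precision.** float32 by default (about twice the CPU throughput);
  float64 available via `TrainConfig.dtype` (used by the gradient-check
  tests).
- **NaN guard.** Training aborts with learning-rate guidance if the loss
  goes non-finite.

**Intrinsic dimension.** The scan trains one model per candidate `d` and
chooses the smallest `d` whose relative validation-MSE improvement to the
next candidate falls below a threshold (default 5%). Two stabilizers are
applied, both justified by nested capacity (true validation MSE cannot
increase in `d`): per-candidate MSE is averaged over the final 10% of
epochs, and gains are computed on the running-minimum envelope across
candidates. Raw MSE increases beyond 5% are recorded as warnings, as is a
scan where no candidate plateaus.

**Interpretation.** Learned dimensions are identified only up to
permutation and sign. `align_to_measurements` resolves this by greedily
matching each classical measurement (height, weight, hip-to-waist) to the
remaining parameter with the largest absolute correlation, flipping signs
to make the correlation positive. Decoded ±1.5σ/±3σ sweeps along each
parameter, measured with the mesh-measurement operators, verify the
stature/adiposity/hip-waist reading. A PCA baseline under identical
centering/scaling provides the linear reference embedding.

## Reporting-error diagnostics

Errors are `reported − measured`. The conditional mean E[error | truth] is
estimated by Nadaraya–Watson with an Epanechnikov kernel and Silverman's
rule-of-thumb bandwidth `h = 2.34 · min(sd, IQR/1.349) · n^(−1/5)` (2.34 is
the kernel's canonical constant; both constants are config-exposed, since
the rule, not the constant, is standard). The evaluation grid is 101 points
between the 1st and 99th percentile of the truth — kernel estimates at the
sample boundary are unstable and scientifically uninteresting here.
Confidence bands are pointwise percentile intervals from a pairs (x, y)
nonparametric bootstrap (not a residual bootstrap: no model is assumed),
default 95%. The zero crossing of the estimated weight-error curve is
located by linear interpolation between grid points; all crossings are
returned, the first reported.

Linear-mean regressions of error on truth use OLS with HC1 robust errors;
quantile regressions minimize the check loss (statsmodels' IRLS) with
pairs-bootstrap standard errors, which are more trustworthy than asymptotic
ones at the non-smooth objective. Default quantiles 0.25/0.5/0.75.

## Income equations and the control function

OLS fits use heteroskedasticity-robust (HC1) standard errors — the right
default when the error-variance structure is unknown. Categorical
covariates expand to dummies against declared reference levels (white /
married / managerial); occupation enters as fixed effects. Confidence
bands are nonparametric bootstrap over subjects (default 90%, B=400),
reported as percentile intervals.

For endogenous stature the control-function (two-stage residual inclusion)
estimator regresses stature on the instruments — shoe size, jacket size
for men / blouse size for women, pants size — plus all exogenous
covariates, then adds the first-stage residual to the income equation.
The residual's robust t-test is the test of the null of exogenous stature
(5% default level). The first-stage robust Wald F on the excluded
instruments is reported; F < 10 flags weak instruments without aborting.
Bootstrap inference re-runs *both* stages inside every resample — required
for valid inference with a generated regressor.

Effect-size conversions: a log-income coefficient `c` at base income `B`
is reported both as the exact `B(e^c − 1)` and the linear `B·c` dollars
(published dollar figures may use either convention). Per-SD coefficients
on body parameters convert to per-cm effects by dividing by the decoded
height change per parameter SD, measured from sweeps — never assumed.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the conditions under
which every downstream claim is verified.

**Geometry.** The template is a capped tube of `rings × segments` vertices
whose radius profile is interpolated through hand-authored body stations
(legs, hip bulge at relative height 0.52, waist pinch at 0.63, chest,
shoulders, neck, head). Radii are calibrated once so that enclosed volume ×
density (985 kg/m³) equals the gender's base weight (78 kg male / 62 kg
female) at base height (175 / 162 cm). Latent factors deform the template
multiplicatively: stature scales z by 1 + 0.04·s per z-score (≈7 cm/SD),
adiposity scales all radii by 1 + 0.06·o (≈12% of weight per SD), and the
hip-to-waist factor scales radii up near the hip station and down near the
waist through Gaussian bumps of half-width 0.10 in relative height (wide
enough to span several rings at the 16-ring toy scale). i.i.d. Gaussian
vertex noise (3 mm) is added last. Women draw an active hip-to-waist
factor; male hip-waist variance is zero — so the generative intrinsic
dimension is 2 for men and 3 for women. Measured height, weight and girths
are always derived from the subject's mesh (vertical extent, enclosed
volume × density, ring-polygon perimeters), never shortcut from the
latents.

**Reporting errors.** Height: +1 cm over-report for everyone, plus, for
women, 0.15 cm of extra over-report per cm of measured height below
162 cm, plus N(0, 0.6 cm) noise. Weight: −0.25·(weight − pivot) with
pivots 75 kg (men) / 50 kg (women) plus N(0, 1.5 kg) noise, so the
conditional mean error crosses zero exactly at the pivot.

**Income and endogeneity.** Log income is a linear index in the covariates
(education 0.08/yr, experience 0.02 − 0.0004·exp², children −0.02,
small race/marital/occupation offsets, intercept 9.5) plus gender-specific
latent-factor effects (men: stature 0.06, adiposity 0.005; women: stature
0.01, adiposity −0.06, hip-waist 0.005 — positive stature premium for men,
adiposity penalty for women) plus λ_g·ability plus N(0, 0.5) noise. A
single standard-normal ability factor loads with the same λ_g on realized
stature (stature = s₀ + λ_g·a) and on income; the default λ is 0.6 for
women and 0 for men, so female stature is endogenous and male stature is
not. Under this one-confounder structure the OLS plim bias on stature has
the closed form λ²/(1+λ²), used as the oracle in tests.

**Instruments.** Shoe/garment/pants sizes load (0.8/0.6/0.7) on the
*exogenous skeletal component* s₀ of stature with independent N(0, 0.6)
noise: correlated with stature, independent of ability and of the income
disturbance. This is the substantive content of the exclusion restriction —
frame size is set by skeletal growth, not by the ability channel — and it
is what makes the control-function null and alternative both reachable
with one knob.

**Covariates.** Education and experience are truncated normals
(13.5 ± 2.5 on [8, 22]; 18 ± 10 on [0, 45]), children Poisson(1.1) capped
at 6, race/marital/occupation categorical with fixed plausible
probabilities. None of these marginals is an estimate of any real survey;
they are config values chosen once to give non-degenerate, realistic
regressions.

**Gender counts.** Quota mode (default) makes the male count exactly
`round(male_fraction · n)` — the default 2,383-subject cohort reproduces
1,122 men and 1,261 women; binomial mode draws genders independently.

**What the generator does not emulate.** Real anthropometric shape
statistics (the tube is not an anatomical model), garment-sizing standards,
missing data, income top-coding, or dependence between covariates and body
shape beyond the single ability factor. Passing tests therefore establish
that the estimators recover the structures they target *when those
structures are present as modeled* — internal validity of the machinery,
not external claims about any real population.

## Problem sizes in tests and the acceptance script

Desk-scale runs use the 16×12-ring template (576 inputs), hidden widths
(64, 32, 16), 450 epochs, batch 100, cohorts of 600 (dimension scans, 5
seeds per gender mode), 2,000 (latent recovery, control-function and
coverage studies; 100–200 Monte-Carlo seeds) and 4,000 (reporting-error
curves). These sizes were chosen so the full statistical battery runs on a
single CPU while every check retains its discriminating power; the
CAESAR-scale architecture (45,534 inputs, 256–64–16–d) is the documented
default of `EncoderSpec` and runs unchanged, just longer.

## Known limitations

- The dimension scan inherits optimizer noise; its stabilizers (tail
  averaging, monotone envelope) make the 5-seed recovery check robust
  but a single scan on a single seed can still plateau one dimension early
  or late.
- Kernel bands are pointwise, not uniform, and carry smoothing bias near
  curvature; coverage checks use interior grid points.
- The control-function estimator assumes a linear first stage and a scalar
  confounder, matching the generator; with richer confounding its
  exogeneity test is a specification test, not a certificate.
- Quantile-regression IRLS can hit its iteration cap on small resamples;
  bootstrap draws that do so still contribute their last iterate.
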