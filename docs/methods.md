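# Methods

This note records the models implemented in `possireg`, the defaults and
numerical choices behind them, and what the synthetic-data tests do and
do not demonstrate.

## Data model and encoding

A study table has exactly one continuous response (triglycerides,
mg/dL), continuous predictors (waist circumference in cm, HDL in mg/dL)
and a categorical predictor stored as ordered integer codes
(blood-pressure status: 0 normal, 1 borderline, 2 high). A categorical
variable with `a` levels is represented by `a − 1` binary indicators;
the reference level (default: code 0, normal blood pressure) maps to the
all-zero pattern, so every coefficient on an indicator is a shift
relative to the normotensive baseline. Design-matrix column order is
fixed — intercept, continuous variables in declared order, indicators in
level order — so coefficient reports are stable across runs.

Input CSVs are comma-separated with a header row and `.` decimals. Rows
with missing cells are listwise-deleted and counted; a category code
outside the declared levels is treated as a data error and raises,
naming the row and value, rather than being silently dropped — with a
dozen records, an impossible code is more likely a transcription error
worth surfacing than noise worth discarding.

## Bootstrap

Each replicate draws `replicate_size` rows (default: the original sample
size) uniformly with replacement; `n_replicates` (default 1000)
replicates are concatenated into the pseudopopulation that downstream
models are fit to. Per-replicate column means are retained; their mean
converges to the original column mean and their SD approximates the
standard error s/√m of the sample mean. The expected fraction of
distinct original rows per replicate is 1 − (1 − 1/m)^m (≈ 0.632 for
large m), which the tests verify against simulation. All resampling is
driven by a NumPy generator seeded per run. Downstream models are fit to
the concatenated mega file by default (`fit_on="mega"`); fitting to the
raw table is exposed as an option. Note that inference statistics (OLS
standard errors, p-values) computed on the mega file treat resampled
copies as independent observations and are therefore optimistic; they
describe the pseudopopulation, not the original 14 patients.

## MLP predictor validation

The network has one hidden layer: `ŷ(x) = Σⱼ wⱼ g(Σᵢ vⱼᵢ xᵢ + E₁ⱼ) + E₂`
with a linear output node. Defaults: H = 2 hidden nodes, logistic
activation (tanh available), 70:30 train/test split, 2000 full-batch
gradient-descent iterations at learning rate 0.5. Gradient descent was
chosen over quasi-Newton or stochastic methods because at these problem
sizes speed is irrelevant while bitwise determinism under a seed is a
requirement; the learning rate is halved whenever a step would increase
the training loss ("bold-driver" damping), which makes descent monotone
and scale-robust. If the loss never falls below its initialisation value
a convergence warning is issued and the model is returned as-is.

Inputs are min-max scaled to [0, 1] with train-set ranges stored on the
model; the response is min-max scaled the same way internally (stored as
`output_scaling`, default identity) and inverted at prediction, so a
single learning-rate default works across response scales and reported
MSEs are always on the raw mg/dL scale. The intercept column is not a
network input — the biases E₁, E₂ play that role.

Subset validation trains one network per non-empty subset of candidate
predictor blocks (a categorical variable's indicators form one block)
on a shared seeded split, and ranks subsets by test MSE ascending, ties
broken by smaller subset then lexicographic order. Exhaustive
enumeration is refused above 2¹² subsets. The train-row count is
`round(f·m)` clamped to `[1, m − 1]` so both partitions are non-empty at
extreme fractions.

## Ordinary least squares

The dummy-coded model `Trig = β₀ + β₁Waist + β₂HDL + β₃Border +
β₄Hyper + ε` is fit by OLS (QR-based, via statsmodels) with standard
inference: SEs from σ̂²(XᵀX)⁻¹, two-sided p-values against
t(residual df). Both plain and adjusted R² are reported; the plain R² is
the headline number. Rank-deficient designs raise an error naming the
dependent columns rather than silently pseudo-inverting.

## Possibilistic fuzzy regression

Coefficients are triangular fuzzy numbers Ãⱼ = (aⱼ, cⱼ) with support
[aⱼ − cⱼ, aⱼ + cⱼ]. Fitting minimises the data-weighted total spread
Σⱼ cⱼ Σᵢ |xᵢⱼ| subject to the h-level coverage constraints (see README)
— a linear program with free centers and non-negative spreads, solved
with HiGHS. Choices:

- **h defaults to 0**: the minimal-spread model whose support band
  contains all observations, the usual default in this model family; h
  is a parameter of every entry point.
- **An intercept term is always included** and behaves as a regressor
  with constant value 1, so its spread contributes once per observation.
- **Symmetric spreads are the default**; an asymmetric mode with
  independent left/right spreads (objective weight (cⱼᴸ + cⱼᴿ)/2) is
  provided for data whose residuals are skewed. Any symmetric solution
  is feasible in asymmetric mode at equal cost, so the asymmetric
  optimum never exceeds the symmetric one.
- **All-zero predictor columns** contribute nothing to any constraint,
  leaving their spread unidentified; it is pinned to 0 with a warning.
- **Spreads below 1e-9 are reported as exactly 0**, so noiseless data
  yield a visibly crisp model.
- After solving, the support band's containment of every training row is
  re-verified (tolerance 1e-6 relative to the response magnitude) and
  the objective is recomputed from the returned coefficients; either
  failing raises, as it would indicate a solver fault.

Useful identities the test suite exploits: the objective is
non-decreasing in h (constraints only tighten); scaling y by s > 0
scales centers, spreads and objective by s; at zero noise the centers
equal the generating coefficients and all spreads vanish.

## Synthetic cohorts

The generator emulates the study's variable structure: waist ~
N(92, 10²) cm, HDL ~ N(50, 12²) mg/dL, blood-pressure codes drawn with
probabilities (0.50, 0.25, 0.25), and response = linear predictor +
N(0, noise_sd²) with default coefficients (79.43, 0.3349, 0.5786,
8.557, 19.935) and noise SD 10 mg/dL — physiologically plausible values
that put fitted coefficients at the magnitudes a lipid-panel regression
reports. Default cohort size is 14. The generator deliberately does
not model covariance between waist, HDL and blood pressure, outliers,
measurement rounding, or non-Gaussian noise; passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not robustness of the workflow to real clinical data quirks.

## Pipeline

`run_pipeline` executes load/generate → encode → bootstrap → MLP subset
validation → OLS → fuzzy fit, with phases II and III restricted to
exactly the subset phase I validated (a `force_full_model` flag bypasses
the gate, reflecting that in practice a clinical expert may pre-select
the variables). A single master seed derives per-stage seeds through
`SeedSequence`, making artifact files byte-identical across reruns.
Artifacts per run: the input table, the mega file with replicate index,
the subset ranking, the OLS and fuzzy coefficient tables, the three
equations, and a JSON provenance record (seeds, row counts, timings).

## Problem sizes

Default runs use 14-patient cohorts, 1000 bootstrap replicates (14,000
mega rows), 7 predictor subsets and 2000 training iterations per subset;
a full pipeline completes in under ten seconds on one CPU, and the
entire test suite — including 500-cohort OLS coverage sweeps and the
brute-force LP cross-checks — in well under a minute. The brute-force
LP oracle used in tests enumerates constraint-set vertices and is only
applied to datasets with at most 6 observations and 2 predictors.

## Known limitations

- Fuzzy outputs/inputs are out of scope: only the coefficients are
  fuzzy, and only triangular memberships are supported.
- The possibilistic fit is sensitive to outliers by construction — a
  single extreme observation widens the band, since coverage is a hard
  constraint.
- No bias-corrected bootstrap intervals, stratification, robust or
  weighted regression, interactions, or imputation.
- MLP subset enumeration is exhaustive; no forward-selection mode is
  implemented yet (the cap error message suggests it as the workaround:
  shrink the candidate list).
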