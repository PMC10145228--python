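# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the package. Units are fixed
project-wide: dose in mg, volume in L, clearance in L/h, time in hours,
concentration in ng/mL (1 mg/L = 1000 ng/mL).

## Structural and statistical PK model

Concentrations follow a one-compartment model with first-order absorption
(rate constant Ka) and first-order elimination (rate ke = CL/V). Under
repeated dosing of amount D every τ hours, the concentration at time t
since the first dose is the superposition of Bateman terms over all
administered doses. Because the doses are equally spaced, the sum is
evaluated with the geometric closed form

    Σ_{j=0}^{n−1} e^{−k(t_ad + jτ)} = e^{−k·t_ad} (1 − e^{−kτn}) / (1 − e^{−kτ}),

applied at k = ke and k = Ka, which is algebraically identical to the
per-dose sum but immune to exponential overflow at large dose counts. The
degenerate case Ka → ke uses the exact limit (per-dose term k·Δt·e^{−kΔt}).
The closed form is verified against direct ODE integration of the
gut/central system to 4 significant digits in the test suite.

Between-subject variability acts on clearance only:
CL_i = TVCL(covariates_i)·exp(η_i), η_i ~ N(0, ω²). An optional η on volume
is deliberately not implemented (sparse steady-state sampling identifies it
poorly, and clearance dominates steady-state exposure). Residual error is
additive, y = C + ε, ε ~ N(0, σ²); proportional and combined error models
are out of scope.

Covariate submodels on clearance: continuous covariates enter as power
terms (x / reference)^θ with the reference taken as the dataset median
(falling back to the mean, floored at 1, for count covariates whose median
is 0); binary covariates as multiplicative level ratios, stored as
(θ_level0, θ_level1) pairs so that with a single effect and TVCL equal to
the level-0 value the two levels reproduce the two level clearances
directly. Race enters as three separate binary indicators.

## FO estimation

The marginal likelihood is approximated by linearizing the model in η
about η = 0 (the classical first-order method): per subject,
y_i ≈ f_i(0) + g_i·η_i + ε with g_i = ∂f/∂η|₀ evaluated by a central
difference (step 1e-4 on η). The marginal covariance ω²·g_i g_iᵀ + σ²·I is
rank-one, so the determinant-lemma and Sherman–Morrison identities reduce
the −2 log-likelihood (OFV) to per-subject scalar sums; the whole objective
is vectorized over observations. Optimization is L-BFGS-B on log-scale
parameters (log TVCL, log V, log ω, log σ, plus effect coefficients), with
three jittered starts (seeded, multiplicative jitter SD 0.2) to reduce
local-minimum risk; the best OFV wins and the procedure is deterministic
given the jitter seed. Ka is fixed at 0.5 h⁻¹ by default (standard for this
drug; estimable via a flag). `PopPKParams.sigma_add = 0` is accepted by the
container (the simulator uses it for noise-free data) while the fitter
floors its starting value and bounds σ ≥ 1e-6.

Forward covariate selection refits the current model plus each remaining
candidate, accepts the largest OFV drop if it clears the χ² quantile at
p < 0.01 for the effect's degrees of freedom (6.635 for one parameter,
computed from `scipy.stats.chi2.ppf`, never hard-coded), and repeats until
no candidate qualifies. Individual (empirical-Bayes) predictions maximize
the per-subject posterior over η by bounded scalar search; the benchmark
RMSE is computed on these individual predictions, matching how such
benchmarks are usually reported.

## Synthetic-data generator

The generator emulates the *structure* of a pooled two-arm antipsychotic
trial, not its actual concentrations:

- **Population**: 523 subjects by default; each belongs to a schizophrenia
  arm (probability 406/523) or a dementia arm. Ages come from the
  corresponding truncated normals — N(42, 10.9²) on [18, 65] and
  N(78, 8.5²) on [45, 103] — giving a pooled median near 45. Weight is
  N(84.43, 22.1²) truncated above 30 kg; sex is male with probability
  332/523; smoking 274/523; race white/black/other at 346/149/28 out of
  523. Concomitant-medication counts are Poisson with means 4 (total), 0.3
  (inducers), 0.5 (inhibitors) and 1.5 (substrates) — plausible values for
  a chronically medicated population; no published marginals exist for
  them, so these are synthetic defaults, not literature values.
- **Dosing**: dementia arm 2.5–20 mg once daily; schizophrenia arm
  7.5–30 mg/day once or twice daily (50/50), drawn from the clinically used
  dose strengths.
- **Sampling**: 1–6 samples per subject with a mildly decreasing pmf
  (0.28, 0.20, 0.17, 0.14, 0.11, 0.10; mean ≈ 2.9), reproducing the
  observed overall sparsity of ~1527 samples per 523 subjects; a uniform
  pmf is available via `SamplingConfig.samples_pmf = None`. Samples are
  taken at steady state (≥ 10 administrations, visit dose-counts drawn up
  to 400) at a uniform 2–24 h after the most recent dose (capped by the
  interval). Time since first dose assumes uninterrupted dosing, so the
  regimen is recoverable from (TSFD, INTERVAL) alone.
- **Calendar**: each observation receives a distinct global calendar index
  from a seeded permutation, made chronologically consistent within each
  subject — so the date-ordered split mixes subjects across partitions, as
  a pooled multi-site trial would.
- **Truth**: every dataset is returned with a `SimulationTruth` (population
  parameters, per-subject η draws, seed); regeneration from the same seed
  and configuration is bit-identical.
- **Defaults**: CL 15.90 L/h, V 2182 L, Ka 0.5 h⁻¹ (typical olanzapine
  values), ω = 0.3 (~30% CV) and σ = 10 ng/mL. The variance components are
  synthetic defaults chosen to give realistic scatter in the 0–150 ng/mL
  range; no published estimates exist for this configuration.

What the generator does **not** emulate: dropout and non-adherence, visit
scheduling, assay quantification limits, covariate drift over time,
multi-compartment kinetics, and any real concentration values. Passing
tests therefore demonstrate internal correctness and statistical operating
characteristics under the stated generative model — not clinical
performance on the restricted data.

## Preprocessing

Rows are sorted by calendar index (ties broken by subject then sample time,
so the split is deterministic for any input order); the first ⌊0.70·N⌋ rows
form the training set. The split is row-level, as a pooled date-sorted
split implies, so a subject may appear in both partitions — a leakage
caveat inherited from the design being reproduced and flagged here
deliberately. Min-max scaling is fitted on the training partition only
(`scaler_scope="pooled"` reproduces the alternative); validation values may
fall outside [0, 1] and are never clipped; constant features scale to 0
with a logged warning. RMSEs are always reported on the ng/mL scale after
inverse scaling.

Each observation becomes one sequence sample: the subject's current and
previous `time_steps − 1` (TSFD, dose) records within the partition,
front-padded with zeros before the subject's first observation — the only
fixed-length construction consistent with per-observation prediction —
plus the 11 scaled covariates and the scaled concentration target.

## LSTM-ANN

The network is implemented directly in numpy (no deep-learning framework is
required): gates use the standard sigmoid recurrences; the candidate is
tanh; the configurable "LSTM activation" is the cell-output activation,
h_t = o_t ⊙ act(C_t), with act = ReLU by default and tanh available. All
time-step outputs of every LSTM block are kept, so the flatten layer
exposes every hidden state to the dense head; stacked blocks likewise pass
full sequences. Dropout (rate 0.1, inverted scaling) follows every LSTM and
dense block during training only — two evaluation passes are bit-identical.
The output unit is linear by default (the scaled target can exceed 1 on
validation data); a ReLU output is available by config.

Training uses per-sample Adam updates (batch size 1, the configuration
being reproduced), seeded Glorot-uniform initialization, seeded per-epoch
shuffling, optional gradient-norm clipping (off by default), and records
the per-epoch mean training loss. Backpropagation through time is verified
against central finite differences in the test suite, and the layer's
forward pass against an independently coded per-step recurrence. A
non-finite loss aborts with the epoch and learning rate in the message.

Reference architecture (`ArchitectureSpec()` defaults): one 8-node LSTM
block, two dense blocks of 88 and 184 nodes, time steps 2, dropout 0.1 —
19 377 trainable parameters, matched against the closed-form count.

## Hyperparameter search

The searchable space is: 1–3 LSTM blocks, 8–256 LSTM nodes, 1–3 dense
blocks, 8–256 nodes per dense block (sampled independently per block),
learning rate log-uniform on [1e-4, 1e-3], epochs 40–120. Activations,
optimizer, batch size and time steps are fixed.

The TPE sampler is univariate: after 10 random startup trials, completed
trials are split at the γ = 0.15 objective quantile; each group's density
is a Parzen mixture with per-point bandwidths taken from neighbor gaps
(clipped to [range/min(100, n+1), range]) plus an always-present prior
component at the range midpoint with full-range bandwidth — the prior is
what keeps exploration alive late in the study. 24 candidates drawn from
the good density are scored by log l(x) − log g(x) and the best is kept.
The objective is the final-epoch training MSE (scaled space); the final
model is chosen by validation RMSE among completed trials, ties broken by
smaller parameter count then earlier index.

Pruning is successive-halving-style: trials report training loss per epoch;
at rung epochs 10, 20, 40 and 80 a trial whose loss exceeds the median of
previously recorded losses at that rung (minimum 4 records) is stopped. No
trial can be pruned before epoch 10, protecting slow-starting batch-1 runs.
Pruned trials keep their partial history and no validation RMSE. The study
journal is append-only JSON-lines and studies resume from it.

The default budget is 50 trials — adequate for the small models involved;
a deterministic separable surrogate objective (`toy_objective`) is provided
for benchmarking samplers without training costs.

## Permutation importance

Baseline RMSE is computed once on the ng/mL scale on the validation
partition (the ranking partition; a train flag exists for diagnostics). For
each covariate and repetition, the covariate's column is shuffled across
all validation samples with an independent seed derived from
(root seed, covariate index, repetition) via `SeedSequence`, predictions
are recomputed, and the importance is the RMSE increase. Ten repetitions
give the mean ± SD (SD reported as 0 for a single repetition); the report
is sorted by descending mean, ties broken by name. One-hot race columns are
permuted independently like any other covariate, so a permuted sample may
transiently hold an invalid race combination — acceptable because the model
consumes the columns as plain numbers.

## Problem sizes and tolerances

The test suite exercises the statistical claims at desk scale, chosen as
the smallest sizes at which the properties are comfortably separated from
noise: parameter recovery at 500 subjects × 20 replicates (CL within 15%,
V within 25% — volume is weakly identified from steady-state data);
selection power at 200 subjects × 20 replicates and type-I error at 100
subjects × 100 replicates; network training checks at 300 subjects with 40
epochs; sampler comparison over 20 paired 40-trial studies. Scaler algebra
is exact to 1e-12, structural-model agreement to 4 significant digits, and
LSTM layer/oracle agreement to 1e-5 (observed: machine precision).

## Known limitations

- The FO approximation is biased for large ω; FOCE/SAEM are out of scope.
- Volume estimates from steady-state sparse designs are imprecise by
  nature; the wider recovery tolerance reflects the design, not the code.
- Row-level chronological splitting lets subjects straddle partitions (see
  above).
- TPE is univariate (no interaction modeling between hyperparameters).
- Training is strictly batch-size-1 and CPU-bound; large node counts are
  slow because the Adam update dominates at one sample per step.
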