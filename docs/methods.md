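# Methods

## The generative model

`vambn` generates fully synthetic cohorts for longitudinal studies whose
data are *heterogeneous* (mixed statistical types), *incomplete* (skipped
visits) and *modular* (variables fall into expert-defined groups such as
times, nutrition, anthropometry, socioeconomics). The model composes two
parts:

1. **Per-module heterogeneous-incomplete VAEs.** Each module's slice of the
   participant × visit × variable array is compressed to a low-dimensional
   embedding consisting of a discrete mixture component `s` (one-hot,
   uniform prior) and a Gaussian code `z` with component-dependent prior
   mean `p(z|s) = N(mu_s, I)`. The decoder maps `z` through a shared network
   `g(z)` to a homogeneous representation `Y` with one slice per visit; a
   separate small head turns each visit's slice (concatenated with `s`)
   into the parameters of one (visit, variable) likelihood:

   | dtype | head |
   |---|---|
   | real | Gaussian on the standardised scale |
   | positive_real | Gaussian on the standardised log scale |
   | count | Poisson, log link |
   | categorical / boolean | softmax over levels |
   | ordinal | cumulative link: ordered thresholds minus a scalar |

   The joint factorises as `p(x, z, s) = p(s) p(z|s) prod_v prod_d
   p(x_vd | z, s)`, and the training objective (ELBO) sums log-likelihood
   contributions over **observed cells only**. Missing encoder inputs are
   zero after standardisation, so a missing cell's stored value can never
   influence the fit; the information that a visit was skipped lives in the
   attendance indicators, not in the fill value.

2. **A conditional linear-Gaussian Bayesian network** over all module
   embeddings, the standalone covariates (e.g. sex) and one boolean
   attendance indicator per visit. Discrete nodes carry conditional
   probability tables; Gaussian nodes carry one linear regression (intercept,
   parent weights, residual variance) per configuration of their discrete
   parents; discrete nodes never have Gaussian parents. Structure is learned
   by greedy hill climbing on the BIC score with add/delete/reverse moves,
   seeded random restarts and lexicographic tie-breaking, under user black/
   white edge lists. Two structural constraints are always imposed: each
   module's `s` node is whitelisted into its own `z` nodes, and for the
   per-visit (baseline) variant edges from later-visit module nodes to
   earlier-visit ones are blacklisted.

Synthesis is ancestral sampling of the network followed by decoding each
module's sampled embedding through its likelihood heads. Raw output always
has full attendance and no cell-level missingness.

### Encoder variants

* **baseline** — one autoencoder per (module, visit); all temporal structure
  must be carried by the network over the many per-visit embeddings.
* **FT (flattened)** — one autoencoder per module; the V visit inputs are
  concatenated and passed to a feedforward encoder.
* **MT (sequence)** — as FT, but the per-visit inputs are consumed by an
  LSTM in chronological order and its final state feeds the posterior
  networks. With V = 1 both FT and MT reduce to the baseline contract.

The expectation over the discrete component in the ELBO is computed by
exact enumeration of the `s_dim` components weighted by `q(s|x)` rather
than by a sampled relaxation; for the small `s_dim` used here this is exact
and lower-variance, and it keeps encoding extraction (argmax component,
posterior-mean code) trivially deterministic.

### Why a bespoke numerical core

The autoencoder is trained with a small reverse-mode automatic
differentiation engine over numpy arrays (`vambn/_nn.py`) providing exactly
the operations the model needs (broadcast arithmetic, matmul, the usual
nonlinearities, reductions, slicing, an LSTM cell and Adam). Its gradients
are verified against central finite differences in the test suite. The
Bayesian network learner is likewise implemented directly (BIC scoring with
closed-form Gaussian/multinomial fits, networkx for acyclicity), because the
conditional linear-Gaussian family with mandatory/forbidden edge lists is
the exact object the pipeline needs.

## Defaults and tunable parameters

| parameter | default | meaning |
|---|---|---|
| `s_dim` | 3 | mixture components per module |
| `z_dim` | 2 | Gaussian code dimensions per module |
| `hidden_dim` | 32 | width of encoder/decoder hidden layers |
| `lstm_units` | 16 | LSTM output dimensionality (`h_end`), MT only |
| `y_dim` | 8 | width of each visit's slice of `Y` |
| `epochs` / `batch_size` / `learning_rate` | 250 / 64 / 1e-3 | Adam training |
| `bn_max_parents` | 4 | parent limit during structure search |
| `oversample_factor` | 1.5 | raw pool size relative to the target size |

All of these are per-module configurable (`PipelineConfig.module_overrides`);
no setting is hard-wired. Posterior log-variances are squashed to [-4, 4]
and standardisation guards against zero spread, which keeps training stable
on degenerate (near-constant) variables.

## Post-processing

A raw synthetic cohort is matched to a reference in three steps: stratified
subsampling on sex down to the reference's participant count (the raw pool
is oversampled so each stratum can be filled; the fraction then matches to
well under one percentage point), resampling of whole empirical attendance
patterns from the reference (which preserves the entry-age structure better
than independent per-visit coin flips), and blanking of visits whose study
time exceeds the reference's observed maximum (such records would lie in
the future). Blanking only removes values; surviving cells are never
altered.

## Evaluation suite

* **Distributions** — per-variable summary statistics and base-2
  Jensen-Shannon divergence of histograms with shared edges; the bin count
  is the larger of Sturges' rule and the Freedman-Diaconis estimator
  computed on the reference sample, with edges spanning the pooled range.
  Discrete variables use raw category frequencies. Base 2 makes the
  divergence land in [0, 1] with 1 for disjoint support. Per-visit
  divergences are averaged with equal weights per visit, then over
  variables (mean ± SD).
* **Correlations** — pairwise-complete Pearson matrices over all
  (variable, visit) columns, ordered group-major then visit-ascending, and
  the relative error `eps = ||R_real - R_synth||_F / ||R_real||_F`.
  The reference's missingness pattern is imposed on the synthetic cohort
  first so both matrices rest on comparable observation sets; undefined
  correlations (constant columns) count as zero in both.
* **Direct dependencies** — violation rate of a monotone boolean flag
  (observed consecutive 1→0 transitions over observed transitions), the
  per-consecutive-visit-pair error Δtime − Δage (15 values per fully
  attended 16-visit participant), and |protein + fat + carbohydrate − 100|
  per record.
* **Trends** — `outcome ~ axis + axis² + axis³` with a per-participant
  random intercept, fitted by maximum likelihood. Internally the axis is
  centred and scaled and the coefficients and their covariance are mapped
  back to the raw basis exactly (raw cubic designs are numerically
  ill-conditioned); the optimiser falls back from L-BFGS to BFGS/Powell on
  linear-algebra failures, and non-converged fits are flagged and excluded
  from aggregation with a logged count. Aggregation over repeatedly sampled
  datasets reports the per-grid-point mean, empirical 2.5%/97.5% quantiles
  (numpy's default interpolation of order statistics) and the fraction of
  datasets with all three polynomial terms at p < 0.05.

## The cohort simulator

Because the motivating study's records are not public, the package ships a
simulator that reproduces its *structure*, not its numbers: 1312
participants by default, 16 annual visits covering ages 3–18 (visit =
rounded age − 3), 2 static covariates plus the participant id and 33
longitudinal variables (530 wide columns), entry mostly at visit 0 with a
late-entering minority, independent per-visit skips, and three deterministic
dependencies — `time = age + offset` exactly, a 0→1-only education flag, and
macronutrient fractions summing to exactly 100. The added-sugar outcome is
cubic in age plus cubic in calendar time with per-participant random
intercepts (SD 2 %E) and residual noise (SD 2 %E); the default age
coefficients (−0.35, 0.21, −0.012) produce a rise to a peak near age 10–11
followed by a slow decline, and the time trend is gently decreasing. The
true coefficients are returned with every draw, so the simulator doubles as
the parameter-recovery oracle; `corrupt_fixture` injects an exactly known
number of dependency violations as negative controls for the metrics.

What the simulator does **not** emulate: real dietary measurement error,
secular changes in attendance, correlations between nutrition and
socioeconomic variables beyond what the module structure induces, or the
original study's actual effect sizes. Passing tests therefore demonstrate
that the machinery is correct and that the expected *orderings* hold (the
sequence encoder preserves cross-visit structure best), not that any
specific published number is reproduced.

## Problem sizes used by tests and the acceptance script

The variant-comparison study runs at 300 participants, 4 visits, 6
variables in two modules and 150 training epochs — small enough to iterate
on while still exhibiting strong cross-visit dependence; the trend studies
use the full 1312-participant simulator (recovery) and a 600 × 8 two-module
cohort (synthetic significance). These sizes are the package's declared
experiment defaults. For the recovery harness the simulator is configured
with the calendar-time coefficients at zero so the generating model for the
age-axis regression is exactly the fitted model; with both trends active the
unadjusted single-axis model is deliberately misspecified (as it is for the
real analyses it mirrors) and no longer a parameter-recovery oracle.

## Known limitations

* Linear-Gaussian network nodes cannot represent multimodal or heteroscedastic
  dependence between module codes beyond what the discrete components induce.
* Hill climbing finds local optima; the exhaustive-scoring guarantee in the
  tests covers three-node problems only.
* The time/age lock is learned, never enforced: even the sequence encoder
  leaves a residual increment error, consistent with the motivation for
  evaluating this dependency explicitly.
* Poisson is the only count head; over-dispersed counts would need a
  negative-binomial extension.
* The trend harness fits a random intercept only; random slopes are out of
  scope.
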