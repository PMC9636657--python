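# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of `callusopt`. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`; nothing is
quoted from elsewhere.

## The problem and its encoding

The unit of analysis is a *culture condition*: one cell of the factorial
design (hormone treatment 1–8 × explant × MS strength 1/4/8 × sampling day
8/25; 192 conditions). Raw data are per-explant-piece replicate records
(callus yes/no, callus diameter in mm); 24 replicates per condition in 3
sub-sets of 8 mirror the completely randomized design of the screening
experiment the package emulates. Conditions are summarised to an induction
percentage (0–100), a mean diameter over callused pieces (0 if none) and a
speed value, and these summaries — not the raw replicates — are what the
surrogates model, because percentage and speed are condition-level
quantities.

The feature encoding is a 10-vector: the four hormone concentrations in
mg/l, the MS multiplier (1/4/8, numeric), the sampling day (numeric), and a
one-hot explant block. Explants are unordered categories, hence one-hot;
MS strength and day are dose-like and kept numeric. The encoding is a
bijection on the grid (tested exhaustively).

**Units and the speed formula.** Diameter units are nowhere fixed by the
underlying experiment's description; mm is assumed throughout and recorded
here as an assumption. The canonical speed definition used in the raw and
summary CSVs is *sampling time divided by mean callus diameter* (day/mm),
with speed = 0 when no callus forms so every condition has a finite outcome.
This definition makes large, fast-growing calli "slow", so the package also
provides the physically conventional `inverted` mode (mm/day). Both modes
are first-class; the default merely follows the as-stated definition. The
two readings are reconciled in the generator and optimizer as follows: small
calli maximise the day/mm value, growth-rate desirability (mm/day) is what
the optimizer maximises.

## Synthetic-data generator

`simulate_experiment` draws from a 192-row effect table: induction
probability `p`, diameter mean `mu` (mm, conditional on induction) and
spread `sigma`. Per sub-set, `p` is perturbed on the logit scale
(`N(0, 0.3)` by default) to give between-sub-set overdispersion — a
logit-normal random effect, chosen because the experiment reports sub-sets
but no variance components; 0.3 gives within-condition percentage spreads
of roughly ±10 points at mid-range `p`, a realistic bench-to-bench
variation. Probabilities of exactly 0 and 1 are clamped (no noise): the
all-or-nothing outcomes they encode are treated as structural, which makes
the 0%/100% blocks of the design exactly reproducible at any seed.
Replicate outcomes are Bernoulli; diameters of callused pieces are
Normal(mu, sigma) truncated at zero (a gamma model was considered and
rejected — at sigma/mu ≈ 0.1–0.3 the truncation is almost never active and
the normal keeps the moments transparent). One seed fixes the whole table
bit-exactly.

The default effect table encodes the emulated study's reported outcome
structure:

* 8× MS: `p = 0` everywhere (mineral toxicity suppresses callus);
* 4× MS: `p = 1` for treatments 5–7 on every explant, `p = 0` for
  treatments 1, 2, 4 and the hormone-free control 8; treatment 3 is
  unreported at 4× and given an intermediate 0.30/0.255 (day 25/8);
* 1× MS: graded response. Shoot explants are strongest in treatments
  1, 2, 5, 6, 7 with the global optimum `p = 1` at treatment 6
  (0.5 mg/l 2,4-D + 0.5 mg/l BAP) on day 25; nodal explants are strong in
  treatments 2–6 and weak in 1 and 7.

Only the extremes and orderings above are reported facts; every intermediate
probability (the 0.15–0.90 values) and all diameter parameters are free
modelling choices, set once so that (i) the stated orderings hold, (ii)
day-8 probabilities are 0.85 of day-25 ones (induction accumulates over
time), (iii) leaf explants grow the largest calli with the maximum growth
rate at (leaf, 1×, treatment 6, day 8) — day-8 diameters are 0.55 of day-25
ones, so early sampling always wins on mm/day — and (iv) leaf and root
pieces in treatment 4 form the smallest calli, making them the "fastest" on
the day/mm scale. Choices (iii)–(iv) reconcile the two speed readings noted
above. Tests then check that models and optimizer *recover* this structure
from simulated data; what passing shows is internal consistency of the
pipeline under realistic noise, not anything about new laboratory data.

`expected_summaries` exposes the infinite-replicate limit (percentage =
100p, diameter = mu) as a deterministic regression surface for
parameter-recovery tests.

## MLP surrogate

Architecture: 10 inputs → one hidden layer of 11 tanh units → linear
output. The width follows the emulated study's stated "11 hidden" topology,
read as 11 neurons in one layer (an 11-layer-deep net is implausible for a
≤384-row problem); depth is configurable for anyone wanting the literal
reading. Inputs and target are min–max scaled to [0, 1] (scaling inverted at
the interface; percentage predictions clipped to [0, 100]).

Training minimises MSE + α‖W‖² — the deterministic core of Bayesian-
regularised backpropagation; full evidence-based re-estimation of α is out
of scope. Gradients come from the analytic backprop pass and are driven by
L-BFGS-B (up to 2000 iterations, `ftol` 1e-12), so training is
deterministic given the seed that fixes the Glorot-style initial weights:
the recorded loss history is non-increasing over accepted epochs and
repeated fits are bit-identical. Default α = 3e-3 (on the scaled problem):
small enough that the noise-free surface is fit to R² > 0.99, large enough
that the fitted surface does not chase single-condition noise — the level at
which the surrogate's global maximum sits where the generating surface puts
it rather than on a sampled outlier.

The 90/10 train/test split (`round(n·f)` training rows, seeded shuffle)
matches the emulated modelling protocol; no validation split or early
stopping beyond it.

## RBF surrogate

Gaussian kernels `exp(−[d·0.8326/h]²)` on min–max-scaled features (so the
spread h is dimensionless and the one-hot block cannot dominate), centers at
all training points by default (k-means subset available for larger data),
weights plus unpenalised bias from ridge-regularised least squares solved in
stacked form (never via normal equations — the kernel matrix is
ill-conditioned at useful spreads). The constant 0.8326 ≈ √(ln 2) makes h
the half-response distance: a point at distance h from a center receives
kernel value ≈ 0.49996 (asserted to 1e-12). Whether that reading was
intended by the source formulation is unknowable; the constant is used
verbatim.

When h is not given it is selected on a 22-point log grid (0.063–7.9) by
closed-form leave-one-out error: Rippa's rule on the (ridged) kernel matrix
for all-point centers, the hat-matrix identity for subset centers. With
λ = 0 and distinct points the fit interpolates exactly (tested to 1e-6);
duplicate points with conflicting targets raise a solver error advising
λ > 0. The default λ = 1.0 deliberately smooths: an interpolating RBF
memorises replicate noise, and the regularised network reproduces the
qualitative model comparison the package emulates (MLP ≥ RBF on both
targets, asserted as a seeded regression test — a property of these study
conditions, not a theorem).

## Metrics and sensitivity

RMSE and R² use the standard forms √(SS_res/n) and 1 − SS_res/SS_tot
(cross-checked against scikit-learn to 1e-12, plus the identity
R² = 1 − n·RMSE²/SS_tot). R² refuses constant observations.

Variable sensitivity: the baseline model is fit on the full summary table
(fixed seed and hyperparameters) and its RMSE on that table is the
reference error. For each semantic input group — {4 hormone concentrations},
{MS multiplier}, {sampling day}, {explant block} — the model is retrained
with the group's columns removed and VSE(g) is the resulting RMSE;
VSR(g) = VSE(g)/baseline. Higher VSR ⇒ more essential input; an
uninformative column leaves VSR ≈ 1 (tested with a pure-noise dummy,
1 ± 0.1). Retraining (leave-one-covariate-out) rather than permutation is
the primary mode because "error without the variable" is the quantity the
ranking is meant to capture; permutation importance is available as a
cheaper alternative. Fitting and evaluating on the full table (no split)
keeps the comparison deterministic and isolates the variable's
contribution; the exact normalisation of the published VSE/VSR ranking is
not defined anywhere, so this ratio definition is a documented choice. On
default synthetic data the ranking is MS ≫ hormones > explant > day for the
percentage target, which the acceptance suite asserts.

## Genetic algorithm

Chromosome: (treatment 1–8, explant 1–4, MS index 1–3, day index 1–2).
Defaults: population 100, 1000 generations (the emulated run size),
crossover probability 0.9 with a uniform cut in {1, 2, 3}, per-gene uniform
resampling mutation at 0.05, binary tournament, elitism 1, and 5 random
immigrants per generation. Immigrants are the one addition to the textbook
operator set: with only neighbourhood-scale mutation a converged population
cannot reach distant optima on landscapes without exploitable structure,
and the package's contract is that the GA equals the exhaustive 192-point
enumeration in every seeded run. Five uniform draws per generation make the
expected coverage of the grid complete well within a default run while
leaving selection dynamics untouched. Fitness is memoised over the grid at
run start (192 surrogate evaluations), so a run costs integer operations
only.

Single-objective mode tracks the best-so-far fitness per generation
(monotone under elitism; ties broken toward the lexicographically smallest
chromosome so GA and brute force return identical answers even on flat
surfaces). The speed objective is maximised on the desirability (mm/day)
scale; `speed_sense="min"` negates predictions from an as-written-scale
surrogate instead.

Multi-objective mode is fast non-dominated sorting with crowding distance
(parent+offspring environmental selection), an archive of every evaluated
condition, and the final front computed on the archive — on a 192-point
space a default run visits essentially every condition, and the returned
front is verified to be a subset of the exact brute-force front. The
per-generation history records the best sum of min–max-normalised
objectives on the current rank-0 front (the published notion of a single
"multi-objective fitness value" is not pinned down; this scalarisation is a
documented choice). The single reported compromise solution maximises the
same normalised sum over the final front, with the rule named in the
output.

## Pipeline and reproducibility

`run_pipeline` derives stage seeds from one global seed by fixed offsets
(generator +0, MLP +1, RBF +2, GA +3, split +4; all mod 2³¹−1), writes raw
and summary CSVs, four serialized models (JSON), metric and sensitivity
reports, optimization results, and a manifest with the config, derived
seeds and sha256 of every artifact. Re-running an identical config is
byte-identical. Surrogates used for optimization are refit on the full
summary table (the split-fit models exist for honest generalisation
metrics; the optimizer should use all information available). Metrics for
the speed target are reported on the desirability scale, the scale the
speed models are trained on.

Default problem sizes (192 conditions × 24 replicates; 173/19 split; GA
100×1000) make every stage run in seconds on one CPU; the law-of-large-
numbers generator check uses 2400 replicates per condition.

## Known limitations

* The generator emulates outcome *structure*, not measured variance
  components; real screens have plate, operator and batch effects the
  logit-normal sub-set term only caricatures. Passing tests demonstrate
  pipeline correctness under the stated noise model, not field validity.
* Intermediate effect-table cells are modelling choices; conclusions that
  depend on their exact values (rather than the encoded orderings and
  extremes) are not meaningful.
* The goodness-of-fit figures reported for the original laboratory data
  cannot be checked without that dataset; the corresponding check in the
  acceptance suite requires a user-supplied export of it and fails
  otherwise (see `tests/test_acceptance.py::test_study_data_model_fit`).
* The optimizer searches the tested discrete treatments only; it does not
  interpolate hormone doses between them, by design.
* The MLP loss surface is non-convex; determinism is per-seed, and
  different seeds can reach different (similar-quality) fits.
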