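# Methods

This note documents the models implemented by the package, the defaults
and numerical choices, what the synthetic generators do and do not
emulate, and the known limitations.

## Regulatory network inference

A simplified local-GRN procedure in the hLICORN family:

* **Discretization.** Expression is mean-centered per gene and thresholded
  into {−1, 0, +1}.  The default threshold is one gene-wise standard
  deviation (`per_gene_sd=True` in `infer_network`); a fixed absolute
  threshold is available.
* **Mining.** For each target, all signed regulator sets with up to
  `max_set_size` members (default 2) are enumerated level-wise.  The
  combined state of a candidate is the elementwise min over co-activator
  states and negated co-repressor states; its support is the fraction of
  samples with nonzero target state where the combined state equals the
  target's.  Candidates need support ≥ `min_support` (default 0.6).
  There is deliberately **no Apriori support pruning**: the match-support
  statistic is not anti-monotone under min-combination, so pruning could
  drop satisfying sets.  This caps the practical regulator-set size, which
  is acceptable at the intended scale (tens to a few hundred regulators).
* **Scoring.** Each candidate is scored by the R² of an OLS fit of the
  continuous target expression on two covariates — min over co-activator
  expression and min over co-repressor expression — with an intercept so
  R² is the usual coefficient of determination, clipped to [0, 1].
* **Selection.** The merged score is `(1 − w)·R² + w·mean(edge evidence)`
  with `w = evidence_weight` (default 0, i.e. pure data; missing evidence
  counts 0).  Ties break toward the smallest regulator set, then
  lexicographically, so inference is fully deterministic.

These candidate-matching semantics (min-combination, support counted on
target-nonzero samples, centering before thresholding) are this package's
fixed contract; they are a simplification, not a reconstruction, of the
full published hLICORN (no bootstrapping or multi-run GRN merging).

## Influence scores

The influence of regulator *j* in sample *k* is the two-sample Welch
statistic between its activated and repressed target expression within
that sample (unbiased variances, set sizes as n).  Choices:

* `min_targets=2` per class (the smallest n with a defined sample
  variance); entries below that are NaN ("undefined") and propagate as
  missing predictions downstream.
* If both class variances are exactly zero with unequal means the
  statistic is ±∞; it is clamped to ±1e6 with a warning so downstream
  regressions stay finite.  Zero variances with equal means give 0.
* Targets absent from the expression matrix are dropped from the classes
  before computing.
* Values are used as given (no per-gene centering) by default; influence
  is invariant to adding a constant to, or positively rescaling, a whole
  sample, so global normalization shifts are harmless.  A
  `center_genes` flag exists for data with strong gene baselines.

## Linear influence predictor

Per-gene OLS of expression on the influences of the gene's regulators,
with **no intercept by default** (the linear model is a pure weighted sum
of influences; an `intercept` flag exists because real log-expression has
a nonzero baseline — with the flag off, baselines are absorbed into the
coefficients via the influence offsets, which is adequate when training
and context share the network).  No regularization by default; optional
ridge with fixed λ for ill-posed regulator sets.  Samples with any
required influence undefined are dropped per gene; genes with fewer
usable samples than coefficients + 1 are skipped and recorded.  Rank
deficiency falls back to the minimum-norm solution with a warning.

## GPR evaluation and softplus bounds

Boolean GPR strings are parsed into flat n-ary trees (AND binds tighter
than OR).  Continuous evaluation maps OR → max, AND → min.  The discard
rule — genes without an available activity are removed — applies at
every nesting level: discard first, then evaluate; a fully discarded tree
is "undefined" and the reaction keeps its model bounds.  Negative
activities pass through unchanged; the softplus already maps ℝ to (0, ∞),
so no flooring is needed.

The bound for a reaction with GPR value g at offset θ is
ln(1 + exp(g + θ)), computed as `logaddexp(0, g + θ)` (overflow-safe; may
underflow to exactly 0 for g + θ below about −745, which simply closes
the reaction).  Application to the model is by tightening only:
`ub ← min(ub, b)` and, for reversible reactions, `lb ← max(lb, −b)` — the
bound is mirrored because enzyme limitation is directionless, and model
irreversibility is never relaxed.

## FBA

The LP (max c·v, S·v = 0, bounds) is solved with HiGHS through
`scipy.optimize.linprog` at 1e−9 primal/dual tolerance; optimal solutions
are checked for steady state at 1e−6 per metabolite.  Infeasible and
unbounded problems are reported in the solution status, never raised.
Exchange reactions are detected structurally (single nonzero
stoichiometric column), overridable by an explicit list, since SBML
boundary conventions vary.  In tests, cobrapy solves the same models
independently as a cross-check; it is never the implementation.

## Calibration of θ

Objective: −ln(|v_obs − v_sim(θ)| / v_obs), floored at a relative error of
1e−9 so an exact match stays finite.  Natural log (the base only shifts
the objective's scale, not its argmax).  Search: 10-point uniform grid on
[−10, 10] (endpoints included), then deterministic golden-section
refinement on the bracket around the best grid point, within a total
budget of 50 simulations.  Growth is nondecreasing in θ (softplus bounds
only enlarge the feasible region), so the objective is unimodal and
golden-section is reliable and reproducible; the refinement method is a
recorded field of the result and can be swapped.  If the plain-FBA
optimum is below v_obs·(1 − 1e−3), no θ can close the gap and the result
is flagged `fba_underestimates` without refinement.  Calibration is
against biomass only.

## Dynamic FBA

Forward Euler with default Δt = 0.01 h: per step, uptake of each tracked
exchange metabolite is capped at min(V_max, C/(X·Δt)) so concentrations
cannot go negative; the FBA solve yields μ and exchange fluxes; then
X ← X(1 + μΔt) and C ← max(C + v·X·Δt, 0).  An infeasible step freezes
the state with μ = 0 and a flag.  Phase switching is checked at step
boundaries only (O(Δt) bias); the default trigger is a tracked
concentration falling below a threshold (default 1e−6), with an absolute
switch time as the alternative.  The step-halving convergence of the
integration is part of the test suite.  The integrator is not meant for
stiff kinetics — no pH, oxygen transfer, or Michaelis–Menten uptake
beyond the V_max cap.

## Robustness protocol

Noise level ℓ permutes the values of ⌊ℓ·n_genes⌋ uniformly chosen genes
within each sample (an independent permutation per sample), preserving
each sample's value multiset.  This fraction-of-genes reading of
"permutation noise", and the error normalization below, are this
package's choices.  The error statistic is the mean over observed
exchange fluxes of ((v_sim − v_obs)/s)² with s = max|v_obs|, unit-free
and reported raw and log10.  Streams are spawned per (level, replicate)
from one seed, so results are independent of evaluation order.

## Synthetic generators and the planted benchmark

Toy models: a 4-reaction chain (optimum = uptake bound), a 2-substrate
branch with distinct yields, and an abstract diauxic network — glucose →
2 pyruvate + 2 ATP, fermentation pyruvate → ethanol, respiration
pyruvate → 6 ATP, ethanol → 0.5 pyruvate, biomass = 6 ATP — with GPRs on
the regulated branches.  The stoichiometry was chosen once so that
fermentative growth ≈ 0.35 h⁻¹, respiratory growth ≈ 2.33 h⁻¹ per unit
glucose uptake, and the ethanol phase ≈ 0.25 h⁻¹: the qualitative
ordering of a real diauxic culture at toy scale.

Expression generators draw regulator profiles i.i.d. N(0, 1) per sample;
targets follow either the linear-influence regime (±effect·min over the
signed regulator sets + N(0, noise²), defaults effect 1.0, noise 0.2) or
the discrete-logic regime (amplitude·min-combined discretized states +
noise, amplitude 2.0).  An optional per-gene baseline offset
(N(0, baseline_sd²), constant across samples) emulates the gene-specific
expression levels of real log-scale data; it defaults to 0.

The end-to-end benchmark (`coregflux.benchmark.make_benchmark`) fixes the
study conditions in one place: 6 regulators × 120 targets (≈ 60 targets
per regulator, so influence genuinely pools — with only a handful of
targets the Welch statistic is itself noisy and the method's robustness
premise does not hold), 3 edges per target with 40 % repressors (every
regulator keeps both target classes), baseline sd 2, training compendium
of 100 samples, and three context conditions whose observed growth is
anchored at 0.35 h⁻¹ by calibrating θ on the noise-free context; the
working θ is then re-calibrated per condition from the noisy context, as
one would against a measured growth rate.  Robustness errors are pooled
over the three conditions per noise level.

What passing tests on this benchmark do **not** show: performance on real
transcriptomes (no probe-level noise model, no batch effects, no
condition-correlated structure), on genome-scale models (thousands of
reactions, nested isoenzyme/complex GPRs), or for regulators whose
targets are not informative about their activity.

## Known limitations

* Candidate mining is exhaustive up to the set-size cap; very large
  regulator panels need the cap kept small.
* The linear influence model cannot represent the min-combination
  nonlinearity of cooperative regulation; on such data its predictions
  are correlated but biased (visible in `examples/03`).
* θ is a single global offset per condition; per-reaction offsets are out
  of scope.
* Euler integration with boundary-only switch detection biases switch
  times by O(Δt).
* When plain FBA underestimates observed growth, calibration reports
  failure rather than relaxing the model.
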