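# Methods

## Scope and data model

The package analyses trial-level logs of a two-alternative speeded
directional task (every stimulus requires a left/right response) played in
three display environments, 2D, 3D and AR. One row per stimulus event:
participant, environment, 1-based trial index within the block, stimulus and
response direction, correctness (1 = "V", 0 = "F"), reaction time in ms, and
the inter-stimulus interval in seconds. The reference study conditions are
22 participants (six women), one 120-trial block per environment (360 events
per session), the arrow visible ~1 s, and ISI uniform on 0.7–1.3 s; these
are the generator defaults.

## Preprocessing

RTs below 200 ms are anticipatory by Welford's criterion — faster than
perceptual processing permits — and are removed before any modelling. The
exclusion is strictly "less than": a 200 ms RT survives. The threshold is a
parameter (`filter_rt(..., threshold_ms=200)`). Normality of RT is assessed
with the Shapiro–Wilk test; because the natural grouping unit is genuinely
ambiguous, the pipeline reports both the per-environment pooled test and a
per participant × environment table, flagging groups too small or constant
for the test instead of failing. Bimodality screening is supported by
histogram export only — a deliberately visual check; no dip test is
implemented because none is part of the reference procedure.

## Markov-chain estimation

Each participant-block becomes a binary outcome sequence. Windows of `w`
consecutive outcomes at stride 1 are the "chains of states": a sequence of
length L gives L − w + 1 windows (118 for L = 120, w = 3), and windows never
span participants or blocks. Windows are coded in base 10 with the **oldest
trial as the most significant bit** — the convention only affects labels,
never probabilities. Order-k transition tables count, for each length-k
history, the outcome of the following trial; probabilities are raw maximum
likelihood with **no smoothing**, so empirical 0%/100% cells are reported
as such, and histories never observed are flagged undefined rather than
imputed (`smoothing="add_one"` exists for downstream modelling that needs
strictly positive probabilities). Pooling across participants sums counts —
it never averages per-participant probabilities, so participants with more
surviving trials weigh proportionally more.

Filtered trials leave gaps. By default the survivors are treated as
consecutive (the simplest convention, and the one the pipeline uses for
reporting); `break_at_gaps=True` instead breaks every chain at a gap in the
original trial indices so no window spans a removed trial. Parameter
recovery is validated in this strict mode: with stitching, roughly 2% of
windows straddle a removed trial and mix two-step transitions into the
one-step conditionals, a small but measurable bias (~0.4 SE on the rarest
histories at study size) that the strict mode eliminates. Sequences shorter
than the window raise an explicit error rather than returning an empty
matrix, to surface data problems early.

## Reaction-time ANOVAs and the order rule

The **prior-state models** regress trial-level RT on m binary correctness
factors — level 0 is the current trial's outcome, level j the outcome j
trials back within the same block — for m = 1, 2, 3. The design is a
fixed-effects, main-effects-only factorial on pooled trials with Type II
sums of squares (robust to the mild imbalance of history cells; documented
so results reproduce bit for bit). Trials lacking m − 1 predecessors in
their block are dropped per model, mirroring the window construction. A
participant fixed factor is available (`include_participant=True`) but off
by default, matching a reference analysis that reports exactly one F per
level. No multiple-testing correction is applied by default; a Bonferroni
flag exists for methodological comparison.

The **order-assignment rule**: an environment is assigned Markov order
m* − 1, where m* is the smallest model size whose levels 0..m*−1 are all
significant at α = 0.05; if no model qualifies the result is
"undetermined". Applied to the published prior-state ANOVA summary bundled
in `REFERENCE_PRIOR_STATE_TABLE`, the rule yields order 0 for 2D, 1 for 3D
and 2 for AR.

**Cofactors** (answer V/F, coffee, mood, gender) are tested per
environment. Answer varies within participants and is tested on trial-level
RTs; coffee, mood and gender are constant within a participant, so they are
tested on participant-mean RTs — a trial-level test of a between-subject
factor would treat ~2,600 correlated trials as independent and its type-I
rate would be badly inflated by participant-level RT heterogeneity. The
grouping unit was an open design choice; this is the calibrated one.

## Synthetic cohort generator

The generator exists so that every stage can be validated by parameter
recovery. It emulates: the block structure and timings above; correctness
following a configurable order-k kernel (all 2^k history probabilities
explicit); RTs Gaussian (truncated at 1 ms) around an environment baseline
with additive shifts keyed by the window of recent outcomes *ending at the
current trial*, a per-participant offset (SD 20 ms), an optional gender
shift, and anticipatory contamination: with probability 0.02 a trial's RT
is replaced by a uniform draw on (100, 200) ms, purely to exercise the
filter. Block-start histories are padded with "correct" by default (no
burn-in is defined in the reference procedure); a burn-in mode discards a
short simulated warm-up instead. RNG streams derive from
(seed, participant, environment) only, so cohorts are bit-reproducible and
invariant to generation order.

### Default study conditions and the masked-shift design

The defaults give the three environments true orders 0, 1 and 2:

| environment | accuracy kernel | baseline (ms) | RT history shift |
|---|---|---|---|
| 2D | i.i.d., P(V) = 0.93 | 450 | −35 ms when current answer correct |
| 3D | order 1: P(V\|F) = 0.95, P(V\|V) = 0.78 | 520 | masked, depth 1 (−16, −94 ms on lags 0, 1) |
| AR | order 2: P(V\|FF) = 0.95, P(V\|FV) = 0.80, P(V\|VF) = 0.88, P(V\|VV) = 0.68 | 620 | masked, depth 2 (−20, −34, −177 ms on lags 0, 1, 2) |

Women respond 40 ms faster in 3D only; coffee and mood carry no effect;
noise SD is 70 ms. Two deliberate departures from surface realism:

* **Kernel probabilities sit well below ceiling.** Near-ceiling accuracy
  would leave error histories (F, FF) with a handful of observations per
  cohort, making both the transition tables and the history ANOVAs
  unestimable at 22 × 120 trials. The kernels trade accuracy realism for
  identifiable sequential structure.
* **History shifts are masked (suppression-designed).** The order rule can
  only assign order q ≥ 1 if every smaller nested model *fails*, which
  requires the marginal (omitted-variable) association of each lag < q with
  RT to vanish while its partial effect remains. `masked_history_shift`
  solves the linear coefficients on lags 0..q against the kernel's
  stationary covariance (computed exactly from the history chain's
  stationary distribution) so that all sub-model marginals are exactly zero,
  then scales the smallest coefficient to a target effect (16–20 ms,
  i.e. t ≈ 4.4–5 at pooled cohort size — power ≈ 0.99 per partial test).
  This is not an artefact of convenience: the same signature appears in the
  reference data, where the current outcome is non-significant in the
  1-state model yet strongly significant in larger models, and the "answer"
  cofactor is significant only in 2D. The generator reproduces both
  patterns for the same structural reason.

With exact masking, each masked level's test is calibrated at the nominal
α, so the per-environment probability of recovering the true order is
bounded by (1 − α) per masked sub-model: ≈ 0.95 for 3D and ≈ 0.94 for AR in
the infinite-data limit. Recovery is therefore asserted per environment
(≥ 90/100 replicates each; measured 100/95/96 at design time), not as a
joint triple, whose ceiling (~0.89) no generator satisfying the rule's
logic can exceed.

### What the generator does not emulate

Stationarity is assumed: no within-block learning or fatigue drift (the
reference observations of improvement over time in AR have no published
generative form). Mood is a 3-level ordinal placeholder; its real
measurement scale is unknown. Anticipatory trials keep their kernel-drawn
correctness — only the RT is replaced. RT distributions are exactly
Gaussian, so passing normality calibration says nothing about how the
Shapiro–Wilk test behaves on genuinely skewed empirical RTs. Consequently,
green tests demonstrate estimator correctness and calibration under the
stated generative assumptions, not fidelity to any particular empirical
dataset.

## Decision-process extension

`MDPSpec` validates a finite MDP (row-stochastic kernel to 1e-9, rewards
defaulting to 0) with discount γ ∈ [0, 1) and learning term μ ≥ 0. The
backup implemented is

    V(s) = max_a Σ_{s'} T(s,a,s') [ R(s,a,s') + (γ + μ) V(s') ]

i.e. the learning term is read as an additional discount-like weight on the
successor value. The written form of the augmented backup omits the
expectation over successors and any discount on V; since no numerical value
constrains it, the reading that (a) restores the expectation, (b) is
consistent with the μ = γ² truncated n-step special case, and (c) reduces
to classical value iteration at μ = 0 was adopted, and is isolated in a
single `_backup` function so alternatives can be swapped in. γ + μ < 1 is
enforced at construction — the backup is then a (γ+μ)-contraction — and the
solver sweeps states in sorted order, stopping when the contraction bound
(γ+μ)·Δ/(1−(γ+μ)) falls below the tolerance (default 1e-8 sup-norm), so
reported values are within tolerance of the true fixed point, not merely of
the last sweep. Greedy policies break exact ties toward the lowest action
index. History-conditioned policies π(aₙ | sₙ, …, sₙ₋ₕ₊₁) come from
augmenting states to h-tuples (full tuple product, |S|^h states) and
re-running the same solver; h = 1 reproduces the original MDP up to
relabelling.

## Numerical and validation choices

* Validation problem sizes: parameter recovery and order recovery use 100
  replicate cohorts at full study size (22 × 120 per environment); ANOVA
  type-I calibration uses 200 single-environment null cohorts; the
  brute-force transition oracle uses 100 random sequences of length ≤ 60;
  convergence oracles use 10⁴ plain sweeps. These sizes make the whole
  suite run in about a minute on one core.
* Degenerate inputs raise typed errors (`ConfigurationError`, `DataError`,
  `SequenceTooShortError`, `DegenerateSampleError`,
  `DegenerateDesignError`, `NonContractionError`) rather than returning
  empty results.
* Reports serialise with sorted keys and no timestamps; the same config and
  seed produce byte-identical JSON. Provenance carries the config hash,
  seed and package version.
* DOT export writes one node per history and one out-edge per defined
  outcome, labelled to 3 decimals; undefined histories are logged and
  skipped.

## Known limitations

* The stitched (default) chain mode slightly biases transition estimates
  when the filter removes trials; use `break_at_gaps=True` when unbiased
  conditionals matter more than window count.
* The prior-state ANOVA treats pooled trials as exchangeable apart from the
  modelled factors; residual autocorrelation induced by history-dependent
  RT shifts is ignored (its measured effect on masked-level calibration at
  study size is below 1%).
* The masked-shift solver assumes stationarity of the accuracy kernel;
  the first few trials of a block (padded history) deviate negligibly for
  mixing kernels but the masking is not exact for strongly persistent ones.
* Order assignment inherits the rule's own ceiling: even a perfectly
  specified cohort is mis-assigned with probability ≈ α per masked
  sub-model.
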