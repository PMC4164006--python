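# Methods

This note documents the statistical procedures implemented in `beelearn`,
the assumptions behind them, the defaults and why they were chosen, and what
the validation on synthetic data does and does not establish.

## Data model

The universal input is a binary conditioned-response (CR) matrix: `N` animals
by `K` trials, entries `x_t ∈ {0, 1}`, with a role per trial —
`conditioning` (rewarded CS–US pairing), `cs_only` (unrewarded CS during
training) or `retention` (unrewarded CS memory test, after all conditioning
trials). Trial indices are 1-based everywhere in the interface, matching the
convention in which the response on trial `t` reflects the learning induced
by trials `1..t-1`. Optional fields: per-response durations in seconds
(recorded only where the response occurred; absence is an explicit missing
marker, never 0), and a per-animal gustatory response score (GRS, an integer
0–10 measure of sucrose responsiveness taken before conditioning).

Animals that respond to the very first CS — before any pairing — are kept in
the data model ("spontaneous responders") and removed only by an explicit
filter; model fitting excludes them by default because a trial-1 response has
probability zero under the model's initial condition, while the descriptive
statistics operate on whatever matrix they are given.

## Three individual-learning parameters

The group-average learning curve (fraction of animals responding per trial)
confounds three attributes of individual behaviour, which the package
computes separately:

1. **Non-responder fraction** — animals with no CR in any included trial.
2. **First-response latency** `t_firstCR` — the 1-based trial of the first
   CR; its mean is taken over responders only, since non-responders have no
   latency and are reported in their own column.
3. **CR stability** — for the subgroup of animals with `t_firstCR = j`, the
   conditional probabilities `p(x_t = 1 | t_firstCR = j)` are computed for
   every later trial `t > j`; the subgroup stability is their unweighted mean
   over `t`, and the overall stability is the subgroup-size-weighted mean
   across subgroups. Pooling animal-trials across trials first would weight
   early subgroups by their longer tails; the per-trial-first, then
   size-weighted convention is used instead. Non-responders and animals whose
   first CR falls on the last included trial have no `t > j` and do not
   contribute.

By default the stability analysis includes the retention trial
(`include_retention=True`); a conditioning-only view is a flag because
summary tables computed on the training phase alone can differ.

## Learning-curve regression and its decomposition

Average CR probabilities across trials are fitted by least squares with

    p(t) = a · (1 − e^{−b (t − 1)}) + c · (t − 1)

(amplitude `a ∈ [0,1]`, rate `b ∈ [0,10]` per trial, linear slope
`c ∈ [−1,1]`). Both terms vanish at `t = 1`, so the curve is structurally 0
on the first trial. The fit uses conditioning trials only by default (the
curve maximum is a training-phase quantity); fitting through the retention
point is a flag.

The fit is a deterministic bounded multi-start: trust-region least squares
(`scipy.optimize.least_squares`, `trf`) from a coarse 5×5×5 grid of starts
over the parameter box, lowest SSE wins, ties broken toward the smallest
`(b, |c|, a)`. The raw grid starts themselves are kept in the candidate pool:
the trust-region solver nudges boundary starts into the interior, which would
otherwise lose exact degenerate optima such as the canonical `(0, 0, 0)`
solution for flat all-zero data.

The curve's second derivative is `−a b² e^{−b(t−1)} ≤ 0`, so the maximum over
the trial range is either the closed-form stationary point
`t* = 1 + ln(a b / −c) / b` (when `c < 0` and `t*` is interior) or a range
boundary. `p_max = p(t_max)`. A dense-grid-plus-refinement numerical oracle
(`curve_max_bruteforce`) exists purely for validation.

The decomposition check compares the fitted maximum with

    p_max ≈ CR_stability · (1 − N_nonresponders / N),

both sides computed under the same retention-inclusion scope. The relation
expresses that the "asymptote of learning" of a group curve is the fraction
of responding animals modulated by how reliably they respond, not a
performance asymptote of any individual. On two-component simulations (25%
non-learners, learners at `(α, λ) = (0.6, 0.9)`, N = 400, 8 trials) the
absolute error is ≈ 0.02 on average and below 0.05 in 20 of 20 replicates.

## Homogeneous Rescorla–Wagner model

Associative strength follows `v_{t+1} = v_t + α (λ − v_t)` with
`α, λ ∈ [0, 1]` and `v_1 = 0` (no prior associative strength; the initial
condition also makes a trial-1 response impossible, which is why spontaneous
responders are excluded from fits by default). The CR probability on trial
`t` is read linearly as `v_t` — the strength accrued before that trial's
update. Unrewarded trials (CS-only, retention) read out the current strength
without updating it: retention is treated as a constant continuation of
training-phase behaviour, with no extinction term. With all trials rewarded
the recursion has the closed form `v_t = λ (1 − (1−α)^{t−1})`, which the
iterative implementation matches to 1e−12.

The dataset likelihood is the product of independent Bernoulli terms; since
all animals share one `(α, λ)`, it reduces to per-trial response counts.
Fitting is a grid search over `[0,1]²` at spacing 0.1 for the start, followed
by bounded L-BFGS-B refinement. During optimisation the per-trial
probabilities are clamped to `[ε, 1−ε]` with `ε = 1e−9`, because exact 0/1
probabilities produce infinite objective values that break gradient steps;
the reported final NLL is exact (unclamped) and may be `+inf` if genuinely
impossible observations remain. Degenerate optimum families (e.g. all-zero
data, optimal along both axes) are reported at the lexicographically smallest
`(α, λ)` grid point for determinism, and the refined result is never allowed
to be worse than its grid start.

Parameter recovery at the package's reference conditions (N = 500, 6 trials,
truth `(0.4, 0.9)`, 20 replicates) gives mean absolute errors ≈ 0.02 for both
parameters.

## Heterogeneous model

For each animal the likelihood of its response sequence is evaluated on an
11×11 grid over `(α, λ)` (spacing 0.1, endpoints included — degenerate
non-learner parameters live exactly on the axes). Surfaces are accumulated in
log space and exponentiated at the end, so long sequences do not underflow.
Summing surfaces over animals gives the population distribution `P(α, λ)`.
Two normalisations are provided: division by the number of animals (the
reporting convention; each grid value is then an average likelihood in
`[0, 1]`, but the grid total is not 1) and division by the grid total
(`grid_sum`), which makes the distribution a proper probability mass. The
`grid_sum` form is mandatory wherever the distribution acts as mixture
weights: the mixture log-likelihood of a sequence is
`ln Σ mass(α,λ) · L(x | α,λ)` (computed with log-sum-exp), and the
model-implied group curve is the mass-weighted mixture of trajectories,
which is monotone non-decreasing because every component trajectory is.

Per-animal surfaces are *not* individually normalised before summation
(they are likelihoods, not posteriors); whether to do so is a genuinely open
choice, and the unnormalised-sum convention was adopted because it keeps the
per-animal contribution interpretable as an average likelihood.

## Model comparison by cross-validation

`crossval_compare` runs k-fold (default 4) cross-validation: per fold, the
homogeneous model is fitted by maximum likelihood on the training animals and
the heterogeneous model is the `grid_sum` population distribution of the
training animals; both are scored by the total negative log-likelihood of
the held-out animals (homogeneous: Bernoulli product at the fitted point;
heterogeneous: mixture likelihood). Held-out scoring uses the same
`ε = 1e−9` clamp for both models so a single boundary probability cannot
produce an infinite score. Folds are unstratified random partitions with
sizes differing by at most one, deterministic under the seed; spontaneous
responders are excluded before splitting. The lower total wins; exact ties
go to the homogeneous model (parsimony). The score table accumulates win
flags across datasets.

On two-component data (30% non-learners, learners `(0.7, 0.95)`, N = 100,
6 trials) the heterogeneous model wins in 10/10 seeds; on the trial-wise
permuted surrogates of the same datasets the homogeneous model wins in
10/10 — the double dissociation that motivates the heterogeneous extension.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes: each
animal has its own `(α, λ)`; given those, responses are independent
Bernoulli draws with probability `v_t`. Serial dependence, first-response
latency spread and the non-responder mass all emerge from parameter
heterogeneity, not from an autocorrelated noise process. Population kinds:
a single point; a two-component mixture (non-learners drawn as `λ = 0` with
`α ~ U[0,1]` — the data cannot distinguish a zero asymptote from a zero
learning rate, and `λ = 0` was fixed as the convention); independent Beta
laws per parameter; or an explicit grid distribution. Protocols: fixed
trial count with optional retention trial (read out at the post-training
strength `v_{T+1}`, no update), or the adaptive stop-at-first-CR protocol
that yields histories `01, 001, …, 00…0` whose frequencies follow the
first-passage law `P(t_first = j) = v_j · Π_{k<j} (1 − v_k)`.

Durations, where requested, are shifted-geometric on `{1, 2, …}` seconds
(1-s resolution, mean as given; an optional negative-binomial shape
parameter tightens the dispersion), and the GRS covariate is
`round(10·λ + noise)` clamped to `[0, 10]`. Both links are deliberately
simple: they exercise the duration-based discrimination index and GRS
subgrouping and claim no physiological fidelity.

What passing tests on these simulations does **not** show: real conditioning
data have within-animal dependences beyond parameter heterogeneity
(satiation, sensitisation, US habituation under massed trials), drifting
motivation across a session, and non-random sample composition; none of
these are generated, so agreement on synthetic data validates the estimators
under the model's own assumptions, not the model against biology.

## Numerical and design choices

- Probability clamp `ε = 1e−9` for optimisation and held-out scoring; exact
  (unclamped) values for reported final likelihoods.
- Grid spacing 0.1 (11×11) by default; halving the spacing changes the
  dataset mixture NLL of random datasets by < 2%. Populations with a sharp
  off-grid mode can shift more when the refined grid lands on the mode —
  that is grid/mode alignment, not numerical error.
- All randomness flows through `numpy.random.default_rng` (PCG64); every
  generator and the permutation surrogate are bit-reproducible given
  (inputs, seed). Permutation shuffles columns left-to-right with a single
  generator stream.
- CSV dialect is fixed (comma, UTF-8, `.` decimal, LF) with trial roles in
  the header (`t1:cond, …, tK:retention`), metadata in one `#meta` JSON
  comment line, and durations in a sidecar file; writes are byte-stable and
  reads round-trip exactly.
- Degenerate inputs: empty subgroups and undefined statistics raise explicit
  signals (`EmptySubgroupError`, undefined stability as `None`) rather than
  returning 0; an all-zero dataset reports non-responder fraction 1 and
  undefined stability.

## Validation problem sizes

The test suite and the acceptance script validate at: 1000 random parameter
draws for the trajectory closed form; exhaustive sequence enumeration up to
6 trials for likelihood normalisation; 20 replicates of N = 500 for
homogeneous recovery; 20 replicates of N = 400, 8 trials for the
decomposition; 10 datasets of N = 100 (plus their permuted surrogates) for
cross-validated model selection; N = 2000 for the first-response law; 100
random matrices for permutation conservation; and 200 random parameter draws
against the dense-grid curve-maximum oracle. These sizes give comfortable
statistical resolution for the assertions made while keeping a full run in
well under a minute.

## Known limitations

- Single-CS absolute conditioning only; no CS-compound, blocking or
  differential-conditioning (CS−) dynamics.
- No extinction: unrewarded presentations never decrease `v`.
- The heterogeneous model is grid-based by construction; no continuous
  density estimation over `(α, λ)`.
- No confidence intervals on the learning-curve parameters; the regression
  is a descriptive summary.
- Standard inferential tests (χ², Mann–Whitney, ANOVA) are out of scope; the
  reports expose the counts and tables from which any statistics package can
  compute them.
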