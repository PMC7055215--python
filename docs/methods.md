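# Methods

## Scope

`kirbyhorizon` implements the analysis chain of an individual-differences
study linking temporal discounting to explore–exploit behaviour: scoring of
the 27-item monetary choice questionnaire into hyperbolic discount rates,
model-free and model-based quantification of directed and random exploration
on the Horizon Task, the statistics that relate the two, and a synthetic
cohort generator so every stage is exercisable end-to-end without any
subject data.

## Discounting: hyperbolic scoring of the 27-item questionnaire

Each item offers an immediate amount against a larger delayed amount. Under
hyperbolic discounting the delayed amount A after D days is worth
V = A/(1 + kD), with k (day⁻¹) the subject's discount rate. Each item
therefore defines an *indifference rate* k* = (A/V − 1)/D at which the two
offers are equal; a subject with k > k* should take the immediate option.

Scoring assigns, to any item set, the rate most consistent with the observed
choices. Candidate rates are the geometric means of adjacent distinct item
indifference rates plus the ladder endpoints; the consistency of a candidate
is the fraction of items whose response matches "today iff candidate ≥ item
rate" (at exact equality either response counts as consistent — a respondent
sitting exactly at an item's indifference point is not penalised for either
choice). Ties between equally consistent candidates are resolved by their
geometric mean, matching the published spreadsheet convention for this
instrument. Six measures result: overall k (27 items), small/medium/large-
bin k (9 items each, bins defined by the delayed amount), their geometric
mean, and the raw count of "today" choices.

**Ladder endpoints.** `K_FLOOR` and `K_CEIL` are the exact minimum and
maximum indifference rates of the packaged instrument, (35/34 − 1)/186 ≈
1.5813 × 10⁻⁴ and (55/20 − 1)/7 = 0.25 day⁻¹. The conventional printed
endpoints (0.00016, 0.25) are the rounded versions of these; using the exact
values (rather than the 2-significant-figure rounding of the floor) is what
makes a fully patient responder perfectly consistent at the floor.
All internal logs are natural; the correlation layer reports log₁₀ k, the
scale conventional for this instrument's group tables.

Partial profiles are rejected by default with the missing item indices
named; a permissive mode scores the answered items only and flags the
result (`complete=False`).

## Horizon Task: model-free measures

Games are two-armed Gaussian bandits (reward SD fixed at 8 points). Four
forced choices open each game, either [1 3] (one arm shown once — the
*high-information* arm) or [2 2], followed by 1 (horizon 1) or 6
(horizon 6) free choices. All measures use the first free choice:

- p(high info), [1 3] games: probability of picking the once-played arm;
- p(low mean), [2 2] games: probability of picking the generatively worse
  arm;
- accuracy: probability of picking the generatively better arm (all games);
- directed exploration = Δp(high info) across horizons; random exploration
  = Δp(low mean).

"Low mean"/"better" are judged against the *generative* means carried in
the trial log, not the forced-trial sample means; games with tied generative
means drop out of those denominators. This matches the task's design, in
which one arm is always better on average, and makes the flags independent
of forced-trial sampling noise. Reaction times are the raw first-free-choice
latencies, untrimmed. Games with no free choices are dropped with a logged
count; an empty horizon-condition cell leaves the affected fields NaN with
a named warning.

## Horizon Task: logistic choice model

The model-based counterparts are the parameters of a logistic model of the
first free choice,

    p(right) = 1 / (1 + exp(−(ΔR + A·ΔI + b) / σ)),

with ΔR the observed forced-trial mean reward difference (right − left,
points), ΔI ∈ {−1, 0, +1} flagging whether the right arm is the
once-played one (0 in [2 2] games), A the information bonus (points), b a
rightward spatial bias (points) and σ > 0 the decision noise (softmax
temperature, points). The ±1 coding of ΔI means A is expressed directly in
reward points. The model is fit independently per subject and horizon by
maximum likelihood, pooling both information conditions. This single-level,
single-logistic form is a reconstruction of the first-free-choice model
standard for this task; hierarchical pooling and models of later free
choices are out of scope.

**Optimisation.** Bounded L-BFGS-B over (A, b, log σ) with A, b ∈ [−80, 80]
and σ ∈ [0.1, 200]; 10 multi-starts (Latin-hypercube over the box, plus one
anchored neutral start at A = b = 0, σ = 8); likelihood ties resolve toward
the smaller |A|. Fits report the NLL, a convergence flag, the game count,
and a boundary flag (estimate at a bound, or degenerate all-same choices,
for which the bias direction is unidentified). Tests hold every fit to the
standard of a 21³ grid search over the same box. At least 20 first free
choices are required per fit.

**Identifiability.** σ is well identified when it is comparable to the
reward gaps (≲ 20 points); at large σ the likelihood flattens (all choice
probabilities near 0.5) and fitted σ acquires a heavy tail. The coherence
property (fitted A and σ horizon differences tracking directed/random
exploration with r > 0.7) is therefore demonstrated on a moderate-noise
population (σ means 10/16, CV 0.5, 100 games per cell); at the default
calibration below, whose large noise tail is needed to reproduce the
group-level p(low mean), the raw-σ coherence degrades to r ≈ 0.6 for this
identifiability reason, not because of a defect in either estimator.

## Synthetic cohorts

Subjects carry five latent traits — log k, information bonus per horizon,
log decision noise per horizon — drawn from a multivariate Gaussian copula
(correlations imposed on the latent scale, since k and σ are log-normal-
like), plus an independent side bias ~ N(0, 3 points). Questionnaire
responses follow a softmax of (immediate − V) with temperature 2 dollars by
default (0 gives the deterministic responder, with exact indifference
resolving to the immediate offer). Games draw one generative mean uniform
on [40, 60], offset the other by ±{4, 8, 12, 20, 30} points, balance forced
patterns over sides, and sample all free choices from the logistic rule
(horizon-6 trials beyond the first reapply it to the running observed
means and play counts — there is no learning model). Reaction times are
log-normal nuisance draws carrying no signal. A single seeded generator
stream drives every draw; the same seed reproduces a study byte-for-byte.
The default of 32 games per horizon×condition cell is an assumption exposed
in the configuration.

**Calibration.** Default trait distributions were chosen once so that the
expected group means of the four first-free-choice measures match the
reference values 0.5146 / 0.5486 (p(high info) h1/h6) and 0.2883 / 0.3554
(p(low mean) h1/h6): information bonus ~ N(1.6, 12.3²) and N(6.3, 16.3²)
points; decision noise log-normal with natural-scale mean/SD 20/20 and
38/38 points; log k ~ N(−4.157, 1.15²) (moment-matched to a reported
overall-k mean 0.0303 and SD 0.0503). Bonus dispersions reproduce the
reference trait SDs of p(high info) (≈ 0.145). The default latent
correlation matrix carries the reference discounting–exploration structure
(log k with bonus h1 +0.35, bonus h6 −0.01, log noise h1/h6 +0.22/+0.27)
with within-pair correlations (bonus 0.487, log noise 0.219) set so the
implied latent correlations of log k with the bonus and log-noise horizon
differences are −0.30 and +0.04.

**What the generator does not emulate.** (1) The attainable trait-level SD
of p(low mean) under a log-normal noise distribution is ≈ 0.12, below the
reference 0.176 (which includes binomial sampling noise); matching it more
closely requires an extreme bimodal noise distribution that destroys the
information-bonus signal. Noise dispersion is fixed at CV = 1 as the
compromise. (2) Finite game counts attenuate correlations between latent
traits and measured probabilities: with 32 games per cell, a configured
latent correlation of 0.35 between log k and the h1 bonus is recovered by
the plain-Pearson pipeline as ≈ 0.26–0.28 at n = 1000. Directed (−0.30)
and random (+0.04) recoveries land within ±0.08 of their configured values;
the h1 bonus cell sits at its band edge, and a passing test on synthetic
data should accordingly not be read as a statement about real-data effect
sizes. (3) No within-game learning, payment lotteries, or session effects.

## Statistics

Paired horizon contrasts use the dependent-samples t (two-tailed p on n − 1
df), computable from raw vectors or from summary statistics (the two agree
identically). Effect sizes are reported both as d_av = mean difference /
RMS of the two condition SDs — the variant that reproduces conventional
printed values for this design — and d_z = mean difference / SD of
differences. Identical pairs define t = 0 (flagged degenerate).

The correlation layer computes a 6 × 10 Pearson grid (log₁₀ k measures and
today-count × task measures) on pairwise-complete observations, two-tailed
p from the t transform of r, cells with fewer than 4 pairs marked missing.
No multiple-testing correction is applied by default; a Bonferroni column
is available but off.

The sample-size helper inverts the Fisher-z power approximation,
n = ⌈((z_α + z_β)/atanh r)² + 3⌉, floored at 4. At r = 0.3, α = 0.05,
power = 0.8 (two-tailed) it gives 85; software using exact noncentral
distributions reports slightly smaller values (e.g. 82), a known gap of the
z approximation that this package documents rather than forces into
agreement.

## Numerical choices and problem sizes

Log-likelihoods use `log_expit` for stability; choice probabilities are
never exactly 0 or 1. Consistency comparisons use exact ≥/≤ so equality at
a ladder rung counts for either response. Test problem sizes: recovery
grids use 400 games per horizon; the end-to-end correlation recovery 1,000
subjects; the type-I calibration 5,000 subjects with an identity trait
copula; questionnaire recovery 500 deterministic responders. The CLI and
all writers stamp outputs with the package version, seed and a
configuration hash.
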