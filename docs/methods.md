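# Methods

## The tie-fitness model

The core object is a dyadic logit fitted per network wave.  For ordered
dyad (i, j) with wave adjacency R:

    logit p(e_ij) = α + β_sex·same_sex + β_eth·same_eth + β_ses·same_ses
                  + β_status·x1 + β_clust·x2 + β_rec·x3 (+ ε_S[i] + ε_R[j])

* `x1 = z(log(C_ij + 1))`, `C_ij = indeg(j) − R[i, j]`.  Excluding ego's own
  nomination keeps the covariate free of the focal outcome, so the tie never
  predicts itself.
* `x2 = z(log(TP_ij + 1))`, with `TP = R̄²` and `R̄` the elementwise OR of R
  and its transpose (diagonal zeroed).  TP is symmetric by construction.
* `x3 = R[j, i]`.

Z-scores are taken over all n(n−1) ordered dyads of the wave, **after** the
log transform (the formula order), using the population standard deviation;
the scale convention is immaterial to percentile-rank fitness but fixed for
reproducibility.  A constant raw column z-scores to all zeros with a logged
warning.

The default fit is a plain maximum-likelihood logit (statsmodels GLM/IRLS).
This is a pseudo-likelihood under tie dependence: standard errors are
anti-conservative and deliberately not surfaced — the model's job is point
prediction and ranking.  Crossed sender/receiver intercepts are available
as an option (`random_effects=True`): they are estimated by alternating
ridge-penalized Newton updates per node, with the ridge weight set to the
inverse of the current moment estimate of the intercept variance (floored
at 1e-4) and the intercept means absorbed into the constant each sweep.
This is a MAP/PQL-style scheme chosen for determinism and speed; only the
predictive contract (finite, mean-zero effects entering the linear
predictor) is guaranteed.  Perfect separation is detected by exact outcome
prediction or runaway coefficients (|β| > 50 on z-scored covariates) and
reported with the offending covariate.

**Fitness** is the percentile rank of the predicted probability within the
wave: `f = (rank − 1)/(N − 1)` with average ranks for ties, so min f = 0,
max f = 1, and mean f = 0.5 absent ties.  Fitness is computed per
network-wave independently and is invariant to any strictly monotone
transform of the probabilities.  If all probabilities are identical there
is no ranking information; all dyads get f = 0.5 with a warning.

**Threshold calibration** pools the fitness values of reported ties across
networks and picks the largest observed value f\* whose at-or-above share
still reaches the retrieval target (default 0.90).  Read from the top this
is "the share of reported ties with f ≥ f\* is ≥ 90%"; it coincides with
the 10th percentile from below of reported-tie fitness.  With distinct
fitness values the achieved retrieval overshoots the target by less than
one reported-tie weight; heavy ties in f can overshoot more (the guarantee
is only exercised on continuous surfaces).

## The synthetic cohort generator

The generator emulates school-cohort nomination panels: n = 240 students
(configurable), 7 waves by default, sex balanced 50/50, an 85% ethnic
majority, half the students SES-high, i.i.d. per-wave participation with 5%
attrition, and a target mean outdegree of 6 named friends (nomination
instruments typically cap at a handful of names; the emulated studies do
not publish this figure, so 6 is the package's choice).  Ground-truth
coefficients default to empirically plausible magnitudes: sex homophily
declining linearly 2.1 → 0.9 across waves, ethnicity and SES homophily 0.2,
reciprocity 2.9, status 0.5, clustering 0.7.

Waves are drawn from the same logit family the estimator fits, by
sequential dyad updates:

* **Pair-block Gibbs.**  Each sweep visits unordered pairs {i, j} once and
  draws (y_ij, y_ji) jointly from the 4-state distribution implied by the
  two directed conditionals with the reciprocity interaction,
  P(y_ij, y_ji | rest) ∝ exp(a_ij·y_ij + a_ji·y_ji + β_rec·y_ij·y_ji).
  Sampling the pair as a block makes the reciprocity term exact — a
  one-directed-edge-at-a-time scan leaves whichever direction is visited
  first conditioned on a stale reverse edge, which measurably attenuates
  recovered reciprocity and contaminates the homophily terms.
* **Frozen standardization.**  Within a wave, the z-scoring constants of
  x1/x2 are frozen at the initializing state (the previous wave, or a
  sex-homophilous random graph at target density for wave 1) while the raw
  covariate *values* are updated incrementally after every toggled edge.
  Re-standardizing against the moving state is catastrophically unstable:
  when the graph drifts sparse the covariate SDs shrink and the effective
  feedback coefficients explode — the degeneracy this model family is known
  for.
* **Density tuning.**  The constant is tuned by bisection on the realized
  mean outdegree until it is within 10% of the target, starting from the
  closed-form independence approximation and reusing the same uniform draws
  across evaluations so realized density is (near-)monotone in the
  constant.  Because strong reciprocity/clustering feedback makes realized
  density jump discontinuously for some draw sequences, tuning retries with
  fresh draws a bounded number of times before raising a convergence error.
* **One sweep per wave.**  A wave is one sweep from its predecessor, a
  deliberate *transient*: with these coefficient magnitudes the chain run
  to stationarity is bistable (near-empty vs. near-complete), and the
  interesting regime — realistic density with strong norms — exists only as
  a density-controlled snapshot, which is also what panel waves are.
  `CohortConfig.n_sweeps` exposes the choice.

Quality flags are synthesis conveniences, not estimated quantities: the top
20% of each ego's reported ties by linear predictor (at least one) are
flagged best friends, and meeting frequency bins the tie's linear predictor
into within-wave quintiles.  They exist so the quality-covariate outcome
models are exercisable.

**Recovery protocol.**  Parameter recovery is evaluated by fitting wave T4
of 4-wave, attrition-free cohorts generated under constant ground truth:
the first wave starts from a seed graph with no configurational structure
and a single transient sweep is still far from the conditional law (biases
up to ±0.3), while by waves 3–4 the chained, density-controlled snapshots
are close to it (all |bias| ≤ ~0.13 over 20 cohorts at n = 240).
Attrition is disabled for this study because the *reported* matrix zeroes
the rows of non-participating egos, censoring reciprocation and biasing
β_rec by about −0.36.  Both choices are study-design parts of the recovery
claim.

**What the generator does not emulate:** sender/receiver degree
heterogeneity beyond the modelled covariates (no random effects in the
generating process), classroom/activity foci, alter-side item
non-response, multiple settings with distinct norm profiles, and any
calibration to non-published empirical marginals.  Tests passing on these
cohorts show the *machinery* is correct under the stated model, not that
the model describes any particular real school.

## Outcome models

The dyad-wave table holds one record per ordered dyad per wave T1..T−1,
restricted to dyads whose ego participated at both the current and next
wave (otherwise the tie's future is unobserved); fitness itself is always
computed on the complete network.  Outcomes: `is_reported` (logit, all
records), `will_form` (logit, unreported records), `survival` (logit,
reported records), `longevity` (count of strictly future waves reported;
Poisson with log link — the simplest count GLM, chosen over alternatives
because only the conditional-mean curve is consumed).  Survival and
longevity models add quality covariates (times reported in strictly past
waves, best-friend flag, meeting-frequency dummies with the lowest level
as reference); all models carry wave dummies (first wave reference) and
setting dummies when settings are pooled.  Variances are dyad-clustered
sandwich estimates, since dyads repeat across waves; with singleton
clusters the uncorrected sandwich reduces exactly to HC0.
Marginal-effect curves evaluate the inverse link on a fitness grid with
quality covariates at baseline and wave/setting dummies at the modal
category.

## Dormant ties and niches

A dyad is *fit* when f ≥ f\*; dormant ties are fit, unreported dyads; the
two sets partition the fit dyads against the reported fit ties.  The
accounting helper rounds `fit_share × n(n−1)` to the fit-dyad count (100
students at a 17% share → 1,683) and reports the reported share of fit
dyads (368/1,683 = 21.9%).  Note the internal arithmetic of that worked
scenario: 90% of 400 reported ties would be 360, not 368; the accounting
reproduces the printed 368/1,683 = 21.9% figures as given and leaves the
368-vs-360 inconsistency unresolved.

Matrix reordering uses CONCOR-style iterated column correlations on the
symmetrized fit matrix: repeatedly split the largest splittable block by
the sign pattern of the converged correlation matrix, until the requested
block count (or, in auto mode, until blocks stop splitting, reach size
< 4, or 8 blocks exist).  CONCOR is chosen for determinism and its
historical role in social blockmodeling; it is a display ordering, not a
likelihood-based stochastic blockmodel.  Zero-variance columns contribute
zero correlations; a constant matrix yields a single block with a warning.
Block-pair fit densities exclude diagonal cells within blocks; the
within/between clustering ratio is capped at 1e6 when no between-block fit
ties exist.  Cell states for matrix display classify each dyad as
dormant / stable / forming / dissolving / attrited / unfit using the next
wave and ego's participation there.

## The agent-based model

Agents carry one of five identity profiles weighting (x1, x2, x3, same-sex,
same-eth, same-SES): conformist = the fitted coefficients; status-seeker =
(+1, 0, β_rec, 0, 0, 0); group-oriented = (−1, +1, β_rec, 0, 0, 0);
individualist = (−1, −1, β_rec, 0, 0, 0); intrepid = conformist with the
sex weight negated.  Divergent profiles use unit magnitudes on the
z-scored covariates because only preference *directions* are specified;
magnitudes are exposed in the profile objects.  Every profile keeps the
fitted (positive) reciprocity weight.

Utilities split into a static part — x1/x2/homophily terms computed from
the seed network (fixed scenario) — and a dynamic reciprocity term read
from the current relation graph, so "prefers peers who reciprocate"
tracks the simulation itself.  Each iteration: (1) every agent compares
each of its 9 interaction partners against one uniformly drawn alternative
(not self, not already a partner) and switches on strict improvement;
(2) agents send overtures to their top-6 interactions by own utility
(ties broken by partner index) and recipients accept incoming overtures by
their own utility up to 9 — the acceptance rule is symmetric with sending
and swappable, as the original protocol's acceptance detail is
unspecified; (3) relations with f below the threshold (default 0.83) are
eliminated; the updating scenario first recomputes covariates and the
fitness surface from the just-accepted relation graph with frozen
coefficients.  Relations are rebuilt each iteration as the accepted subset
of current overtures — the only reading that keeps the outgoing-capacity
invariant (≤ 6) without an extra eviction rule.  The realized share
divides surviving outgoing relations by the overture capacity (6), an
interpretation of "relative to the simulated capacity".

**Known limitation.**  With a homogeneous fitness surface (no node random
effects), the top-17% fit set concentrates on popular, clustered, same-sex
dyads.  Individualists, whose targets are anti-configurational, then
realize almost nothing (~2% of capacity), falling *below* intrepids
(~12%), who still find occasional well-embedded cross-sex dyads — so the
expected ordering "intrepid last" holds only under near-total sex
segregation (generator sex coefficient ≥ 4, beyond the realistic range;
the package does not adopt that).  Conformists are robustly first in the
fixed scenario.  Heterogeneous (random-effects) fitness surfaces would
spread fit dyads across the popularity spectrum and likely soften the
individualist collapse; this is the main candidate for future work.

## Problem sizes

The test suite and acceptance script use: 20 cohorts × n = 240 × 4 waves
for parameter recovery; 20 cohorts × n = 60 × 4 waves for outcome-model
sign recovery; one n = 240 × 7-wave cohort for threshold calibration and
assortativity trends; 10–20 seed networks × n = 120 × 50 iterations for
the simulation experiments; exhaustive enumeration at n = 3 plus
randomized coverage to n = 5–6 for the combinatorial oracles.  These sizes
were chosen so the whole pipeline reruns from scratch in minutes on one
CPU while keeping Monte-Carlo error well below the tolerances tested.
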