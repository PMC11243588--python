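# netecol

Tie fitness, relational niches, and identity competition in longitudinal
friendship networks.

## The problem

Adolescent friendship networks (and bounded social settings generally) are
shaped by *relational norms*: friendships are reciprocated, they cluster
among mutual acquaintances, they flow toward popular peers, and they stay
within salient categories such as sex, ethnicity and socio-economic status.
`netecol` turns those norms into a dyad-level metric — **tie fitness** — that
quantifies how well any pair of individuals *would* align with their setting
if they became friends, and then uses that metric to study network dynamics:
which ties form, survive, and persist; where unexpressed but viable
("dormant") ties cluster into relational niches; and how agents with
divergent relational preferences fare when competing on the fitness
topology.

It is written for computational social scientists and network
methodologists working with sociometric panel data (directed nomination
rosters observed in waves), and for anyone who wants a fully synthetic,
ground-truth-known testbed for dyadic tie-prediction methods.

## The model

For each network wave with adjacency matrix R, every ordered dyad (i, j) is
scored with a network logit:

```
logit p(e_ij | G_t) = α + β_C · (same-sex, same-ethnicity, same-SES)
                        + β_R · (x1, x2, x3) + ε_S[i] + ε_R[j]
```

where

* `x1 = z(log(C_ij + 1))` — alter's indegree popularity, with C_ij the
  column sum of R excluding any tie from ego i,
* `x2 = z(log(twopaths_ij + 1))` — shared acquaintances, counted in the
  symmetrized adjacency matrix,
* `x3 = Rᵀ[i, j]` — reciprocity,
* ε_S, ε_R — optional crossed sender/receiver intercepts (off by default;
  the model is used for point prediction and ranking, not inference).

Predicted probabilities are rank-normalized per network into the fitness
percentile `f = PR(p) ∈ [0, 1]`. A *fitness threshold* f\* is calibrated so
that a target share (default 90%) of reported relations score f ≥ f\*.
Dyads with f ≥ f\* that are unreported are *dormant ties*; a CONCOR-style
blockmodel reorders the fit-tie matrix to expose relational niches; and an
agent-based model lets five identity profiles (conformist, status-seeker,
group-oriented, individualist, intrepid) compete for relations on the
fitness surface under interaction/overture/acceptance capacities of 9/6/9
and ecological selection at f\*.

Because the empirical school panels the method targets are not public, the
package includes a first-class synthetic generator: cohorts of ~240
students over 7–8 waves drawn from the same logit family with known
coefficients (strong declining sex homophily, strong reciprocity, moderate
status and clustering norms, per-wave attrition), so every pipeline stage
is testable against ground truth.

## Worked example

```python
from netecol import (CohortConfig, TieFitnessModel, accounting,
                     calibrate_threshold, generate_cohort)

cfg = CohortConfig(n=120, n_waves=4, seed=42)
panel, truth = generate_cohort(cfg)

results = TieFitnessModel.from_panel(panel, "T4").fit()
print(results.summary())

reported = []
for wave in panel.wave_labels[:-1]:
    surface = TieFitnessModel.from_panel(panel, wave).fit().fitness()
    reported.append(surface.reported_fitness(panel.wave(wave).edge_set()))
calib = calibrate_threshold(reported, retrieval_target=0.90)
print(f"fitness threshold f* = {calib.threshold:.3f} "
      f"(retrieves {100*calib.achieved_retrieval:.1f}% of reported ties)")

acc = accounting(n=100, n_reported=400, fit_share_of_dyads=0.17,
                 n_fit_reported=368)
print(f"fit dyads: {acc.n_fit_dyads}, dormant: {acc.n_dormant}, "
      f"reported share of fit: {100*acc.reported_share_of_fit:.1f}%")
```

prints

```
Tie fitness network logit
==============================================
observations: 14280   log-likelihood: -1104.1
converged: True   random effects: False
----------------------------------------------
term                coef
sex homophily      0.728
eth homophily      0.122
SES homophily      0.095
reciprocity        3.485
status (indeg)     0.588
clustering         0.638
constant          -5.392
----------------------------------------------
...
fitness threshold f* = 0.784 (retrieves 90.1% of reported ties)
fit dyads: 1683, dormant: 1315, reported share of fit: 21.9%
```

The fitted coefficients track this cohort's wave-4 ground truth (sex
homophily 0.9 after its scripted decline from 2.1, reciprocity 2.9, status
0.5, clustering 0.7) up to single-cohort sampling noise; the 20-cohort
recovery study in `scripts/acceptance.py` puts the mean absolute bias of
every term at or below ~0.13.  The friendship system rewards reciprocation
most, then embedding and same-sex ties.  The
calibrated threshold says 90% of the reported friendships sit in roughly
the top fifth of all possible dyads by fitness; the accounting shows that
in a 100-student population with a 17% fit share, the 368 fit reported ties
cover only 21.9% of the 1,683 fit dyads — the remaining 1,315 dormant ties
are the setting's activation potential.

A command-line interface mirrors the library
(`netecol simulate | fit-fitness | describe | outcomes | niches | abm | run`);
`netecol run --seed 3 --out results/` executes every stage and writes a
checksummed manifest.

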