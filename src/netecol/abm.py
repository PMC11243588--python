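"""Agent-based simulation of identity-differentiated friendship dynamics.

Agents carrying one of five social identities compete on a fitness topology
estimated from a seed network.  Identities differ in how they value potential
partners (weights on indegree popularity, shared acquaintances, reciprocity,
and the three homophily indicators):

* conformist      — the setting's fitted coefficients, all six terms;
* status_seeker   — seeks popular peers, indifferent to clustering;
* group_oriented  — seeks shared acquaintances, avoids popular peers;
* individualist   — avoids both popularity and cliques;
* intrepid        — conformist weights with the sex-homophily weight negated
                    (befriends across the sex boundary).

All identities keep a positive reciprocity weight: everyone prefers partners
who reciprocate.  Each iteration has three stages: (1) every agent compares
each current interaction partner against one randomly drawn alternative and
switches when the alternative is strictly preferred; (2) agents send
relational overtures to their top-valued interaction partners (up to the
overture capacity) and recipients accept incoming overtures in decreasing
order of their own valuation up to the incoming capacity; (3) ecological
selection deletes every accepted relation whose tie fitness falls below the
threshold.  In the *fixed* scenario the fitness surface is the seed network's
and never changes; in the *updating* scenario covariates and the surface are
recomputed from the current relation graph each iteration with frozen
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import build_design, standardize
from .fitness import TieFitnessResults, percentile_rank
from .panel import Panel, adjacency_matrix

IDENTITIES = (
    "conformist",
    "status_seeker",
    "group_oriented",
    "individualist",
    "intrepid",
)

# utility weight order: status (x1), clustering (x2), reciprocity (x3),
# sex-, ethnicity-, SES-homophily
WEIGHT_NAMES = ("x1", "x2", "x3", "same_sex", "same_eth", "same_ses")

__all__ = [
    "IDENTITIES",
    "SimConfig",
    "IdentityProfile",
    "SimState",
    "default_profiles",
    "init",
    "step",
    "run",
    "run_experiment",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation protocol constants.

    Capacities mirror the study protocol: each agent interacts with nine
    peers, makes overtures to six, and accepts up to nine incoming
    friendships; runs last 100 iterations and are repeated 10 times per seed
    network.
    """

    interaction_capacity: int = 9
    overture_capacity: int = 6
    incoming_capacity: int = 9
    iterations: int = 100
    runs: int = 10
    fitness_threshold: float = 0.83
    scenario: str = "fixed"  # or "updating"
    identity_mix: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        if min(self.interaction_capacity, self.overture_capacity,
               self.incoming_capacity) <= 0:
            raise ValueError("capacities must be positive")
        if self.scenario not in ("fixed", "updating"):
            raise ValueError("scenario must be 'fixed' or 'updating'")
        if len(self.identity_mix) != len(IDENTITIES):
            raise ValueError(f"identity_mix needs {len(IDENTITIES)} entries")
        if abs(sum(self.identity_mix) - 1.0) > 1e-9:
            raise ValueError("identity_mix must sum to 1")


@dataclass(frozen=True)
class IdentityProfile:
    """Named relational-preference profile: weights on the six covariates."""

    name: str
    weights: tuple[float, ...]  # order WEIGHT_NAMES

    def __post_init__(self):
        if len(self.weights) != len(WEIGHT_NAMES):
            raise ValueError("profile needs six weights")
        if self.weights[2] <= 0:
            raise ValueError("reciprocity weight must be positive")


def default_profiles(results: TieFitnessResults) -> dict[str, IdentityProfile]:
    """The five identity profiles anchored on a fitted tie-fitness model.

    Conformists use the setting's fitted coefficients verbatim; divergent
    identities use unit magnitudes on the z-scored configurational covariates
    (the model gives only the direction of their preferences).
    """
    b = results.params
    rec = float(b["x3"])
    if rec <= 0:
        raise ValueError("fitted reciprocity coefficient must be positive")
    conf = (float(b["x1"]), float(b["x2"]), rec,
            float(b["same_sex"]), float(b["same_eth"]), float(b["same_ses"]))
    return {
        "conformist": IdentityProfile("conformist", conf),
        "status_seeker": IdentityProfile("status_seeker",
                                         (1.0, 0.0, rec, 0.0, 0.0, 0.0)),
        "group_oriented": IdentityProfile("group_oriented",
                                          (-1.0, 1.0, rec, 0.0, 0.0, 0.0)),
        "individualist": IdentityProfile("individualist",
                                         (-1.0, -1.0, rec, 0.0, 0.0, 0.0)),
        "intrepid": IdentityProfile(
            "intrepid", (conf[0], conf[1], conf[2], -conf[3], conf[4], conf[5])
        ),
    }


@dataclass
class SimState:
    """Mutable simulation state for one run."""

    config: SimConfig
    identities: np.ndarray  # identity index per agent
    interactions: np.ndarray  # (n, interaction_capacity) partner indices
    relations: np.ndarray  # (n, n) int8, i -> j accepted surviving overtures
    fitness: np.ndarray  # (n, n) percentile-rank fitness, NaN diagonal
    results: TieFitnessResults
    attributes: pd.DataFrame
    roster: list[str]
    seed_adjacency: np.ndarray
    static_utility: np.ndarray  # (identities, n, n) utility minus reciprocity term
    rec_weights: np.ndarray  # reciprocity weight per identity
    rng: np.random.Generator
    iteration: int = 0

    @property
    def n(self) -> int:
        return self.identities.size

    def utility_row(self, agent: int) -> np.ndarray:
        """Agent's valuation of every alter under its identity profile,
        including the dynamic reciprocity term from the relation graph."""
        ident = self.identities[agent]
        return (
            self.static_utility[ident, agent]
            + self.rec_weights[ident] * self.relations[:, agent]
        )

    def realized_shares(self) -> pd.DataFrame:
        """Per-identity mean share of realized outgoing relations."""
        out = self.relations.sum(axis=1) / self.config.overture_capacity
        return pd.DataFrame({
            "identity": [IDENTITIES[i] for i in self.identities],
            "share": out,
        }).groupby("identity", sort=False)["share"].mean().reindex(IDENTITIES).to_frame()


def _covariate_stack(R: np.ndarray, attributes: pd.DataFrame,
                     roster: list[str]) -> np.ndarray:
    """(6, n, n) array of the utility covariates computed from graph R.

    x1/x2 are z-scored over the off-diagonal dyads of R (all-zero when the
    raw column is constant), matching the estimation-side standardization.
    """
    design = standardize(build_design(R, attributes, roster=roster))
    n = R.shape[0]
    off = ~np.eye(n, dtype=bool)
    stack = np.zeros((len(WEIGHT_NAMES), n, n))
    for k, name in enumerate(WEIGHT_NAMES):
        stack[k][off] = design.table[name].to_numpy(dtype=float)
    return stack


def _fitness_matrix(results: TieFitnessResults, stack: np.ndarray) -> np.ndarray:
    """Percentile-rank fitness from frozen coefficients on a covariate stack."""
    n = stack.shape[1]
    off = ~np.eye(n, dtype=bool)
    beta = results.params[list(WEIGHT_NAMES)].to_numpy()
    eta = results.constant + np.tensordot(beta, stack, axes=1)
    F = np.full((n, n), np.nan)
    F[off] = percentile_rank(expit(eta[off]))
    return F


def init(panel: Panel, wave: str, results: TieFitnessResults,
         config: SimConfig, rng: np.random.Generator | None = None) -> SimState:
    """Initialize a run on one seed network.

    Identities are drawn i.i.d. from the configured mix; every agent starts
    with ``interaction_capacity`` distinct random partners and an empty
    relation graph.  The fixed scenario caches the seed network's fitness
    surface; the updating scenario recomputes it each iteration from the
    relation graph with the frozen coefficients.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = panel.n
    if n <= config.interaction_capacity:
        raise ValueError("population too small for the interaction capacity")
    R_seed = adjacency_matrix(panel, wave)
    identities = rng.choice(len(IDENTITIES), size=n, p=np.asarray(config.identity_mix))
    interactions = np.empty((n, config.interaction_capacity), dtype=np.int64)
    for i in range(n):
        pool = np.delete(np.arange(n), i)
        interactions[i] = rng.choice(pool, size=config.interaction_capacity,
                                     replace=False)

    profiles = default_profiles(results)
    stack = _covariate_stack(R_seed, panel.attributes, panel.roster)
    weights = np.array([profiles[name].weights for name in IDENTITIES])
    static_stack = stack.copy()
    static_stack[2] = 0.0  # reciprocity handled dynamically
    static_utility = np.tensordot(weights, static_stack, axes=1)
    fitness = _fitness_matrix(results, stack)
    return SimState(
        config=config,
        identities=identities,
        interactions=interactions,
        relations=np.zeros((n, n), dtype=np.int8),
        fitness=fitness,
        results=results,
        attributes=panel.attributes,
        roster=panel.roster,
        seed_adjacency=R_seed,
        static_utility=static_utility,
        rec_weights=weights[:, 2],
        rng=rng,
    )


def step(state: SimState) -> SimState:
    """Advance the simulation by one iteration (in place).

    Stage 1: each agent tests every current interaction against one uniform
    alternative partner and switches on strict improvement.  Stage 2: agents
    send overtures to their top-valued interactions (stable tie-break by
    partner index) and recipients accept by their own valuation up to the
    incoming capacity.  Stage 3: relations below the fitness threshold are
    selected against; in the updating scenario the surface is recomputed from
    the just-formed relation graph first.
    """
    cfg = state.config
    n = state.n
    rng = state.rng

    # stage 1: interaction churn
    for i in range(n):
        row = state.utility_row(i)
        partners = state.interactions[i]
        current = set(partners.tolist())
        for slot in range(cfg.interaction_capacity):
            alt = int(rng.integers(n))
            if alt == i or alt in current:
                continue
            if row[alt] > row[partners[slot]]:
                current.discard(int(partners[slot]))
                current.add(alt)
                partners[slot] = alt

    # stage 2: overtures and acceptance
    overtures = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        row = state.utility_row(i)
        partners = np.sort(state.interactions[i])  # stable index tie-break
        order = np.argsort(-row[partners], kind="stable")
        targets = partners[order[: cfg.overture_capacity]]
        overtures[i, targets] = 1

    accepted = np.zeros((n, n), dtype=np.int8)
    for j in range(n):
        senders = np.nonzero(overtures[:, j])[0]
        if senders.size == 0:
            continue
        row_j = state.utility_row(j)
        order = np.argsort(-row_j[senders], kind="stable")
        keep = senders[order[: cfg.incoming_capacity]]
        accepted[keep, j] = 1

    # stage 3: ecological selection
    if cfg.scenario == "updating":
        stack = _covariate_stack(accepted, state.attributes, state.roster)
        state.fitness = _fitness_matrix(state.results, stack)
    with np.errstate(invalid="ignore"):
        survives = state.fitness >= cfg.fitness_threshold
    state.relations = (accepted & survives).astype(np.int8)
    state.iteration += 1
    return state


def run(state: SimState, iterations: int | None = None) -> pd.DataFrame:
    """Run the simulation, returning the per-identity share trajectory."""
    if iterations is None:
        iterations = state.config.iterations
    rows = []
    for _ in range(iterations):
        step(state)
        shares = state.realized_shares()["share"]
        rows.append({"iteration": state.iteration, **shares.to_dict()})
    return pd.DataFrame(rows).set_index("iteration")


def run_experiment(panels: list[tuple[Panel, str, TieFitnessResults]],
                   config: SimConfig,
                   scenarios: tuple[str, ...] = ("fixed", "updating"),
                   ) -> pd.DataFrame:
    """Full crossing of scenarios x runs x seed networks.

    Returns one row per (scenario, setting, run, identity) with the mean
    realized share at the final iteration.
    """
    if not panels:
        raise ValueError("need at least one seed network")
    from dataclasses import replace

    rows = []
    root = np.random.default_rng(config.seed)
    for scenario in scenarios:
        for panel, wave, results in panels:
            for r in range(config.runs):
                rng = np.random.default_rng(root.integers(2**31))
                cfg = replace(config, scenario=scenario)
                state = init(panel, wave, results, cfg, rng=rng)
                traj = run(state)
                final = traj.iloc[-1]
                for ident in IDENTITIES:
                    rows.append({
                        "scenario": scenario,
                        "setting": panel.setting_id,
                        "wave": wave,
                        "run": r,
                        "identity": ident,
                        "share": float(final[ident]),
                    })
    return pd.DataFrame(rows)
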