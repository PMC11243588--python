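"""Synthetic school-cohort panels with known relational-norm coefficients.

The generator draws longitudinal nomination networks from the same logit
family the estimator fits, so parameter recovery is well-posed: each wave is
produced by sequential (Gibbs-style) dyad updates in which the probability of
ego i nominating alter j is ``logistic`` of the ground-truth linear predictor
on the six covariates (sex/ethnicity/SES homophily, indegree popularity,
two-path clustering, reciprocity).  The constant is tuned by bisection so the
realized mean outdegree hits a target density, emulating cohorts of a few
hundred students surveyed over 7-8 waves with declining sex homophily,
per-wave attrition, and best-friend / meeting-frequency quality flags.

Within a sweep the popularity and clustering covariates are recomputed
incrementally after every toggled edge; their z-scoring constants are frozen
at the state the sweep started from (a moving standardization target would
make the conditional model ill-defined mid-sweep).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .panel import Panel, WaveNetwork

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_attributes",
    "simulate_wave",
    "generate_cohort",
    "ConvergenceError",
]

COEF_COLUMNS = (
    "sex_homophily",
    "ethnicity_homophily",
    "ses_homophily",
    "reciprocity",
    "status",
    "clustering",
    "constant",
)


class ConvergenceError(RuntimeError):
    """Density tuning failed to reach the target within bounded bisection."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for one synthetic cohort.

    Defaults emulate the empirical settings: ~240 students per cohort, seven
    analyzable waves, a dominant ethnic majority, roughly half the students
    SES-high, mild per-wave attrition, and a mean outdegree of six named
    friends (nomination instruments typically cap at a handful of names).
    """

    n: int = 240
    n_waves: int = 7
    majority_share: float = 0.85
    ses_high_share: float = 0.5
    attrition_rate: float = 0.05
    target_mean_outdegree: float = 6.0
    seed: int = 0
    n_sweeps: int = 1  # Gibbs sweeps per wave after initialization

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if self.n_waves < 2:
            raise ValueError("n_waves must be >= 2")
        for name in ("majority_share", "ses_high_share", "attrition_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.target_mean_outdegree <= 0:
            raise ValueError("target_mean_outdegree must be positive")


@dataclass
class GroundTruth:
    """Per-wave logit-scale coefficients the generator commits to.

    ``constant`` may be NaN on input; it is then tuned per wave to the target
    density and the tuned value recorded on the returned copy.
    """

    coefficients: pd.DataFrame  # one row per wave, columns COEF_COLUMNS

    def __post_init__(self):
        missing = set(COEF_COLUMNS) - set(self.coefficients.columns)
        if missing:
            raise ValueError(f"ground truth missing columns {sorted(missing)}")
        slope_cols = [c for c in COEF_COLUMNS if c != "constant"]
        if not np.all(np.isfinite(self.coefficients[slope_cols].to_numpy())):
            raise ValueError("ground-truth slope coefficients must be finite")

    @classmethod
    def default(cls, n_waves: int = 7, sex_start: float = 2.1, sex_end: float = 0.9,
                ethnicity: float = 0.2, ses: float = 0.2, reciprocity: float = 2.9,
                status: float = 0.5, clustering: float = 0.7) -> "GroundTruth":
        """Empirically plausible magnitudes: strong but declining sex
        homophily, weak ethnicity/SES homophily, strong reciprocity, moderate
        status and clustering norms."""
        waves = np.arange(n_waves)
        sex = np.linspace(sex_start, sex_end, n_waves)
        df = pd.DataFrame(
            {
                "sex_homophily": sex,
                "ethnicity_homophily": ethnicity,
                "ses_homophily": ses,
                "reciprocity": reciprocity,
                "status": status,
                "clustering": clustering,
                "constant": np.nan,
            },
            index=[f"T{t + 1}" for t in waves],
        )
        return cls(df)

    def row(self, t: int) -> pd.Series:
        return self.coefficients.iloc[t]


def generate_attributes(config: CohortConfig, rng: np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Node attribute and participation table for one cohort.

    Sex is balanced 50/50 (within one student for odd n); ethnicity majority
    and SES-high are i.i.d. Bernoulli; participation is i.i.d. per wave with
    probability 1 - attrition_rate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    sex = np.zeros(n, dtype=int)
    sex[: n // 2] = 1
    rng.shuffle(sex)
    table = pd.DataFrame(
        {
            "sex": sex,
            "ethnicity_majority": (rng.random(n) < config.majority_share).astype(int),
            "ses_high": (rng.random(n) < config.ses_high_share).astype(int),
        },
        index=[f"s{i:04d}" for i in range(n)],
    )
    for t in range(config.n_waves):
        table[f"participates_T{t + 1}"] = (
            rng.random(n) < 1.0 - config.attrition_rate
        ).astype(int)
    return table


# ---------------------------------------------------------------------------
# Wave simulation
# ---------------------------------------------------------------------------

def _sex_homophilous_seed(attributes: pd.DataFrame, sex_coef: float,
                          target_outdegree: float, rng: np.random.Generator
                          ) -> np.ndarray:
    """Independent-dyad random graph with sex homophily at target density."""
    sex = attributes["sex"].to_numpy(dtype=int)
    n = sex.size
    same = (sex[:, None] == sex[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    off = ~np.eye(n, dtype=bool)
    target_density = target_outdegree / (n - 1)

    def mean_p(c):
        return expit(c + sex_coef * same[off]).mean()

    lo, hi = -30.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target_density:
            lo = mid
        else:
            hi = mid
    c = 0.5 * (lo + hi)
    P = expit(c + sex_coef * same)
    R = (rng.random((n, n)) < P).astype(np.int8)
    np.fill_diagonal(R, 0)
    return R


class _SweepState:
    """Adjacency plus incrementally maintained covariate matrices."""

    def __init__(self, R: np.ndarray):
        self.R = np.ascontiguousarray(R, dtype=np.int8).copy()
        n = self.R.shape[0]
        self.n = n
        self.indeg = self.R.sum(axis=0).astype(np.int64)
        Rbar = ((self.R + self.R.T) > 0).astype(np.int64)
        np.fill_diagonal(Rbar, 0)
        self.Rbar = Rbar
        self.TP = Rbar @ Rbar

    def toggle(self, i: int, j: int, new: int) -> None:
        old = int(self.R[i, j])
        if new == old:
            return
        self.R[i, j] = new
        self.indeg[j] += new - old
        other = int(self.R[j, i])
        newbar = 1 if (new or other) else 0
        oldbar = 1 if (old or other) else 0
        d = newbar - oldbar
        if d == 0:
            return
        col_i = self.Rbar[:, i].copy()
        col_j = self.Rbar[:, j].copy()
        # TP = Rbar^2 updated for the symmetric perturbation at (i, j), (j, i)
        self.TP[:, j] += d * col_i
        self.TP[:, i] += d * col_j
        self.TP[i, :] += d * col_j
        self.TP[j, :] += d * col_i
        self.TP[i, i] += d * d
        self.TP[j, j] += d * d
        self.Rbar[i, j] = newbar
        self.Rbar[j, i] = newbar

    def z_params(self) -> tuple[float, float, float, float]:
        """Mean/SD of the logged popularity and clustering covariates."""
        n = self.n
        off = ~np.eye(n, dtype=bool)
        x1 = np.log(np.broadcast_to(self.indeg, (n, n)) - self.R + 1.0)[off]
        x2 = np.log(self.TP + 1.0)[off]
        return (
            float(x1.mean()), float(x1.std()) or 1.0,
            float(x2.mean()), float(x2.std()) or 1.0,
        )


def _run_sweeps(R0: np.ndarray, same_sex: np.ndarray, same_eth: np.ndarray,
                same_ses: np.ndarray, coeffs: pd.Series, constant: float,
                uniforms: np.ndarray, n_sweeps: int,
                z_params: tuple[float, float, float, float]) -> np.ndarray:
    """Sequential dyad updates; ``uniforms`` has one draw per ordered dyad
    per sweep so the whole trajectory is a deterministic function of them.

    ``z_params`` (mean/SD of the logged popularity and clustering covariates)
    are frozen at the initializing state: re-standardizing against the moving
    state would let the effective feedback coefficients blow up whenever the
    graph drifts sparse (the SDs shrink), a degeneracy this family of models
    is known for.
    """
    state = _SweepState(R0)
    n = state.n
    b_sex = float(coeffs["sex_homophily"])
    b_eth = float(coeffs["ethnicity_homophily"])
    b_ses = float(coeffs["ses_homophily"])
    b_rec = float(coeffs["reciprocity"])
    b_sta = float(coeffs["status"])
    b_clu = float(coeffs["clustering"])
    m1, s1, m2, s2 = z_params
    log, exp = math.log, math.exp
    k = 0
    for _ in range(n_sweeps):
        R, TP, indeg = state.R, state.TP, state.indeg
        for i in range(n):
            base_i = (
                constant
                + b_sex * same_sex[i]
                + b_eth * same_eth[i]
                + b_ses * same_ses[i]
            )
            for j in range(i + 1, n):
                # dyad-pair Gibbs update: draw (y_ij, y_ji) jointly from the
                # 4-state law implied by the two directed conditionals, so the
                # reciprocity interaction is sampled without staleness
                a_ij = (
                    base_i[j]
                    + b_sta * (log(indeg[j] - R[i, j] + 1.0) - m1) / s1
                    + b_clu * (log(TP[i, j] + 1.0) - m2) / s2
                )
                a_ji = (
                    base_i[j]
                    + b_sta * (log(indeg[i] - R[j, i] + 1.0) - m1) / s1
                    + b_clu * (log(TP[j, i] + 1.0) - m2) / s2
                )
                w01 = exp(a_ji)
                w10 = exp(a_ij)
                w11 = exp(a_ij + a_ji + b_rec)
                z = 1.0 + w01 + w10 + w11
                p_ij = (w10 + w11) / z  # marginal P(y_ij = 1)
                y_ij = 1 if uniforms[k] < p_ij else 0
                if y_ij:
                    p_ji = w11 / (w10 + w11)
                else:
                    p_ji = w01 / (1.0 + w01)
                y_ji = 1 if uniforms[k + 1] < p_ji else 0
                k += 2
                state.toggle(i, j, y_ij)
                state.toggle(j, i, y_ji)
    return state.R


def simulate_wave(prev: np.ndarray | None, attributes: pd.DataFrame,
                  coeffs: pd.Series, config: CohortConfig,
                  rng: np.random.Generator | None = None,
                  max_bisection_steps: int = 24,
                  max_restarts: int = 5) -> tuple[np.ndarray, float]:
    """Simulate one wave's directed adjacency matrix.

    Initializes from ``prev`` (or a sex-homophilous random seed graph for the
    first wave), then performs ``config.n_sweeps`` sequential sweeps over all
    ordered dyads, each tie drawn Bernoulli(logistic(eta)).  The constant is
    tuned by bisection on the realized mean outdegree until it lies within 10%
    of ``config.target_mean_outdegree``; the same uniform draws are reused
    across bisection evaluations so the realized density is monotone in the
    constant.

    Returns ``(R, constant)`` with the tuned constant.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    sex = attributes["sex"].to_numpy(dtype=int)
    eth = attributes["ethnicity_majority"].to_numpy(dtype=int)
    ses = attributes["ses_high"].to_numpy(dtype=int)
    same_sex = (sex[:, None] == sex[None, :]).astype(np.float64)
    same_eth = (eth[:, None] == eth[None, :]).astype(np.float64)
    same_ses = (ses[:, None] == ses[None, :]).astype(np.float64)

    if prev is None:
        R0 = _sex_homophilous_seed(
            attributes, float(coeffs["sex_homophily"]),
            config.target_mean_outdegree, rng,
        )
    else:
        R0 = np.asarray(prev, dtype=np.int8)

    target = config.target_mean_outdegree
    tol = 0.10 * target
    z_params = _SweepState(R0).z_params()

    # initial guess: independence approximation on the seed state's covariates
    guess = float(coeffs["constant"]) if np.isfinite(coeffs.get("constant", np.nan)) \
        else _independence_constant(R0, same_sex, same_eth, same_ses, coeffs, target)

    # the realized density can jump discontinuously in the constant (cascade
    # effects), so a particular draw sequence may skip the tolerance window;
    # retry with fresh draws a few times before giving up
    last_d = np.nan
    for _ in range(max_restarts):
        uniforms = rng.random(n * (n - 1) * config.n_sweeps)

        def realized(constant: float) -> tuple[np.ndarray, float]:
            R = _run_sweeps(R0, same_sex, same_eth, same_ses, coeffs, constant,
                            uniforms, config.n_sweeps, z_params)
            return R, float(R.sum(axis=1).mean())

        R, d = realized(guess)
        if abs(d - target) <= tol:
            return R, guess
        lo = hi = guess
        d_lo = d_hi = d
        step = 1.0
        while d_lo > target and lo > guess - 30:
            lo -= step
            _, d_lo = realized(lo)
            step *= 2
        step = 1.0
        while d_hi < target and hi < guess + 30:
            hi += step
            _, d_hi = realized(hi)
            step *= 2
        for _ in range(max_bisection_steps):
            mid = 0.5 * (lo + hi)
            R, d = realized(mid)
            if abs(d - target) <= tol:
                return R, mid
            if d < target:
                lo = mid
            else:
                hi = mid
        last_d = d
    raise ConvergenceError(
        f"could not tune density to {target:.2f} +/- 10% "
        f"(last realized mean outdegree {last_d:.2f})"
    )


def _independence_constant(R0, same_sex, same_eth, same_ses, coeffs, target
                           ) -> float:
    """Constant solving mean(p) = target density, treating dyads as
    independent with covariates frozen at the seed state."""
    state = _SweepState(R0)
    n = state.n
    off = ~np.eye(n, dtype=bool)
    m1, s1, m2, s2 = state.z_params()
    x1 = (np.log(np.broadcast_to(state.indeg, (n, n)) - state.R + 1.0) - m1) / s1
    x2 = (np.log(state.TP + 1.0) - m2) / s2
    eta0 = (
        coeffs["sex_homophily"] * same_sex
        + coeffs["ethnicity_homophily"] * same_eth
        + coeffs["ses_homophily"] * same_ses
        + coeffs["reciprocity"] * state.R.T
        + coeffs["status"] * x1
        + coeffs["clustering"] * x2
    )[off]
    target_density = target / (n - 1)
    lo, hi = -40.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(mid + eta0).mean() < target_density:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _quality_flags(R: np.ndarray, eta: np.ndarray, rng: np.random.Generator
                   ) -> dict[tuple[int, int], tuple[int, int]]:
    """Attach best-friend and meeting-frequency flags to reported ties.

    Best friends are the top 20% of each ego's ties by linear predictor
    (at least one); meeting frequency bins the tie's linear predictor into
    within-wave quintiles (1 = least frequent).  These synthesis rules are a
    modelling convenience of the generator, not an estimated quantity: they
    exist so that quality-covariate models are exercisable on synthetic data.
    """
    edges: dict[tuple[int, int], tuple[int, int]] = {}
    rows, cols = np.nonzero(R)
    if rows.size == 0:
        return edges
    tie_eta = eta[rows, cols]
    quintiles = np.quantile(tie_eta, [0.2, 0.4, 0.6, 0.8])
    meet = 1 + np.searchsorted(quintiles, tie_eta)
    best = np.zeros(rows.size, dtype=int)
    for ego in np.unique(rows):
        mask = np.nonzero(rows == ego)[0]
        k = max(1, int(math.ceil(0.2 * mask.size)))
        top = mask[np.argsort(-tie_eta[mask], kind="stable")[:k]]
        best[top] = 1
    for r, c, b, m in zip(rows, cols, best, meet):
        edges[(int(r), int(c))] = (int(b), int(m))
    return edges


def generate_cohort(config: CohortConfig, truth: GroundTruth | None = None,
                    setting_id: str = "synthetic") -> tuple[Panel, GroundTruth]:
    """Generate a full longitudinal cohort panel plus the truth used.

    Waves are chained: each wave's sweep initializes from the previous wave's
    latent matrix.  Egos who do not participate at a wave report no ties at
    that wave (their outgoing nominations are censored from the panel, not
    from the latent dynamics).
    """
    if truth is None:
        truth = GroundTruth.default(config.n_waves)
    if len(truth.coefficients) != config.n_waves:
        raise ValueError("ground truth must supply one coefficient row per wave")
    rng = np.random.default_rng(config.seed)
    attributes = generate_attributes(config, rng)
    node_ids = list(attributes.index)

    sex = attributes["sex"].to_numpy(dtype=int)
    eth = attributes["ethnicity_majority"].to_numpy(dtype=int)
    ses = attributes["ses_high"].to_numpy(dtype=int)
    same_sex = (sex[:, None] == sex[None, :]).astype(float)
    same_eth = (eth[:, None] == eth[None, :]).astype(float)
    same_ses = (ses[:, None] == ses[None, :]).astype(float)

    tuned = truth.coefficients.copy()
    waves: list[WaveNetwork] = []
    prev: np.ndarray | None = None
    part_cols = [f"participates_T{t + 1}" for t in range(config.n_waves)]
    participation = attributes[part_cols].astype(bool).copy()
    participation.columns = [f"T{t + 1}" for t in range(config.n_waves)]

    for t in range(config.n_waves):
        label = f"T{t + 1}"
        coeffs = truth.row(t)
        R, constant = simulate_wave(prev, attributes, coeffs, config, rng)
        tuned.iloc[t, tuned.columns.get_loc("constant")] = constant
        # linear predictor on the realized wave, for quality-flag synthesis
        state = _SweepState(R)
        n = config.n
        m1, s1, m2, s2 = state.z_params()
        x1 = (np.log(np.broadcast_to(state.indeg, (n, n)) - R + 1.0) - m1) / s1
        x2 = (np.log(state.TP + 1.0) - m2) / s2
        eta = (
            constant
            + coeffs["sex_homophily"] * same_sex
            + coeffs["ethnicity_homophily"] * same_eth
            + coeffs["ses_homophily"] * same_ses
            + coeffs["reciprocity"] * R.T
            + coeffs["status"] * x1
            + coeffs["clustering"] * x2
        )
        participates = participation[label].to_numpy()
        R_reported = R * participates[:, None].astype(np.int8)
        flags = _quality_flags(R_reported, eta, rng)
        edges = {
            (node_ids[i], node_ids[j]): bf_mf for (i, j), bf_mf in flags.items()
        }
        waves.append(WaveNetwork(label, edges))
        prev = R

    panel = Panel(
        setting_id=setting_id,
        roster=node_ids,
        attributes=attributes[["sex", "ethnicity_majority", "ses_high"]],
        waves=waves,
        participation=participation,
    )
    return panel, GroundTruth(tuned)
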