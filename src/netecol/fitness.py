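"""The network logit for tie fitness: model, results, ranks and threshold.

The probability that ego i nominates alter j is modelled as

    logit p(e_ij | G_t) = const + beta_C . (same_sex, same_eth, same_ses)
                                + beta_R . (x1, x2, x3) + eps_S[i] + eps_R[j]

where beta_C weighs the categorization (homophily) norms, beta_R the
configurational norms (indegree popularity, local clustering, reciprocity),
and eps_S / eps_R are optional crossed sender and receiver intercepts that
absorb latent sociality differences.  The model is used for point prediction:
predicted probabilities are rank-normalized per network into a *tie fitness*
f in [0, 1] (the dyad with the highest probability has f = 1), and a fitness
threshold is calibrated so a target share of reported relations (default 90%)
scores at or above it.

The model deliberately stays a (pseudo-likelihood) logit rather than an
ERGM/SAOM: dyadic covariates are functions of the rest of the graph only, and
only the probability *ranking* is consumed downstream.  Standard errors of the
logit are underestimated under tie dependence and are reported for orientation
only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit as logit_fn
from scipy.stats import rankdata

from .design import COVARIATES, DyadDesign, build_design, standardize

logger = logging.getLogger(__name__)

PARAM_NAMES = ("const",) + COVARIATES

__all__ = [
    "TieFitnessModel",
    "TieFitnessResults",
    "FitnessSurface",
    "ThresholdCalibration",
    "RetrievalCurve",
    "SeparationError",
    "fit",
    "predict",
    "percentile_rank",
    "retrieval_curve",
    "calibrate_threshold",
]


class SeparationError(RuntimeError):
    """Perfect separation: a covariate fully determines the outcome."""


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class TieFitnessModel:
    """Dyadic network logit on one wave's design matrix.

    Parameters
    ----------
    design
        A standardized :class:`~netecol.design.DyadDesign` (raw designs are
        standardized on the fly).
    random_effects
        If true, crossed sender/receiver intercepts are estimated by
        alternating ridge-penalized updates; the ridge weight is the current
        inverse variance-component estimate, updated after each sweep.
    """

    def __init__(self, design: DyadDesign, random_effects: bool = False):
        if not design.standardized:
            design = standardize(design)
        self.design = design
        self.random_effects = random_effects
        y = design.outcome()
        if y.sum() == 0:
            raise ValueError("all outcomes are 0; the logit is not identified")
        if y.sum() == len(y):
            raise ValueError("all outcomes are 1; the logit is not identified")

    @classmethod
    def from_panel(cls, panel, wave: str, random_effects: bool = False) -> "TieFitnessModel":
        from .panel import adjacency_matrix

        R = adjacency_matrix(panel, wave)
        design = standardize(
            build_design(R, panel.attributes, roster=panel.roster, wave_label=wave)
        )
        return cls(design, random_effects=random_effects)

    # -- fitting ------------------------------------------------------------
    def fit(self, max_iter: int = 50, tol: float = 1e-6) -> "TieFitnessResults":
        X = sm.add_constant(self.design.matrix(), has_constant="add")
        y = self.design.outcome()
        egos = self.design.table["ego"].to_numpy()
        alters = self.design.table["alter"].to_numpy()
        nodes = pd.unique(np.concatenate([egos, alters]))
        eps_s = pd.Series(0.0, index=nodes)
        eps_r = pd.Series(0.0, index=nodes)

        params, llf, converged = self._fit_glm(X, y, offset=None, max_iter=max_iter)
        p_hat = expit(X @ params)
        if np.max(np.abs(y - p_hat)) < 1e-6:
            worst = int(np.argmax(np.abs(params[1:]))) + 1
            raise SeparationError(
                f"perfect separation on covariate {PARAM_NAMES[worst]!r}: "
                "the model predicts the outcome exactly"
            )
        if self.random_effects:
            params, eps_s, eps_r, llf, converged = self._fit_crossed(
                X, y, egos, alters, params, max_iter=max_iter, tol=tol
            )
        self._check_separation(params)
        return TieFitnessResults(
            model=self,
            params=pd.Series(params, index=PARAM_NAMES),
            sender_effects=eps_s,
            receiver_effects=eps_r,
            llf=llf,
            n_obs=len(y),
            converged=converged,
        )

    def _fit_glm(self, X, y, offset, max_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset).fit(
                maxiter=max_iter
            )
        return np.asarray(res.params), float(res.llf), bool(res.converged)

    def _fit_crossed(self, X, y, egos, alters, params, max_iter, tol):
        """Alternating penalized updates for crossed node intercepts.

        Each sweep refits the fixed effects with the node intercepts as an
        offset, then takes one ridge-penalized Newton step per node; the ridge
        weight is 1 / sigma^2 with sigma^2 the current moment estimate of the
        intercept variance (floored to keep the update proper).
        """
        nodes = pd.unique(np.concatenate([egos, alters]))
        node_pos = pd.Series(np.arange(len(nodes)), index=nodes)
        s_idx = node_pos[egos].to_numpy()
        r_idx = node_pos[alters].to_numpy()
        eps_s = np.zeros(len(nodes))
        eps_r = np.zeros(len(nodes))
        var_s = var_r = 1.0
        converged = False
        llf = -np.inf
        for _ in range(max_iter):
            offset = eps_s[s_idx] + eps_r[r_idx]
            params, llf, _ = self._fit_glm(X, y, offset=offset, max_iter=max_iter)
            eta = X @ params + offset
            p = expit(eta)
            w = p * (1.0 - p)
            resid = y - p
            new_s = eps_s + (
                np.bincount(s_idx, resid, len(nodes)) - eps_s / var_s
            ) / (np.bincount(s_idx, w, len(nodes)) + 1.0 / var_s)
            new_r = eps_r + (
                np.bincount(r_idx, resid, len(nodes)) - eps_r / var_r
            ) / (np.bincount(r_idx, w, len(nodes)) + 1.0 / var_r)
            # keep effects mean-zero; shifts are absorbed by the constant
            shift = new_s.mean() + new_r.mean()
            new_s -= new_s.mean()
            new_r -= new_r.mean()
            params = params.copy()
            params[0] += shift
            delta = max(np.abs(new_s - eps_s).max(), np.abs(new_r - eps_r).max())
            eps_s, eps_r = new_s, new_r
            var_s = max(float(np.mean(eps_s**2)), 1e-4)
            var_r = max(float(np.mean(eps_r**2)), 1e-4)
            if delta < tol:
                converged = True
                break
        offset = eps_s[s_idx] + eps_r[r_idx]
        p = expit(X @ params + offset)
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
        return (
            params,
            pd.Series(eps_s, index=nodes),
            pd.Series(eps_r, index=nodes),
            llf,
            converged,
        )

    def _check_separation(self, params, cutoff: float = 50.0) -> None:
        worst = int(np.argmax(np.abs(params)))
        if np.abs(params[worst]) > cutoff or not np.all(np.isfinite(params)):
            raise SeparationError(
                f"perfect separation suspected on covariate {PARAM_NAMES[worst]!r} "
                f"(coefficient {params[worst]:.2f})"
            )


@dataclass
class TieFitnessResults:
    """Fitted tie-fitness logit: coefficients, node effects, and predictions."""

    model: TieFitnessModel
    params: pd.Series  # index: PARAM_NAMES
    sender_effects: pd.Series
    receiver_effects: pd.Series
    llf: float
    n_obs: int
    converged: bool

    # names matching the printed regression-table layout
    @property
    def beta_C(self) -> pd.Series:
        return self.params[["same_sex", "same_eth", "same_ses"]]

    @property
    def beta_R(self) -> pd.Series:
        return self.params[["x1", "x2", "x3"]]

    @property
    def constant(self) -> float:
        return float(self.params["const"])

    def predict(self, design: DyadDesign | None = None) -> np.ndarray:
        if design is None:
            design = self.model.design
        return predict(self, design)

    def fitness(self, design: DyadDesign | None = None) -> "FitnessSurface":
        """Percentile-rank fitness surface over all ordered dyads."""
        if design is None:
            design = self.model.design
        p = self.predict(design)
        f = percentile_rank(p)
        return FitnessSurface(
            table=pd.DataFrame(
                {
                    "ego": design.table["ego"].to_numpy(),
                    "alter": design.table["alter"].to_numpy(),
                    "p": p,
                    "f": f,
                }
            ),
            n=design.n,
            wave_label=design.wave_label,
        )

    def summary(self) -> str:
        lines = [
            "Tie fitness network logit",
            "=" * 46,
            f"observations: {self.n_obs}   log-likelihood: {self.llf:.1f}",
            f"converged: {self.converged}   "
            f"random effects: {self.model.random_effects}",
            "-" * 46,
            f"{'term':<14}{'coef':>10}",
        ]
        pretty = {
            "const": "constant",
            "same_sex": "sex homophily",
            "same_eth": "eth homophily",
            "same_ses": "SES homophily",
            "x1": "status (indeg)",
            "x2": "clustering",
            "x3": "reciprocity",
        }
        for name in ("same_sex", "same_eth", "same_ses", "x3", "x1", "x2", "const"):
            lines.append(f"{pretty[name]:<14}{self.params[name]:>10.3f}")
        lines.append("-" * 46)
        lines.append("note: logit SEs are anti-conservative under tie")
        lines.append("dependence and are not reported; the model is")
        lines.append("used for point prediction and ranking only.")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "llf": self.llf,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "random_effects": self.model.random_effects,
        }


# ---------------------------------------------------------------------------
# Functional surface mirroring the pipeline stages
# ---------------------------------------------------------------------------

def fit(design: DyadDesign, random_effects: bool = False, max_iter: int = 50,
        tol: float = 1e-6) -> TieFitnessResults:
    """Fit the network logit on a dyadic design (convenience wrapper)."""
    return TieFitnessModel(design, random_effects=random_effects).fit(
        max_iter=max_iter, tol=tol
    )


def predict(results: TieFitnessResults, design: DyadDesign) -> np.ndarray:
    """Predicted tie probabilities for every ordered dyad of ``design``."""
    if not design.standardized:
        design = standardize(design)
    X = design.matrix()
    eta = results.constant + X @ results.params[list(COVARIATES)].to_numpy()
    egos = design.table["ego"]
    alters = design.table["alter"]
    eta = eta + egos.map(results.sender_effects).fillna(0.0).to_numpy()
    eta = eta + alters.map(results.receiver_effects).fillna(0.0).to_numpy()
    return expit(eta)


@dataclass
class FitnessSurface:
    """Per-dyad predicted probability p and percentile-rank fitness f."""

    table: pd.DataFrame  # columns: ego, alter, p, f
    n: int
    wave_label: str | None = None

    def fitness_lookup(self) -> dict[tuple[str, str], float]:
        return dict(
            zip(zip(self.table["ego"], self.table["alter"]), self.table["f"])
        )

    def fitness_matrix(self, roster: list[str]) -> np.ndarray:
        """Dense fitness matrix in roster order (diagonal = NaN)."""
        idx = {node: i for i, node in enumerate(roster)}
        F = np.full((len(roster), len(roster)), np.nan)
        rows = self.table["ego"].map(idx).to_numpy()
        cols = self.table["alter"].map(idx).to_numpy()
        F[rows, cols] = self.table["f"].to_numpy()
        return F

    def reported_fitness(self, reported: set[tuple[str, str]]) -> np.ndarray:
        """Fitness values of the dyads in ``reported`` (the observed ties)."""
        mask = [
            (e, a) in reported
            for e, a in zip(self.table["ego"], self.table["alter"])
        ]
        return self.table.loc[mask, "f"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def percentile_rank(p: np.ndarray) -> np.ndarray:
    """Rank-normalize probabilities to fitness f in [0, 1].

    f = (rank - 1) / (N - 1) with average ranks for ties, so the highest
    probability maps to 1 and the lowest to 0.  If every probability is
    identical there is no ranking information and all dyads get f = 0.5.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two dyads to rank")
    if np.all(p == p[0]):
        logger.warning("all predicted probabilities identical; fitness set to 0.5")
        return np.full(p.shape, 0.5)
    return (rankdata(p, method="average") - 1.0) / (p.size - 1.0)


@dataclass
class RetrievalCurve:
    """Share of reported ties with fitness >= f, a non-increasing step curve.

    ``curve(0) == 1`` always, since fitness is non-negative.
    """

    values: np.ndarray  # sorted ascending reported-tie fitness values
    f_grid: np.ndarray  # distinct observed fitness values (ascending)
    share: np.ndarray  # share of reported ties at or above each grid value

    @property
    def n_reported(self) -> int:
        return self.values.size

    def __call__(self, x: float | np.ndarray) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        n_below = np.searchsorted(self.values, x, side="left")
        out = (self.values.size - n_below) / self.values.size
        return float(out) if out.ndim == 0 else out


def retrieval_curve(surface: FitnessSurface, reported: set[tuple[str, str]]) -> RetrievalCurve:
    """Cumulative share of reported relations by tie fitness for one network."""
    vals = surface.reported_fitness(reported)
    if vals.size == 0:
        raise ValueError("no reported ties")
    vals = np.sort(vals)
    grid = np.unique(vals)
    tail = np.array([(vals >= g).mean() for g in grid])
    return RetrievalCurve(values=vals, f_grid=grid, share=tail)


@dataclass
class ThresholdCalibration:
    """Fitness threshold f* retrieving a target share of reported relations."""

    retrieval_target: float
    threshold: float
    achieved_retrieval: float
    per_network_retrieval: tuple[float, float]  # (min, max) at the threshold
    n_reported: int

    def to_dict(self) -> dict:
        return {
            "retrieval_target": self.retrieval_target,
            "threshold": self.threshold,
            "achieved_retrieval": self.achieved_retrieval,
            "per_network_min": self.per_network_retrieval[0],
            "per_network_max": self.per_network_retrieval[1],
            "n_reported": self.n_reported,
        }


def calibrate_threshold(
    reported_fitness: list[np.ndarray],
    retrieval_target: float = 0.90,
) -> ThresholdCalibration:
    """Choose the fitness threshold from pooled reported-tie fitness.

    The threshold is the largest observed fitness value f* such that the
    pooled share of reported ties with f >= f* still reaches the target.
    (Equivalently, for a 90% target: the 10th percentile from below of
    reported-tie fitness.)  With distinct fitness values the achieved
    retrieval overshoots the target by less than one reported-tie weight.
    """
    if not (0.0 < retrieval_target <= 1.0):
        raise ValueError("retrieval_target must lie in (0, 1]")
    arrays = [np.asarray(a, dtype=float) for a in reported_fitness if np.asarray(a).size]
    if not arrays:
        raise ValueError("no reported ties supplied")
    pooled = np.sort(np.concatenate(arrays))
    n = pooled.size
    # tail share of pooled values >= pooled[i] is (n - i) / n for the first
    # occurrence of each distinct value
    first_idx = np.searchsorted(pooled, pooled, side="left")
    shares = (n - first_idx) / n
    ok = shares >= retrieval_target
    threshold = float(pooled[ok][-1])
    achieved = float((pooled >= threshold).mean())
    per_net = [float((a >= threshold).mean()) for a in arrays]
    return ThresholdCalibration(
        retrieval_target=retrieval_target,
        threshold=threshold,
        achieved_retrieval=achieved,
        per_network_retrieval=(min(per_net), max(per_net)),
        n_reported=n,
    )
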