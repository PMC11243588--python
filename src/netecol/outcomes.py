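"""Dyad-wave outcome table and GLMs linking tie fitness to tie futures.

Four outcomes are modelled as functions of a dyad's fitness percentile:

* ``is_reported`` — the tie is named at the current wave (logit),
* ``will_form``  — an unreported dyad is named at the next wave (logit),
* ``survival``   — a reported tie is named again at the next wave (logit),
* ``longevity``  — number of future waves a reported tie is named
  (Poisson, log link; the simplest count GLM consistent with the
  marginal-effect scale of interest).

All models include wave dummies (first wave as reference) and, when several
settings are pooled, setting dummies.  The survival and longevity models add
relationship-quality covariates: times the dyad was reported in past waves,
the best-friend flag, and meeting-frequency dummies with the lowest level as
reference.  Standard errors are sandwich estimates clustered by dyad, since
the same dyad contributes one record per wave.

Eligibility follows the panel design: records exist only for dyads whose ego
participated at both the current and the next wave (otherwise the tie's
future status is unobserved), while fitness itself is computed on the
complete network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .fitness import FitnessSurface
from .panel import Panel, adjacency_matrix

OUTCOMES = ("is_reported", "will_form", "survival", "longevity")
QUALITY_OUTCOMES = ("survival", "longevity")

__all__ = [
    "OUTCOMES",
    "build_outcome_table",
    "OutcomeModel",
    "OutcomeResults",
    "fit_outcome_model",
    "marginal_effect_curve",
]


def build_outcome_table(panel: Panel,
                        surfaces: dict[str, FitnessSurface]) -> pd.DataFrame:
    """One record per eligible ordered dyad per wave T1..T-1.

    ``surfaces`` maps wave labels to fitness surfaces covering all ordered
    dyads of that wave.  Longevity counts strictly future waves; past counts
    strictly past waves; ``will_form`` is NaN for reported dyads and
    ``survival``/``longevity`` are NaN for unreported ones.
    """
    labels = panel.wave_labels
    if len(labels) < 2:
        raise ValueError("need at least two waves to define tie futures")
    needed = labels[:-1]
    missing = [w for w in needed if w not in surfaces]
    if missing:
        raise ValueError(f"missing fitness surfaces for waves {missing}")

    n = panel.n
    T = len(labels)
    adj = np.stack([adjacency_matrix(panel, w) for w in labels])  # (T, n, n)
    cum_future = np.cumsum(adj[::-1], axis=0)[::-1]  # reported at >= t
    off = ~np.eye(n, dtype=bool)
    ego_idx, alter_idx = np.nonzero(off)
    roster = np.asarray(panel.roster, dtype=object)
    part = panel.participation.loc[panel.roster, labels].to_numpy(dtype=bool)

    frames = []
    for t, label in enumerate(needed):
        surf = surfaces[label]
        if len(surf.table) != n * (n - 1):
            raise ValueError(
                f"surface for {label} covers {len(surf.table)} dyads, "
                f"expected {n * (n - 1)}"
            )
        f_mat = surf.fitness_matrix(panel.roster)
        eligible = part[ego_idx, t] & part[ego_idx, t + 1]
        e, a = ego_idx[eligible], alter_idx[eligible]
        reported = adj[t, e, a].astype(float)
        next_rep = adj[t + 1, e, a].astype(float)
        future = (cum_future[t + 1, e, a] if t + 1 < T else
                  np.zeros(e.size)).astype(float)
        past = (adj[:t, e, a].sum(axis=0) if t > 0 else
                np.zeros(e.size)).astype(float)
        wave_net = panel.wave(label)
        bf = np.zeros(e.size)
        mf = np.ones(e.size)
        for k, (i, j) in enumerate(zip(e, a)):
            flags = wave_net.edges.get((roster[i], roster[j]))
            if flags is not None:
                bf[k], mf[k] = flags
        frames.append(pd.DataFrame({
            "setting": panel.setting_id,
            "wave": label,
            "ego": roster[e],
            "alter": roster[a],
            "dyad": [f"{panel.setting_id}:{x}>{y}" for x, y in
                     zip(roster[e], roster[a])],
            "f": f_mat[e, a],
            "is_reported": reported,
            "will_form": np.where(reported == 0, next_rep, np.nan),
            "survival": np.where(reported == 1, next_rep, np.nan),
            "longevity": np.where(reported == 1, future, np.nan),
            "times_past": past,
            "is_best_friend": bf,
            "meet_freq": mf.astype(int),
        }))
    return pd.concat(frames, ignore_index=True)


def _design_frame(table: pd.DataFrame, outcome: str) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Subset rows, build the dummy-coded design, return (X, y, groups)."""
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; choose from {OUTCOMES}")
    if outcome == "is_reported":
        sub = table
    elif outcome == "will_form":
        sub = table[table["is_reported"] == 0]
    else:
        sub = table[table["is_reported"] == 1]
    y = sub[outcome].astype(float)
    if y.isna().any():
        raise ValueError(f"outcome {outcome!r} undefined on selected rows")
    if y.nunique() < 2 and outcome != "longevity":
        raise ValueError(f"outcome {outcome!r} is degenerate (constant)")

    X = pd.DataFrame({"f": sub["f"].astype(float)}, index=sub.index)
    if outcome in QUALITY_OUTCOMES:
        X["times_past"] = sub["times_past"].astype(float)
        X["is_best_friend"] = sub["is_best_friend"].astype(float)
        for lvl in range(2, 6):  # meet_freq reference = lowest level 1
            X[f"meet_{lvl}"] = (sub["meet_freq"] == lvl).astype(float)
    waves = sorted(table["wave"].unique())
    for w in waves[1:]:
        X[f"wave_{w}"] = (sub["wave"] == w).astype(float)
    settings = sorted(table["setting"].unique())
    for s in settings[1:]:
        X[f"setting_{s}"] = (sub["setting"] == s).astype(float)
    X = sm.add_constant(X, has_constant="add")
    return X, y, sub["dyad"]


class OutcomeModel:
    """GLM for one tie-future outcome on the dyad-wave table."""

    def __init__(self, table: pd.DataFrame, outcome: str):
        self.table = table
        self.outcome = outcome
        self.X, self.y, self.groups = _design_frame(table, outcome)
        self.family = (
            sm.families.Poisson() if outcome == "longevity"
            else sm.families.Binomial()
        )

    def fit(self, cov_type: str = "cluster", **cov_kwds) -> "OutcomeResults":
        glm = sm.GLM(self.y, self.X, family=self.family)
        if cov_type == "cluster":
            kwds = {"groups": pd.Categorical(self.groups).codes, **cov_kwds}
            res = glm.fit(cov_type="cluster", cov_kwds=kwds)
        else:
            res = glm.fit(cov_type=cov_type, cov_kwds=cov_kwds or None)
        return OutcomeResults(model=self, sm_results=res)


@dataclass
class OutcomeResults:
    """Fitted outcome GLM with dyad-clustered sandwich errors."""

    model: OutcomeModel
    sm_results: object

    @property
    def params(self) -> pd.Series:
        return self.sm_results.params

    @property
    def bse(self) -> pd.Series:
        return self.sm_results.bse

    @property
    def fitness_coef(self) -> float:
        return float(self.params["f"])

    def summary(self) -> str:
        return str(self.sm_results.summary())

    def marginal_effect_curve(self, grid: np.ndarray | None = None,
                              profile: dict[str, float] | None = None
                              ) -> pd.DataFrame:
        return marginal_effect_curve(self, grid=grid, profile=profile)


def fit_outcome_model(table: pd.DataFrame, outcome: str,
                      cov_type: str = "cluster", **cov_kwds) -> OutcomeResults:
    """Fit the GLM for one outcome (convenience wrapper)."""
    return OutcomeModel(table, outcome).fit(cov_type=cov_type, **cov_kwds)


def marginal_effect_curve(results: OutcomeResults,
                          grid: np.ndarray | None = None,
                          profile: dict[str, float] | None = None
                          ) -> pd.DataFrame:
    """Predicted outcome over a fitness grid at a reference profile.

    The default profile sets quality covariates to baseline (never reported
    before, not a best friend, lowest meeting frequency) and wave/setting
    dummies to the modal category of the estimation sample.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    X = results.model.X
    ref = pd.Series(0.0, index=X.columns)
    ref["const"] = 1.0
    modal = X.drop(columns=["const", "f"], errors="ignore")
    dummy_cols = [c for c in modal.columns if c.startswith(("wave_", "setting_"))]
    if dummy_cols:
        # modal wave/setting: the dummy whose mean is largest, if it beats
        # the (omitted) reference category
        for prefix in ("wave_", "setting_"):
            cols = [c for c in dummy_cols if c.startswith(prefix)]
            if not cols:
                continue
            means = X[cols].mean()
            if means.max() > 1.0 - means.sum():
                ref[means.idxmax()] = 1.0
    if profile:
        for k, v in profile.items():
            if k not in ref.index:
                raise KeyError(f"unknown covariate {k!r}")
            ref[k] = v
    eta0 = float(ref @ results.params)
    beta_f = results.fitness_coef
    link = results.sm_results.model.family.link
    pred = link.inverse(eta0 + beta_f * (grid - float(ref["f"])))
    return pd.DataFrame({"f": grid, "predicted": pred})
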