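"""Assortativity and coefficient-dispersion diagnostics.

Nominal assortativity follows the Newman mixing-matrix definition on the
*directed* graph: with e the k x k matrix of edge fractions by (ego category,
alter category), a its row sums and b its column sums,

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i).

r = 0 means ties mix as the category margins would predict; r = 1 means all
ties stay within category.  Coefficient dispersion summarizes a collection of
fitted tie-fitness models (one per network-wave) by per-term mean, SD and
coefficient of variation, plus the correlation between the reciprocity and
clustering coefficients, the classic trade-off between nested configurational
terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitness import PARAM_NAMES, TieFitnessResults
from .panel import Panel, adjacency_matrix

__all__ = [
    "MixingMatrix",
    "mixing_matrix",
    "nominal_assortativity",
    "same_category_share",
    "coefficient_dispersion",
    "assortativity_table",
]


@dataclass
class MixingMatrix:
    """Edge-fraction matrix by (ego category, alter category)."""

    e: np.ndarray
    categories: list

    @property
    def a(self) -> np.ndarray:  # row (ego) margins
        return self.e.sum(axis=1)

    @property
    def b(self) -> np.ndarray:  # column (alter) margins
        return self.e.sum(axis=0)


def mixing_matrix(R: np.ndarray, category: np.ndarray | list,
                  symmetrize: bool = False) -> MixingMatrix:
    """Mixing matrix of a binary digraph over node category labels."""
    R = np.asarray(R)
    if symmetrize:
        R = ((R + R.T) > 0).astype(int)
        np.fill_diagonal(R, 0)
    labels = np.asarray(category)
    cats = sorted(pd.unique(labels).tolist())
    pos = {c: i for i, c in enumerate(cats)}
    rows, cols = np.nonzero(R)
    if rows.size == 0:
        raise ValueError("graph has no edges; mixing matrix undefined")
    e = np.zeros((len(cats), len(cats)))
    for r, c in zip(rows, cols):
        e[pos[labels[r]], pos[labels[c]]] += 1
    e /= e.sum()
    return MixingMatrix(e=e, categories=cats)


def nominal_assortativity(R: np.ndarray, category: np.ndarray | list,
                          symmetrize: bool = False) -> float:
    """Newman's nominal assortativity coefficient on the directed graph.

    Returns 1.0 for a perfectly assortative graph even when a single category
    carries all edges (the 0/0 limit of the formula).
    """
    m = mixing_matrix(R, category, symmetrize=symmetrize)
    trace = float(np.trace(m.e))
    agreement = float(m.a @ m.b)
    if np.isclose(agreement, 1.0):
        return 1.0 if np.isclose(trace, 1.0) else float("nan")
    return (trace - agreement) / (1.0 - agreement)


def same_category_share(R: np.ndarray, category: np.ndarray | list) -> float:
    """Share of edges whose endpoints share the category label."""
    R = np.asarray(R)
    labels = np.asarray(category)
    rows, cols = np.nonzero(R)
    if rows.size == 0:
        raise ValueError("graph has no edges")
    return float((labels[rows] == labels[cols]).mean())


def coefficient_dispersion(models: list[TieFitnessResults]) -> pd.DataFrame:
    """Per-term mean, SD and CV across a collection of fitted models.

    The returned frame carries one row per model term; the attribute
    ``reciprocity_clustering_corr`` flags the trade-off between the
    reciprocity and clustering coefficients across networks.
    """
    if len(models) < 2:
        raise ValueError("need at least two fitted models")
    coefs = pd.DataFrame([m.params for m in models])[list(PARAM_NAMES)]
    mean = coefs.mean()
    sd = coefs.std(ddof=0)
    cv = sd / mean.where(mean != 0, np.nan)
    out = pd.DataFrame({"mean": mean, "sd": sd, "cv": cv})
    out.attrs["reciprocity_clustering_corr"] = float(
        np.corrcoef(coefs["x3"], coefs["x2"])[0, 1]
    )
    return out


def assortativity_table(panel: Panel, symmetrize: bool = False) -> pd.DataFrame:
    """Per-wave assortativity on sex, ethnicity, and SES for one panel."""
    rows = []
    attr = panel.attributes.loc[panel.roster]
    for label in panel.wave_labels:
        R = adjacency_matrix(panel, label)
        row = {"wave": label}
        for col, name in (
            ("ses_high", "ses"),
            ("ethnicity_majority", "ethnicity"),
            ("sex", "sex"),
        ):
            try:
                row[name] = nominal_assortativity(
                    R, attr[col].to_numpy(), symmetrize=symmetrize
                )
            except ValueError:
                row[name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("wave")
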