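"""Per-wave dyadic design matrices for the tie-fitness logit.

For every ordered dyad (i, j), i != j, of a wave the design carries

* ``same_sex``, ``same_eth``, ``same_ses`` — attribute-match indicators
  (categorization norms),
* ``x1`` — alter's indegree popularity, log(C_ij + 1) z-scored, where C_ij is
  j's indegree excluding any tie received from ego i,
* ``x2`` — local clustering, log(twopaths_ij + 1) z-scored, twopaths counted
  in the symmetrized adjacency matrix,
* ``x3`` — reciprocity, the transposed adjacency entry R[j, i],
* ``y``  — the outcome R[i, j].

Standardization uses the population standard deviation over all ordered dyads
of the wave; the scale convention is immaterial to percentile-rank fitness but
is fixed here for reproducibility.  None of the covariates depends on the
focal entry R[i, j] itself, so the logit never predicts a tie from itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COVARIATES = ("same_sex", "same_eth", "same_ses", "x1", "x2", "x3")

__all__ = ["DyadDesign", "build_design", "standardize", "twopath_matrix", "COVARIATES"]


@dataclass
class DyadDesign:
    """Covariate table over all n(n-1) ordered dyads of one wave."""

    table: pd.DataFrame  # columns: ego, alter, y, same_sex, same_eth, same_ses,
    #                                x1_raw, x2_raw, x3 [, x1, x2]
    n: int
    wave_label: str | None = None

    @property
    def standardized(self) -> bool:
        return "x1" in self.table.columns

    def matrix(self) -> np.ndarray:
        """Design matrix in the canonical covariate order (requires z-scores)."""
        if not self.standardized:
            raise ValueError("design not standardized; call standardize() first")
        return self.table[list(COVARIATES)].to_numpy(dtype=float)

    def outcome(self) -> np.ndarray:
        return self.table["y"].to_numpy(dtype=float)

    def to_csv(self, path, wave: str | None = None) -> None:
        out = self.table.copy()
        out.insert(0, "wave", wave if wave is not None else (self.wave_label or ""))
        cols = ["wave", "ego", "alter", "y", "same_sex", "same_eth", "same_ses"]
        cols += ["x1", "x2"] if self.standardized else ["x1_raw", "x2_raw"]
        cols += ["x3"]
        out[cols].to_csv(path, index=False)


def twopath_matrix(R: np.ndarray) -> np.ndarray:
    """Count of two-paths i-k-j in the symmetrized graph, for every (i, j).

    Symmetrization is the elementwise OR of R with its transpose; the count is
    the (i, j) entry of the squared symmetrized matrix.  Symmetric by
    construction.
    """
    Rbar = ((R + R.T) > 0).astype(np.int64)
    np.fill_diagonal(Rbar, 0)
    return Rbar @ Rbar


def build_design(R: np.ndarray, attributes: pd.DataFrame,
                 roster: list[str] | None = None,
                 wave_label: str | None = None) -> DyadDesign:
    """Build the raw (unstandardized) dyadic design from one adjacency matrix.

    ``attributes`` must contain sex / ethnicity_majority / ses_high for every
    roster node; rows follow roster order when ``roster`` is given, else the
    attribute table's own order.
    """
    R = np.asarray(R)
    n = R.shape[0]
    if R.shape != (n, n):
        raise ValueError("adjacency matrix must be square")
    if np.trace(np.abs(R)) != 0:
        raise ValueError("adjacency matrix must have a zero diagonal")
    if roster is None:
        roster = list(attributes.index)
    missing = set(roster) - set(attributes.index)
    if missing:
        raise ValueError(f"attribute table missing roster nodes {sorted(missing)}")
    attrs = attributes.loc[roster]
    if len(roster) != n:
        raise ValueError("roster length does not match adjacency dimension")

    indeg = R.sum(axis=0)
    # C[i, j]: alter j's indegree minus any nomination from ego i
    C = np.broadcast_to(indeg, (n, n)) - R
    TP = twopath_matrix(R)

    sex = attrs["sex"].to_numpy(dtype=int)
    eth = attrs["ethnicity_majority"].to_numpy(dtype=int)
    ses = attrs["ses_high"].to_numpy(dtype=int)

    off = ~np.eye(n, dtype=bool)
    ego_idx, alter_idx = np.nonzero(off)
    table = pd.DataFrame(
        {
            "ego": np.asarray(roster, dtype=object)[ego_idx],
            "alter": np.asarray(roster, dtype=object)[alter_idx],
            "y": R[off].astype(int),
            "same_sex": (sex[ego_idx] == sex[alter_idx]).astype(int),
            "same_eth": (eth[ego_idx] == eth[alter_idx]).astype(int),
            "same_ses": (ses[ego_idx] == ses[alter_idx]).astype(int),
            "x1_raw": np.log(C[off] + 1.0),
            "x2_raw": np.log(TP[off] + 1.0),
            "x3": R.T[off].astype(int),
        }
    )
    return DyadDesign(table=table, n=n, wave_label=wave_label)


def standardize(design: DyadDesign) -> DyadDesign:
    """Z-score the logged popularity and clustering columns within the wave.

    A constant raw column yields an all-zero z-score column (with a warning)
    rather than a division by zero.
    """
    if len(design.table) < 2:
        raise ValueError("need at least two dyads to standardize")
    table = design.table.copy()
    for raw, z in (("x1_raw", "x1"), ("x2_raw", "x2")):
        col = table[raw].to_numpy(dtype=float)
        sd = col.std()  # population SD
        if sd == 0.0:
            logger.warning("column %s is constant; z-scores set to 0", raw)
            table[z] = 0.0
        else:
            table[z] = (col - col.mean()) / sd
    return DyadDesign(table=table, n=design.n, wave_label=design.wave_label)
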