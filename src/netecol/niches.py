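"""Dormant ties, fit-tie accounting, and relational-niche blockmodeling.

A *fit dyad* is any ordered pair whose fitness reaches the calibrated
threshold; a *dormant tie* is a fit dyad that is not reported as a relation.
Dormant ties are the activation potential of a setting: relations that would
align with its norms if expressed.  Because fit dyads cluster on subsegments
of the population, reordering the fit-tie matrix so that fit ties bunch
together exposes *relational niches*; the reordering uses CONCOR-style
iterated column correlations, the classic deterministic blockmodeling device.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitness import FitnessSurface
from .panel import Panel, adjacency_matrix

logger = logging.getLogger(__name__)

RATIO_CAP = 1e6  # sentinel for within/between ratios with zero between-density

__all__ = [
    "dormant_ties",
    "FitTieAccounting",
    "accounting",
    "NichePartition",
    "blockmodel_order",
    "niche_density",
    "cell_states",
]


def dormant_ties(surface: FitnessSurface, R: np.ndarray, threshold: float,
                 roster: list[str]) -> set[tuple[str, str]]:
    """Ordered dyads with fitness >= threshold that are not reported in R."""
    idx = {node: i for i, node in enumerate(roster)}
    out = set()
    for ego, alter, f in zip(surface.table["ego"], surface.table["alter"],
                             surface.table["f"]):
        if f >= threshold and R[idx[ego], idx[alter]] == 0:
            out.add((ego, alter))
    return out


@dataclass
class FitTieAccounting:
    """Bookkeeping of fit, reported, and dormant dyads in a population."""

    n: int
    n_dyads: int
    n_reported: int
    fit_share_of_dyads: float
    n_fit_dyads: int
    n_fit_reported: int
    n_dormant: int
    reported_share_of_fit: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n", "n_dyads", "n_reported", "fit_share_of_dyads", "n_fit_dyads",
            "n_fit_reported", "n_dormant", "reported_share_of_fit",
        )}


def accounting(n: int, n_reported: int, fit_share_of_dyads: float,
               n_fit_reported: int) -> FitTieAccounting:
    """Dormant-tie accounting for a population of ``n`` individuals.

    ``n_fit_dyads`` is the rounded share of the n(n-1) ordered dyads that are
    fit; dormant ties are the fit dyads not reported.  E.g. 100 students with
    a 17% fit share give round(0.17 * 9900) = 1683 fit dyads, and 368 fit
    reported relations then cover 368/1683 = 21.9% of them.
    """
    if n < 2:
        raise ValueError("need at least two individuals")
    if not (0.0 <= fit_share_of_dyads <= 1.0):
        raise ValueError("fit_share_of_dyads must lie in [0, 1]")
    if min(n_reported, n_fit_reported) < 0:
        raise ValueError("counts must be non-negative")
    if n_fit_reported > n_reported:
        raise ValueError("fit reported ties cannot exceed reported ties")
    n_dyads = n * (n - 1)
    n_fit = int(round(fit_share_of_dyads * n_dyads))
    if n_fit_reported > n_fit:
        raise ValueError("fit reported ties cannot exceed fit dyads")
    return FitTieAccounting(
        n=n,
        n_dyads=n_dyads,
        n_reported=n_reported,
        fit_share_of_dyads=fit_share_of_dyads,
        n_fit_dyads=n_fit,
        n_fit_reported=n_fit_reported,
        n_dormant=n_fit - n_fit_reported,
        reported_share_of_fit=n_fit_reported / n_fit if n_fit else float("nan"),
    )


# ---------------------------------------------------------------------------
# CONCOR blockmodel ordering
# ---------------------------------------------------------------------------

@dataclass
class NichePartition:
    """Node blocks and a display permutation for the fit-tie matrix."""

    blocks: np.ndarray  # block label per node (contiguous 0..k-1)
    permutation: np.ndarray  # node order for matrix display

    @property
    def k(self) -> int:
        return int(self.blocks.max()) + 1


def _converged_correlation(M: np.ndarray, max_iter: int = 60,
                           tol: float = 1e-8) -> np.ndarray | None:
    """Iterate column correlations until entries stabilize near +/-1."""
    C = M.astype(float)
    for _ in range(max_iter):
        sd = C.std(axis=0)
        if np.all(sd == 0):
            return None
        with np.errstate(invalid="ignore", divide="ignore"):
            nxt = np.corrcoef(C, rowvar=False)
        nxt = np.nan_to_num(nxt, nan=0.0)
        if np.max(np.abs(np.abs(nxt) - 1.0)) < tol:
            return nxt
        C = nxt
    return nxt


def _split(M: np.ndarray, nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """One CONCOR split of ``nodes`` using the submatrix of fit ties."""
    sub = M[np.ix_(nodes, nodes)]
    if sub.std() == 0 or len(nodes) < 4:
        return None
    C = _converged_correlation(sub)
    if C is None:
        return None
    side = C[0] >= 0
    if side.all() or (~side).all():
        return None
    return nodes[side], nodes[~side]


def blockmodel_order(fit_matrix: np.ndarray, k_blocks: int | str = "auto"
                     ) -> NichePartition:
    """Partition nodes so fit ties cluster on diagonal blocks.

    CONCOR-style: repeatedly split the largest splittable block by the sign
    pattern of the converged column-correlation matrix of the symmetrized fit
    matrix.  ``k_blocks='auto'`` splits until blocks stop being splittable or
    reach the minimum size; the display permutation orders nodes by block,
    then by within-block fit degree (descending), then by index.
    """
    F = np.asarray(fit_matrix)
    n = F.shape[0]
    if F.shape != (n, n):
        raise ValueError("fit matrix must be square")
    M = ((F + F.T) > 0).astype(float)
    np.fill_diagonal(M, 0.0)

    if M.std() == 0:
        logger.warning("constant fit matrix; single block returned")
        blocks = [np.arange(n)]
    else:
        target = None if k_blocks == "auto" else int(k_blocks)
        if target is not None and target < 1:
            raise ValueError("k_blocks must be >= 1")
        blocks = [np.arange(n)]
        frozen: list[np.ndarray] = []
        while blocks:
            if target is not None and len(blocks) + len(frozen) >= target:
                break
            if target is None and len(blocks) + len(frozen) >= 8:
                break  # auto mode: display-scale partitions only
            blocks.sort(key=len, reverse=True)
            blk = blocks.pop(0)
            parts = _split(M, blk)
            if parts is None:
                frozen.append(blk)
            else:
                blocks.extend(parts)
        blocks = frozen + blocks

    labels = np.empty(n, dtype=int)
    # contiguous labels in order of each block's mean position (stable)
    blocks.sort(key=lambda b: b.min())
    for lbl, blk in enumerate(blocks):
        labels[blk] = lbl
    degree = M.sum(axis=1)
    perm = np.array(sorted(range(n), key=lambda i: (labels[i], -degree[i], i)))
    return NichePartition(blocks=labels, permutation=perm)


def niche_density(partition: NichePartition, fit_matrix: np.ndarray
                  ) -> pd.DataFrame:
    """Fit-tie density per block pair and the within/between clustering ratio.

    The returned frame has one row per ordered block pair; its attrs carry
    ``clustering_ratio`` = mean within-block density / mean between-block
    density (capped at ``RATIO_CAP`` when no between-block fit ties exist).
    """
    F = np.asarray(fit_matrix).astype(float)
    labels = partition.blocks
    k = partition.k
    rows = []
    for a in range(k):
        ia = np.nonzero(labels == a)[0]
        for b in range(k):
            ib = np.nonzero(labels == b)[0]
            if a == b:
                cells = len(ia) * (len(ia) - 1)
            else:
                cells = len(ia) * len(ib)
            ties = F[np.ix_(ia, ib)].sum()
            if a == b:
                ties -= np.trace(F[np.ix_(ia, ia)])
            rows.append({
                "block_ego": a, "block_alter": b,
                "density": ties / cells if cells else np.nan,
            })
    out = pd.DataFrame(rows)
    within = out.loc[out.block_ego == out.block_alter, "density"].mean()
    between = out.loc[out.block_ego != out.block_alter, "density"].mean()
    if np.isnan(between):  # single block
        ratio = float("nan")
    elif between == 0:
        ratio = RATIO_CAP if within > 0 else float("nan")
    else:
        ratio = min(within / between, RATIO_CAP)
    out.attrs["clustering_ratio"] = float(ratio) if ratio == ratio else ratio
    out.attrs["within_density"] = float(within)
    out.attrs["between_density"] = float(between) if between == between else between
    return out


# ---------------------------------------------------------------------------
# Categorical cell states for matrix display
# ---------------------------------------------------------------------------

def cell_states(panel: Panel, wave: str, surface: FitnessSurface,
                threshold: float) -> pd.DataFrame:
    """Classify every ordered dyad of a wave for fitness-matrix display.

    States: ``dormant`` (fit, unreported), ``stable`` (reported now and
    next), ``forming`` (unreported now, reported next), ``dissolving``
    (reported now, dropped next), ``attrited`` (reported now, ego absent at
    the next wave), ``unfit`` (everything else).
    """
    labels = panel.wave_labels
    t = labels.index(wave)
    if t + 1 >= len(labels):
        raise ValueError("cell states need a following wave")
    R_now = adjacency_matrix(panel, wave)
    R_next = adjacency_matrix(panel, labels[t + 1])
    part_next = panel.participation.loc[panel.roster, labels[t + 1]].to_numpy(bool)
    idx = {node: i for i, node in enumerate(panel.roster)}
    recs = []
    for ego, alter, f in zip(surface.table["ego"], surface.table["alter"],
                             surface.table["f"]):
        i, j = idx[ego], idx[alter]
        fit = f >= threshold
        if R_now[i, j]:
            if not part_next[i]:
                state = "attrited"
            elif R_next[i, j]:
                state = "stable"
            else:
                state = "dissolving"
        elif R_next[i, j] and part_next[i]:
            state = "forming"
        elif fit:
            state = "dormant"
        else:
            state = "unfit"
        recs.append((ego, alter, f, int(fit), state))
    return pd.DataFrame(recs, columns=["ego", "alter", "f", "is_fit", "state"])
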