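"""Longitudinal nomination panels: containers, validation, and CSV round-trip.

A :class:`Panel` holds everything one school-cohort setting contributes to the
analysis: a roster of students, their categorical attributes (sex, ethnicity
majority/minority, parental-SES high/low), per-wave participation indicators,
and one directed nomination network per survey wave.  Node ids are opaque
strings; matrix coordinates always follow roster order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ATTRIBUTE_COLUMNS = ("sex", "ethnicity_majority", "ses_high")

__all__ = [
    "Panel",
    "WaveNetwork",
    "PanelValidationError",
    "read_panel",
    "write_panel",
    "adjacency_matrix",
]


class PanelValidationError(ValueError):
    """Raised when panel files or structures violate an invariant."""


@dataclass(frozen=True)
class WaveNetwork:
    """Directed nominations reported at a single survey wave.

    ``edges`` maps ordered pairs ``(ego, alter)`` to per-edge quality flags
    ``(best_friend, meet_freq)``.  Missing flags default to ``(0, 1)``:
    a regular friend whom ego meets least frequently.
    """

    wave_label: str
    edges: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def __post_init__(self) -> None:
        for (ego, alter) in self.edges:
            if ego == alter:
                raise PanelValidationError(
                    f"wave {self.wave_label}: self-tie {ego!r} -> {alter!r}"
                )


@dataclass
class Panel:
    """One setting's longitudinal nomination study.

    Invariants (enforced by :meth:`validate`): every edge endpoint is on the
    roster, no self-ties, wave labels are unique and ordered as given, and the
    participation table covers every (node, wave) cell.
    """

    setting_id: str
    roster: list[str]
    attributes: pd.DataFrame  # index: node_id; columns: ATTRIBUTE_COLUMNS
    waves: list[WaveNetwork]
    participation: pd.DataFrame  # index: node_id; columns: wave labels (bool)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        roster_set = set(self.roster)
        if len(roster_set) != len(self.roster):
            raise PanelValidationError("duplicate node ids on roster")
        missing = roster_set - set(self.attributes.index)
        if missing:
            raise PanelValidationError(f"attributes missing for nodes {sorted(missing)}")
        for col in ATTRIBUTE_COLUMNS:
            if col not in self.attributes.columns:
                raise PanelValidationError(f"attribute table lacks column {col!r}")
        labels = [w.wave_label for w in self.waves]
        if len(set(labels)) != len(labels):
            raise PanelValidationError("duplicate wave labels")
        if list(self.participation.columns) != labels:
            raise PanelValidationError(
                "participation table columns must equal the wave labels in order"
            )
        if set(self.participation.index) != roster_set:
            raise PanelValidationError("participation table must cover the full roster")
        for wave in self.waves:
            for (ego, alter) in wave.edges:
                if ego not in roster_set or alter not in roster_set:
                    raise PanelValidationError(
                        f"wave {wave.wave_label}: edge ({ego!r}, {alter!r}) "
                        "has endpoint off roster"
                    )
                if not bool(self.participation.at[ego, wave.wave_label]):
                    raise PanelValidationError(
                        f"wave {wave.wave_label}: ego {ego!r} reported a tie "
                        "but did not participate"
                    )

    # -- convenience --------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.roster)

    @property
    def wave_labels(self) -> list[str]:
        return [w.wave_label for w in self.waves]

    def wave(self, label: str) -> WaveNetwork:
        for w in self.waves:
            if w.wave_label == label:
                return w
        raise KeyError(f"unknown wave {label!r}")

    def node_index(self) -> dict[str, int]:
        return {node: i for i, node in enumerate(self.roster)}

    def adjacency(self, wave: str) -> np.ndarray:
        return adjacency_matrix(self, wave)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        return (
            self.setting_id == other.setting_id
            and self.roster == other.roster
            and self.attributes.loc[self.roster, list(ATTRIBUTE_COLUMNS)]
            .astype(int)
            .equals(other.attributes.loc[other.roster, list(ATTRIBUTE_COLUMNS)].astype(int))
            and self.wave_labels == other.wave_labels
            and all(a.edges == b.edges for a, b in zip(self.waves, other.waves))
            and self.participation.loc[self.roster].astype(bool)
            .equals(other.participation.loc[other.roster].astype(bool))
        )


def adjacency_matrix(panel: Panel, wave: str) -> np.ndarray:
    """Dense binary adjacency matrix of a wave in roster order.

    Entry ``(i, j)`` is 1 iff node ``roster[i]`` nominated ``roster[j]``.
    The diagonal is structurally zero.
    """
    w = panel.wave(wave)
    idx = panel.node_index()
    R = np.zeros((panel.n, panel.n), dtype=np.int8)
    for (ego, alter) in w.edges:
        R[idx[ego], idx[alter]] = 1
    return R


# ---------------------------------------------------------------------------
# CSV I/O
#
# edges.csv  : wave,ego,alter,best_friend,meet_freq
# nodes.csv  : node_id,sex,ethnicity_majority,ses_high,participates_<W>,...
# ---------------------------------------------------------------------------

def read_panel(edges_path: str | Path, nodes_path: str | Path,
               setting_id: str | None = None) -> Panel:
    """Read a panel from the two-file CSV schema.

    Rows violating an invariant (self-ties, unknown nodes, egos who reported
    ties without participating) are rejected with line-numbered diagnostics.
    """
    edges_path, nodes_path = Path(edges_path), Path(nodes_path)
    nodes = pd.read_csv(nodes_path, dtype={"node_id": str})
    required = {"node_id", *ATTRIBUTE_COLUMNS}
    if not required.issubset(nodes.columns):
        raise PanelValidationError(
            f"{nodes_path}: missing columns {sorted(required - set(nodes.columns))}"
        )
    part_cols = [c for c in nodes.columns if c.startswith("participates_")]
    if not part_cols:
        raise PanelValidationError(f"{nodes_path}: no participates_<wave> columns")
    wave_labels = [c.removeprefix("participates_") for c in part_cols]

    roster = nodes["node_id"].tolist()
    attributes = nodes.set_index("node_id")[list(ATTRIBUTE_COLUMNS)].astype(int)
    participation = nodes.set_index("node_id")[part_cols].astype(bool)
    participation.columns = wave_labels

    edges = pd.read_csv(edges_path, dtype={"ego": str, "alter": str, "wave": str})
    required_e = {"wave", "ego", "alter"}
    if not required_e.issubset(edges.columns):
        raise PanelValidationError(
            f"{edges_path}: missing columns {sorted(required_e - set(edges.columns))}"
        )
    for col, default in (("best_friend", 0), ("meet_freq", 1)):
        if col not in edges.columns:
            logger.warning("%s: column %r absent, defaulting to %d", edges_path, col, default)
            edges[col] = default
        else:
            n_missing = int(edges[col].isna().sum())
            if n_missing:
                logger.warning("%s: %d missing %r values defaulted to %d",
                               edges_path, n_missing, col, default)
            edges[col] = edges[col].fillna(default)

    roster_set = set(roster)
    problems: list[str] = []
    per_wave: dict[str, dict[tuple[str, str], tuple[int, int]]] = {w: {} for w in wave_labels}
    # +2: header line plus 1-based numbering
    for line_no, row in enumerate(edges.itertuples(index=False), start=2):
        wave, ego, alter = row.wave, row.ego, row.alter
        if wave not in per_wave:
            problems.append(f"line {line_no}: unknown wave {wave!r}")
            continue
        if ego == alter:
            problems.append(f"line {line_no}: self-tie {ego!r} -> {alter!r}")
            continue
        if ego not in roster_set or alter not in roster_set:
            problems.append(f"line {line_no}: endpoint not on roster ({ego!r}, {alter!r})")
            continue
        per_wave[wave][(ego, alter)] = (int(row.best_friend), int(row.meet_freq))
    if problems:
        raise PanelValidationError(f"{edges_path}: " + "; ".join(problems))

    waves = [WaveNetwork(w, per_wave[w]) for w in wave_labels]
    return Panel(
        setting_id=setting_id if setting_id is not None else edges_path.parent.name,
        roster=roster,
        attributes=attributes,
        waves=waves,
        participation=participation,
    )


def write_panel(panel: Panel, out_dir: str | Path) -> dict[str, Path]:
    """Write a panel to ``out_dir`` as edges.csv + nodes.csv.

    Output is byte-stable under fixed column and row order, so
    ``read_panel(*write_panel(p).values()) == p``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges_path = out_dir / "edges.csv"
    nodes_path = out_dir / "nodes.csv"

    rows = []
    for wave in panel.waves:
        for (ego, alter) in sorted(wave.edges):
            bf, mf = wave.edges[(ego, alter)]
            rows.append((wave.wave_label, ego, alter, bf, mf))
    pd.DataFrame(rows, columns=["wave", "ego", "alter", "best_friend", "meet_freq"]).to_csv(
        edges_path, index=False
    )

    nodes = panel.attributes.loc[panel.roster, list(ATTRIBUTE_COLUMNS)].astype(int).copy()
    for label in panel.wave_labels:
        nodes[f"participates_{label}"] = panel.participation.loc[panel.roster, label].astype(int).values
    nodes.index.name = "node_id"
    nodes.reset_index().to_csv(nodes_path, index=False)
    return {"edges": edges_path, "nodes": nodes_path}
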