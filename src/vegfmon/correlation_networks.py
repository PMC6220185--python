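"""Phase-specific Pearson correlation networks of biomarkers.

Pairwise correlations between per-patient biomarker summaries are computed
within treatment phases (pre-treatment, VEGFi monotherapy, combination
therapy) and classified for display: |r| >= 0.5 solid, 0.35 <= |r| < 0.5
dotted, |r| < 0.35 hidden.  Comparing snapshots across phases reports
induced (newly displayed) and lost edges — the drug-induced re-wiring of
the biomarker network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .synthetic_cohort import CohortDataset

__all__ = [
    "NetworkSnapshot",
    "EdgeChange",
    "DEFAULT_PHASES",
    "SOLID_CUTOFF",
    "DOTTED_CUTOFF",
    "build_network",
    "classify_edges",
    "diff_networks",
]

SOLID_CUTOFF = 0.5
DOTTED_CUTOFF = 0.35

#: Default phase windows (day ranges, inclusive): pre-treatment up to day 0,
#: monotherapy days 1-14, combination days 15-180 (up to six months).
DEFAULT_PHASES = {
    "pretreatment": (-14.0, 0.0),
    "monotherapy": (1.0, 14.0),
    "combination": (15.0, 180.0),
}


@dataclass
class NetworkSnapshot:
    """Phase-labeled correlation matrix with classified edges."""

    phase: str
    nodes: list[str]
    r_matrix: pd.DataFrame
    n_pairs: pd.DataFrame
    edge_class: pd.DataFrame
    window: tuple[float, float]
    value_mode: str

    def edges(self, displayed_only: bool = False) -> pd.DataFrame:
        """Long edge list (node_a, node_b, r, n, edge_class, phase)."""
        rows = []
        for i, a in enumerate(self.nodes):
            for b in self.nodes[i + 1:]:
                cls = self.edge_class.loc[a, b]
                if displayed_only and cls == "hidden":
                    continue
                rows.append((a, b, self.r_matrix.loc[a, b],
                             int(self.n_pairs.loc[a, b]), cls, self.phase))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "n",
                                           "edge_class", "phase"])

    def to_graph(self):
        """Displayed edges as a networkx graph."""
        import networkx as nx

        g = nx.Graph(phase=self.phase)
        g.add_nodes_from(self.nodes)
        for _, row in self.edges(displayed_only=True).iterrows():
            g.add_edge(row["node_a"], row["node_b"], r=row["r"],
                       style=row["edge_class"])
        return g


@dataclass
class EdgeChange:
    node_a: str
    node_b: str
    r_from: float
    r_to: float
    delta_r: float
    class_from: str
    class_to: str
    transition: str  # induced | lost | reclassified | unchanged


def classify_edges(r: float) -> str:
    """Display class for a correlation coefficient.

    |r| >= 0.5 -> ``solid``; 0.35 <= |r| < 0.5 -> ``dotted``; smaller (or
    undefined) -> ``hidden``.
    """
    if r is None or (isinstance(r, float) and math.isnan(r)):
        return "hidden"
    a = abs(float(r))
    if a >= SOLID_CUTOFF:
        return "solid"
    if a >= DOTTED_CUTOFF:
        return "dotted"
    return "hidden"


def _patient_summaries(dataset: CohortDataset, window: tuple[float, float],
                       value_mode: str,
                       log2_markers: set[str] | None) -> pd.DataFrame:
    """Per-patient median of in-window values, one column per biomarker."""
    lo, hi = window
    meas = dataset.measurements
    rows = {}
    for marker, grp in meas.groupby("biomarker", sort=True):
        use_log2 = log2_markers is None or marker in log2_markers
        col = {}
        for pid, pg in grp.groupby("patient_id", sort=False):
            inw = pg[(pg["time_days"] >= lo) & (pg["time_days"] <= hi)]
            if inw.empty:
                continue
            vals = inw["value"].to_numpy(float)
            if value_mode == "log2-ratio-to-baseline":
                base = dataset.baseline_value(pid, marker)
                if base <= 0 or np.any(vals <= 0):
                    continue
                vals = np.log2(vals / base)
            elif value_mode == "level":
                if use_log2:
                    if np.any(vals <= 0):
                        continue
                    vals = np.log2(vals)
            else:
                raise ValueError(f"unknown value mode: {value_mode!r}")
            col[pid] = float(np.median(vals))
        rows[marker] = col
    return pd.DataFrame(rows)


def build_network(dataset: CohortDataset,
                  phase_window: tuple[float, float],
                  value_mode: str = "level",
                  *,
                  phase: str = "",
                  log2_markers: set[str] | None = None,
                  min_pairs: int = 3,
                  min_patients: int = 10) -> NetworkSnapshot:
    """Pairwise Pearson correlation network over one phase window.

    Each patient contributes the median of their in-window values per
    biomarker; correlations are computed across patients using
    pairwise-complete cases.  ``value_mode`` is ``"level"`` (circulating
    markers on the log2 scale unless ``log2_markers`` restricts the set) or
    ``"log2-ratio-to-baseline"``.  Pairs with fewer than ``min_pairs``
    complete cases have undefined r (NaN, classified hidden).
    """
    summ = _patient_summaries(dataset, phase_window, value_mode, log2_markers)
    nodes = list(summ.columns)
    if len(nodes) < 2:
        raise ValueError("need at least two biomarkers to build a network")
    max_complete = 0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            max_complete = max(max_complete,
                               int(summ[[a, b]].dropna().shape[0]))
    if max_complete < min_patients:
        raise ValueError(
            f"fewer than {min_patients} patients contribute paired values "
            "for every biomarker pair"
        )
    r = pd.DataFrame(np.eye(len(nodes)), index=nodes, columns=nodes)
    n = pd.DataFrame(0, index=nodes, columns=nodes, dtype=int)
    for a in nodes:
        n.loc[a, a] = int(summ[a].notna().sum())
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            pair = summ[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if len(pair) < min_pairs:
                val = float("nan")
            else:
                x = pair[a].to_numpy(float)
                y = pair[b].to_numpy(float)
                sx, sy = x.std(ddof=1), y.std(ddof=1)
                if sx == 0 or sy == 0:
                    val = float("nan")
                else:
                    val = float(np.corrcoef(x, y)[0, 1])
            r.loc[a, b] = r.loc[b, a] = val
    cls = r.map(lambda v: classify_edges(v))
    for a in nodes:
        cls.loc[a, a] = "self"
    return NetworkSnapshot(
        phase=phase or f"days {phase_window[0]:g}..{phase_window[1]:g}",
        nodes=nodes, r_matrix=r, n_pairs=n, edge_class=cls,
        window=tuple(float(v) for v in phase_window), value_mode=value_mode,
    )


def diff_networks(a: NetworkSnapshot, b: NetworkSnapshot):
    """Edge-change report between two phase snapshots.

    Returns ``(changes, summary)`` where ``changes`` is a list of
    :class:`EdgeChange` (one per biomarker pair) and ``summary`` holds the
    median delta-r and counts of induced/lost edges.  An edge is *induced*
    when it becomes displayed (hidden -> dotted/solid) and *lost* when it
    stops being displayed.
    """
    if set(a.nodes) != set(b.nodes):
        only_a = sorted(set(a.nodes) - set(b.nodes))
        only_b = sorted(set(b.nodes) - set(a.nodes))
        raise ValueError(
            f"node sets differ: only in first {only_a}, only in second {only_b}"
        )
    changes: list[EdgeChange] = []
    deltas = []
    for i, na in enumerate(a.nodes):
        for nb in a.nodes[i + 1:]:
            r0 = float(a.r_matrix.loc[na, nb])
            r1 = float(b.r_matrix.loc[na, nb])
            c0 = a.edge_class.loc[na, nb]
            c1 = b.edge_class.loc[na, nb]
            if c0 == c1:
                trans = "unchanged"
            elif c0 == "hidden":
                trans = "induced"
            elif c1 == "hidden":
                trans = "lost"
            else:
                trans = "reclassified"
            d = r1 - r0
            if np.isfinite(d):
                deltas.append(d)
            changes.append(EdgeChange(na, nb, r0, r1, d, c0, c1, trans))
    summary = {
        "median_delta_r": float(np.median(deltas)) if deltas else float("nan"),
        "n_induced": sum(c.transition == "induced" for c in changes),
        "n_lost": sum(c.transition == "lost" for c in changes),
        "n_reclassified": sum(c.transition == "reclassified" for c in changes),
        "n_pairs": len(changes),
    }
    return changes, summary
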