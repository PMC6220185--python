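"""Unsupervised clustering of per-patient biomarker trajectories.

Trajectories are interpolated onto a common visit grid, compared by
correlation distance (1 - Pearson r between trajectory vectors) and cut
into two cohorts by average-linkage agglomerative clustering — separating
e.g. patients with an immediate transient biomarker reduction from those
with a later but sustained one.  The cluster labels learned on one
biomarker can be projected onto another biomarker's trajectories to ask
whether the two markers co-move (rank-sum comparison of per-patient
summaries between clusters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .synthetic_cohort import CohortDataset

__all__ = [
    "ClusterAssignment",
    "ClusterComparison",
    "DEFAULT_CLUSTER_GRID",
    "cluster_trajectories",
    "compare_cluster_summaries",
    "project_clusters",
]

#: Nominal visit-day grid used to align trajectories.
DEFAULT_CLUSTER_GRID = (3.0, 8.0, 15.0, 22.0, 42.0, 70.0, 98.0, 126.0, 154.0, 182.0)


@dataclass
class ClusterAssignment:
    """Two-cohort assignment from correlation-distance clustering."""

    labels: dict[str, int]  # patient_id -> 1 or 2
    linkage: str
    distance: str
    biomarker: str
    grid: list[float]
    degenerate: bool = False

    def members(self, label: int) -> list[str]:
        return sorted(p for p, c in self.labels.items() if c == label)


@dataclass
class ClusterComparison:
    """Rank-sum comparison of per-patient summaries between two clusters."""

    biomarker: str
    statistic: float | None
    p_value: float | None
    medians: dict[int, float]
    summaries: dict[str, float] = field(repr=False, default_factory=dict)
    curves: pd.DataFrame | None = field(repr=False, default=None)
    evaluable: bool = True


def _trajectory_matrix(dataset: CohortDataset, biomarker: str,
                       grid: np.ndarray) -> pd.DataFrame:
    """Per-patient log2-ratio-to-baseline trajectories on the common grid.

    Values are linearly interpolated within each patient's observed span;
    grid points before the first or after the last observation are left
    missing rather than extrapolated.
    """
    meas = dataset.measurements
    sub = meas[(meas["biomarker"] == biomarker) & (meas["replicate"] == 0)
               & (meas["time_days"] > 0)]
    rows = {}
    for pid, grp in sub.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_days")
        t = grp["time_days"].to_numpy(float)
        v = grp["value"].to_numpy(float)
        if len(t) < 3:
            continue
        base = dataset.baseline_value(pid, biomarker)
        if base <= 0 or np.any(v <= 0):
            continue
        y = np.log2(v / base)
        interp = np.interp(grid, t, y)
        interp[(grid < t[0]) | (grid > t[-1])] = np.nan
        rows[pid] = interp
    return pd.DataFrame(rows, index=grid).T


def _pairwise_correlation_distance(mat: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson r distance using pairwise-complete grid points."""
    ids = list(mat.index)
    n = len(ids)
    d = np.zeros((n, n))
    arr = mat.to_numpy(float)
    for i in range(n):
        for j in range(i + 1, n):
            both = np.isfinite(arr[i]) & np.isfinite(arr[j])
            if both.sum() < 3:
                dist = 1.0  # uninformative: treat as uncorrelated
            else:
                x, y = arr[i, both], arr[j, both]
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    dist = 0.0 if np.allclose(x, y) else 1.0
                else:
                    dist = 1.0 - float(np.corrcoef(x, y)[0, 1])
            d[i, j] = d[j, i] = max(dist, 0.0)
    return d


def cluster_trajectories(dataset: CohortDataset, biomarker: str,
                         grid=DEFAULT_CLUSTER_GRID) -> ClusterAssignment:
    """Cut trajectories into two cohorts by correlation-distance clustering.

    Average-linkage agglomerative clustering on 1 - Pearson r between
    interpolated trajectory vectors, tree cut at k=2.  No thresholds are
    imposed on the trajectories themselves.  Labels are content-defined for
    stability under patient reordering: cluster 1 is the cohort with the
    lower mean trajectory summary (the deeper-decline cohort).
    """
    grid = np.asarray(grid, dtype=float)
    mat = _trajectory_matrix(dataset, biomarker, grid)
    if mat.shape[0] < 2:
        raise ValueError("need at least two patients with >=3 observations")
    d = _pairwise_correlation_distance(mat)
    if np.allclose(d, 0.0):
        labels = {pid: 1 for pid in mat.index}
        return ClusterAssignment(labels, "average", "1 - Pearson r",
                                 biomarker, [float(g) for g in grid],
                                 degenerate=True)
    link = average(squareform(d, checks=False))
    raw = fcluster(link, t=2, criterion="maxclust")
    means = {}
    for lab in np.unique(raw):
        sel = mat.to_numpy(float)[raw == lab]
        means[lab] = float(np.nanmean(sel))
    order = sorted(np.unique(raw), key=lambda lab: (means[lab], lab))
    relabel = {old: new for new, old in enumerate(order, start=1)}
    labels = {pid: int(relabel[lab]) for pid, lab in zip(mat.index, raw)}
    return ClusterAssignment(labels, "average", "1 - Pearson r", biomarker,
                             [float(g) for g in grid])


def _patient_summary(dataset: CohortDataset, biomarker: str) -> dict[str, float]:
    """Per-patient mean log2 ratio to baseline over on-treatment visits."""
    meas = dataset.measurements
    sub = meas[(meas["biomarker"] == biomarker) & (meas["replicate"] == 0)
               & (meas["time_days"] > 0)]
    out = {}
    for pid, grp in sub.groupby("patient_id", sort=True):
        v = grp["value"].to_numpy(float)
        base = dataset.baseline_value(pid, biomarker)
        if base <= 0 or np.any(v <= 0):
            continue
        out[pid] = float(np.mean(np.log2(v / base)))
    return out


def _cluster_curves(dataset: CohortDataset, biomarker: str,
                    assignment: ClusterAssignment,
                    grid: np.ndarray) -> pd.DataFrame:
    """Per-cluster median curves with standard errors per time point."""
    mat = _trajectory_matrix(dataset, biomarker, grid)
    rows = []
    for lab in (1, 2):
        ids = [p for p in assignment.members(lab) if p in mat.index]
        if not ids:
            continue
        sel = mat.loc[ids].to_numpy(float)
        for k, t in enumerate(grid):
            col = sel[:, k]
            col = col[np.isfinite(col)]
            if len(col) == 0:
                continue
            rows.append((lab, float(t), float(np.median(col)),
                         float(np.std(col, ddof=1) / np.sqrt(len(col)))
                         if len(col) > 1 else 0.0,
                         int(len(col))))
    return pd.DataFrame(rows, columns=["cluster", "time_days", "median",
                                       "se", "n"])


def compare_cluster_summaries(assignment: ClusterAssignment,
                              dataset: CohortDataset,
                              biomarker: str) -> ClusterComparison:
    """Mann-Whitney U comparison of per-patient summaries between clusters.

    The comparand is each patient's mean log2 ratio to baseline over
    treatment.  Also returns per-cluster median curves with standard
    errors on the common grid for plotting.
    """
    summaries = _patient_summary(dataset, biomarker)
    groups = {lab: [summaries[p] for p in assignment.members(lab)
                    if p in summaries]
              for lab in (1, 2)}
    grid = np.asarray(assignment.grid, dtype=float)
    curves = _cluster_curves(dataset, biomarker, assignment, grid)
    if min(len(groups[1]), len(groups[2])) < 2:
        return ClusterComparison(biomarker, None, None,
                                 {lab: (float(np.median(v)) if v else float("nan"))
                                  for lab, v in groups.items()},
                                 summaries, curves, evaluable=False)
    stat, p = stats.mannwhitneyu(groups[1], groups[2], alternative="two-sided")
    return ClusterComparison(
        biomarker=biomarker,
        statistic=float(stat),
        p_value=float(p),
        medians={lab: float(np.median(v)) for lab, v in groups.items()},
        summaries=summaries,
        curves=curves,
    )


def project_clusters(assignment: ClusterAssignment, dataset: CohortDataset,
                     other_biomarker: str) -> ClusterComparison:
    """Re-use one biomarker's cluster labels on another biomarker.

    Summarises and tests the other biomarker's trajectories between the
    cluster-defined patient groups (e.g. Tie2-derived clusters projected
    onto K-trans or CK18).
    """
    if other_biomarker not in dataset.biomarkers():
        raise ValueError(f"biomarker {other_biomarker!r} absent from dataset")
    return compare_cluster_summaries(assignment, dataset, other_biomarker)
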