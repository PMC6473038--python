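"""Agglomerative clustering of 3-D foci under Ward's criterion.

The dissimilarity between two clusters A and B is the increase in
within-cluster sum of squares caused by merging them,

    cost(A, B) = |A| |B| / (|A| + |B|) * ||c_A - c_B||^2   [mm^2],

where c_A, c_B are the cluster centroids.  Greedy agglomeration under this
cost yields a monotone merge sequence (Ward linkage is reducible).  The
dendrogram is then cut at a *spatial resolution*: the coarsest partition
whose mean (over clusters) per-axis standard deviation does not exceed the
resolution on any axis — 5 mm by default, the scale at which activation
peaks from different studies are considered anatomically coherent.

Ties between equal-cost merges are broken toward the smallest
(left, right) cluster-index pair, making the sequence deterministic given
input order.  Cluster indices follow the scipy convention: originals are
0..N-1, the cluster created by merge step k is N+k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DatasetError

__all__ = [
    "MergeStep",
    "ClusterSolution",
    "ward_linkage",
    "cut_at_resolution",
    "summarize_clusters",
    "write_cluster_report",
]


@dataclass(frozen=True)
class MergeStep:
    """One agglomeration step: clusters ``left`` and ``right`` are merged."""

    left: int
    right: int
    cost: float  # Ward objective increase, mm^2
    new_size: int


@dataclass
class ClusterSolution:
    """A partition of foci with per-cluster summaries.

    ``assignment`` maps each focus (input order) to a cluster id in
    ``0..K-1``; ids are ordered by first member occurrence.  ``summaries``
    is one row per cluster: size, centroid (mm), per-axis sample standard
    deviation (0 for singletons) and, once labels are attached, one count
    column per label.
    """

    assignment: np.ndarray
    summaries: pd.DataFrame
    resolution_mm: float | None = None
    label_set: tuple[str, ...] = ()

    @property
    def n_clusters(self) -> int:
        return int(self.summaries.shape[0])

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster_id)

    def centroids(self) -> np.ndarray:
        return self.summaries[["x", "y", "z"]].to_numpy(dtype=float)


def _ward_cost(size_a, size_b, cent_a, cent_b) -> np.ndarray:
    d2 = np.sum((np.asarray(cent_a) - np.asarray(cent_b)) ** 2, axis=-1)
    return size_a * size_b / (size_a + size_b) * d2


def ward_linkage(points: Sequence[Sequence[float]]) -> list[MergeStep]:
    """Full greedy Ward merge sequence for a set of 3-D points.

    Returns N-1 :class:`MergeStep` in merge order.  Each step merges the
    active pair with the smallest ESS increase; exact ties resolve to the
    smallest (left, right) index pair.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise DatasetError("ward_linkage requires at least one point")
    n = pts.shape[0]
    if n == 1:
        return []

    m = 2 * n - 1  # total clusters ever created
    cent = np.zeros((m, pts.shape[1]))
    size = np.zeros(m, dtype=int)
    cent[:n] = pts
    size[:n] = 1
    active = np.zeros(m, dtype=bool)
    active[:n] = True

    # full symmetric cost matrix over ever-created clusters; inf where inactive
    cost = np.full((m, m), np.inf)
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    cost[:n, :n] = 0.5 * d2
    np.fill_diagonal(cost, np.inf)

    steps: list[MergeStep] = []
    for k in range(n - 1):
        sub = cost[: n + k, : n + k]
        # row-major argmin -> smallest (i, j) among ties; keep i < j
        flat = int(np.argmin(sub))
        i, j = divmod(flat, n + k)
        if i > j:
            i, j = j, i
        c = float(sub[i, j])
        new = n + k
        sz = int(size[i] + size[j])
        cent[new] = (size[i] * cent[i] + size[j] * cent[j]) / sz
        size[new] = sz
        active[i] = active[j] = False
        cost[i, :] = np.inf
        cost[:, i] = np.inf
        cost[j, :] = np.inf
        cost[:, j] = np.inf
        idx = np.flatnonzero(active[: n + k + 1])
        if idx.size:
            cc = _ward_cost(sz, size[idx], cent[new], cent[idx])
            cost[new, idx] = cc
            cost[idx, new] = cc
        active[new] = True
        steps.append(MergeStep(left=i, right=j, cost=c, new_size=sz))
    return steps


def _replay(merges: list[MergeStep], n: int, n_steps: int) -> np.ndarray:
    """Assignment after the first ``n_steps`` merges; ids by first occurrence."""
    parent = np.arange(2 * n - 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for k in range(n_steps):
        s = merges[k]
        parent[find(s.left)] = n + k
        parent[find(s.right)] = n + k
    roots = np.array([find(i) for i in range(n)])
    _, first = np.unique(roots, return_index=True)
    order = {roots[i]: rank for rank, i in enumerate(sorted(first))}
    return np.array([order[r] for r in roots], dtype=int)


def _per_axis_sd(pts: np.ndarray) -> np.ndarray:
    """Sample (n-1) per-axis sd; defined as 0 for singletons."""
    if pts.shape[0] < 2:
        return np.zeros(pts.shape[1])
    return pts.std(axis=0, ddof=1)


def _summaries_for(pts: np.ndarray, assignment: np.ndarray) -> pd.DataFrame:
    rows = []
    for cid in range(int(assignment.max()) + 1):
        sel = pts[assignment == cid]
        cen = sel.mean(axis=0)
        sd = _per_axis_sd(sel)
        rows.append(
            {
                "cluster_id": cid,
                "size": sel.shape[0],
                "x": cen[0],
                "y": cen[1],
                "z": cen[2],
                "sd_x": sd[0],
                "sd_y": sd[1],
                "sd_z": sd[2],
            }
        )
    return pd.DataFrame(rows).set_index("cluster_id")


def cut_at_resolution(
    merges: list[MergeStep],
    points: Sequence[Sequence[float]],
    resolution_mm: float = 5.0,
    criterion: Literal["mean", "max"] = "mean",
) -> ClusterSolution:
    """Cut the dendrogram at a spatial resolution.

    Returns the *coarsest* partition on the dendrogram (fewest clusters)
    such that, on each axis separately, the chosen statistic of the
    per-cluster standard deviations does not exceed ``resolution_mm``:

    - ``criterion="mean"`` (default): the mean over clusters of the
      per-cluster per-axis sd;
    - ``criterion="max"``: the maximum over clusters.

    The all-singletons partition has sd 0 everywhere, so a valid cut always
    exists.  Raising the resolution never increases the number of clusters
    (nested cuts).
    """
    if resolution_mm <= 0:
        raise ValueError("resolution_mm must be positive")
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if len(merges) != max(n - 1, 0):
        raise DatasetError("merge sequence does not match the point set")

    # incremental per-cluster sufficient statistics along the merge walk
    m = 2 * n - 1 if n > 1 else 1
    s1 = np.zeros((m, 3))
    s2 = np.zeros((m, 3))
    cnt = np.zeros(m, dtype=int)
    s1[:n] = pts
    s2[:n] = pts**2
    cnt[:n] = 1

    def sd_of(i: int) -> np.ndarray:
        if cnt[i] < 2:
            return np.zeros(3)
        var = (s2[i] - s1[i] ** 2 / cnt[i]) / (cnt[i] - 1)
        return np.sqrt(np.maximum(var, 0.0))

    sd_sum = np.zeros(3)  # sum over active clusters of per-axis sd
    stat = np.zeros((n, 3))  # stat[k] = criterion value after k merges
    if criterion == "max":
        alive = np.ones(m, dtype=bool)

    for k, step in enumerate(merges, start=1):
        new = n + k - 1
        s1[new] = s1[step.left] + s1[step.right]
        s2[new] = s2[step.left] + s2[step.right]
        cnt[new] = cnt[step.left] + cnt[step.right]
        if criterion == "mean":
            sd_sum += sd_of(new) - sd_of(step.left) - sd_of(step.right)
            stat[k] = sd_sum / (n - k)
        else:
            alive[step.left] = alive[step.right] = False
            act = np.flatnonzero(alive[: n + k])
            stat[k] = np.array([sd_of(i) for i in act]).max(axis=0)

    # coarsest level: fewest clusters = most merges applied
    n_steps = 0
    for k in range(n - 1, -1, -1):
        if np.all(stat[k] <= resolution_mm + 1e-12):
            n_steps = k
            break
    assignment = _replay(merges, n, n_steps) if n > 1 else np.zeros(1, dtype=int)
    return ClusterSolution(
        assignment=assignment,
        summaries=_summaries_for(pts, assignment),
        resolution_mm=resolution_mm,
    )


def summarize_clusters(
    solution: ClusterSolution,
    labels: Sequence[str],
    points: Sequence[Sequence[float]] | None = None,
) -> ClusterSolution:
    """Attach per-cluster label counts to a solution.

    ``labels`` must align with the points that produced the solution.  The
    returned solution's summaries gain one ``n_<label>`` column per distinct
    label; counts per cluster sum to the cluster size.  Rows are sorted by
    cluster id.
    """
    labels = tuple(labels)
    if len(labels) != len(solution.assignment):
        raise DatasetError(
            f"got {len(labels)} labels for {len(solution.assignment)} foci"
        )
    label_set = tuple(dict.fromkeys(labels))  # stable order of appearance
    summ = solution.summaries.copy()
    for lab in label_set:
        mask = np.array([l == lab for l in labels])
        summ[f"n_{lab}"] = [
            int(mask[solution.assignment == cid].sum()) for cid in summ.index
        ]
    if points is not None:
        pts = np.asarray(points, dtype=float)
        if pts.shape[0] != len(labels):
            raise DatasetError("points/labels length mismatch")
    return ClusterSolution(
        assignment=solution.assignment.copy(),
        summaries=summ.sort_index(),
        resolution_mm=solution.resolution_mm,
        label_set=label_set,
    )


def write_cluster_report(solution: ClusterSolution, target, sep: str = "\t") -> None:
    """TSV report: cluster id, k (size), centroid x/y/z, per-axis sd, counts."""
    df = solution.summaries.rename(columns={"size": "k"})
    df.to_csv(target, sep=sep, float_format="%.3f")
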