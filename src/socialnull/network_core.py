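"""Network construction from observation data and node/dyad summaries.

Edge weights use the simple ratio index (SRI).  For a dyad (i, j),

    SRI(i, j) = x / (x + y_i + y_j)

where x is the number of sampling events containing both individuals and
y_i (y_j) the number containing only i (only j).  Because each GBI row is one
sighting event, "seen but not together" cannot occur within a row, so the
denominator is simply the number of events containing i or j or both; 0/0 is
defined as 0.  The SRI estimates the proportion of time a dyad spends
associated under even sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import (
    FocalSampleSet,
    GroupByIndividualMatrix,
    NodeTable,
    TrajectorySet,
    WeightedNetwork,
)

__all__ = [
    "simple_ratio_index",
    "cooccurrence_counts",
    "focal_to_gbi",
    "trajectories_to_gbi",
    "weighted_degree",
    "binary_degree",
    "threshold_at_median",
    "DyadCategoryMatrix",
    "dyad_category_matrix",
    "network_metric",
]


def simple_ratio_index(gbi: GroupByIndividualMatrix) -> WeightedNetwork:
    """Simple-ratio-index association network from a GBI matrix."""
    x = gbi.membership.astype(np.float64)
    both = x.T @ x
    counts = np.diagonal(both).copy()
    either = counts[:, None] + counts[None, :] - both
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(either > 0, both / np.where(either > 0, either, 1.0), 0.0)
    np.fill_diagonal(sri, 0.0)
    return WeightedNetwork(sri, list(gbi.individual_ids))


def cooccurrence_counts(gbi: GroupByIndividualMatrix) -> WeightedNetwork:
    """Raw per-dyad co-occurrence counts (the SRI numerator) as edge weights."""
    x = gbi.membership.astype(np.float64)
    both = x.T @ x
    np.fill_diagonal(both, 0.0)
    return WeightedNetwork(both, list(gbi.individual_ids))


def focal_to_gbi(focals: FocalSampleSet) -> GroupByIndividualMatrix:
    """Recast focal samples as a GBI: one row per sample, members = focal + associates.

    Two samples sharing the same members stay distinct rows; sample times and
    locations are carried over as event metadata.
    """
    ids = list(focals.individual_ids)
    idx = {ind: j for j, ind in enumerate(ids)}
    k = len(focals)
    membership = np.zeros((k, len(ids)), dtype=np.int8)
    times = np.zeros(k, dtype=np.int64)
    locations = []
    any_loc = False
    for r, s in enumerate(focals):
        for ind in s.members:
            membership[r, idx[ind]] = 1
        times[r] = s.time
        locations.append(s.location)
        any_loc = any_loc or s.location is not None
    return GroupByIndividualMatrix(
        membership,
        ids,
        event_time=times,
        event_location=np.asarray(locations, dtype=object) if any_loc else None,
    )


def _cluster_by_chebyshev(points: np.ndarray, radius: int) -> np.ndarray:
    """Single-linkage clusters of points within Chebyshev distance ``radius``."""
    n = len(points)
    labels = np.arange(n)

    def find(a):
        while labels[a] != a:
            labels[a] = labels[labels[a]]
            a = labels[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            if np.abs(points[a] - points[b]).max() <= radius:
                ra, rb = find(a), find(b)
                if ra != rb:
                    labels[rb] = ra
    return np.array([find(a) for a in range(n)])


def trajectories_to_gbi(
    traj: TrajectorySet, cooccurrence_radius: int = 0
) -> GroupByIndividualMatrix:
    """Gambit-of-the-group events from synchronous grid positions.

    One event is emitted per (day, step, occupied cell) — or, for
    ``cooccurrence_radius`` > 0, per single-linkage cluster of individuals
    within that Chebyshev radius at the same step.  ``event_day`` holds the
    0-based day and ``event_time`` the global step index, so "same period"
    swap restrictions operate on synchronous events.
    """
    n, d, s = traj.n_individuals, traj.n_days, traj.steps_per_day
    obs = traj.observed_mask()
    if cooccurrence_radius == 0:
        # fast path: one event per (step, cell); vectorised over all points
        w, h = traj.grid_shape
        ind, dd, ss = np.nonzero(obs)
        t = dd * s + ss
        cell = traj.positions[ind, dd, ss, 0] * h + traj.positions[ind, dd, ss, 1]
        key = t * (w * h) + cell
        uniq, inv = np.unique(key, return_inverse=True)
        membership = np.zeros((uniq.size, n), dtype=np.int8)
        membership[inv, ind] = 1
        times_arr = uniq // (w * h)
        return GroupByIndividualMatrix(
            membership,
            list(traj.individual_ids),
            event_time=times_arr,
            event_day=times_arr // s,
        )
    rows: list[np.ndarray] = []
    days: list[int] = []
    times: list[int] = []
    for day in range(d):
        for step in range(s):
            present = np.nonzero(obs[:, day, step])[0]
            if present.size == 0:
                continue
            pts = traj.positions[present, day, step]
            labels = _cluster_by_chebyshev(pts, cooccurrence_radius)
            for lab in np.unique(labels):
                members = present[labels == lab]
                row = np.zeros(n, dtype=np.int8)
                row[members] = 1
                rows.append(row)
                days.append(day)
                times.append(day * s + step)
    membership = (
        np.asarray(rows, dtype=np.int8) if rows else np.zeros((0, n), dtype=np.int8)
    )
    return GroupByIndividualMatrix(
        membership,
        list(traj.individual_ids),
        event_time=np.asarray(times, dtype=np.int64),
        event_day=np.asarray(days, dtype=np.int64),
    )


def weighted_degree(net: WeightedNetwork) -> np.ndarray:
    """Node strength: the sum of each individual's edge weights."""
    return net.adjacency.sum(axis=1)


def binary_degree(net: WeightedNetwork, threshold: float = 0.0) -> np.ndarray:
    """Number of edges strictly above ``threshold`` incident to each node."""
    return (net.adjacency > threshold).sum(axis=1)


def threshold_at_median(net: WeightedNetwork) -> WeightedNetwork:
    """Binarise a network keeping the top 50% of (nonzero) edges.

    The cut point is the median of the nonzero edge weights; an edge survives
    only if its weight is strictly greater than that median, so with all
    weights tied every edge is removed.  Raises on an all-zero network.
    """
    w = net.nonzero_edge_weights()
    if w.size == 0:
        raise ValueError("median thresholding needs at least one nonzero edge")
    med = float(np.median(w))
    binary = (net.adjacency > med).astype(np.float64)
    return WeightedNetwork(binary, list(net.individual_ids))


@dataclass
class DyadCategoryMatrix:
    """Symmetric integer dyad classification (e.g. sex categories).

    For a binary attribute with sorted levels (a, b) — e.g. (F, M) — the
    coding is 1 = both b (both males), 2 = mixed, 3 = both a (both females).
    The diagonal is conventionally 0 (self-dyads are unused).
    """

    values: np.ndarray
    coding: dict[str, int]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64)
        if not np.array_equal(v, v.T):
            raise ValueError("dyad category matrix must be symmetric")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]


def dyad_category_matrix(nodes: NodeTable, attribute: str = "sex") -> DyadCategoryMatrix:
    """Classify every dyad by a binary node attribute.

    With sexes M/F this yields 1 = both males, 2 = male-female, 3 = both
    females.
    """
    vals = nodes.get(attribute)
    levels = sorted(set(map(str, vals.tolist())))
    if set(levels) <= {"F", "M"}:
        lo, hi = "F", "M"  # conventional sex coding even if one sex is absent
    elif len(levels) == 2:
        lo, hi = levels
    else:
        raise ValueError(
            f"attribute {attribute!r} must be binary-valued, got levels {levels}"
        )
    is_hi = np.asarray([str(v) == hi for v in vals])
    # both hi -> 1, mixed -> 2, both lo -> 3
    n = len(vals)
    cat = np.where(
        is_hi[:, None] & is_hi[None, :],
        1,
        np.where(is_hi[:, None] ^ is_hi[None, :], 2, 3),
    ).astype(np.int64)
    np.fill_diagonal(cat, 0)
    coding = {f"{hi}{hi}": 1, f"{hi}{lo}": 2, f"{lo}{lo}": 3}
    return DyadCategoryMatrix(cat, coding, list(nodes.individual_ids))


def network_metric(net: WeightedNetwork, metric: str) -> float:
    """Named scalar network summary.

    ``mean_degree``    mean number of nonzero edges per node
    ``mean_strength``  mean weighted degree
    ``cv_edge_weights`` coefficient of variation (population SD / mean) of
                        the nonzero edge weights
    ``density``        proportion of dyads with a nonzero edge
    """
    if metric == "mean_degree":
        return float(binary_degree(net).mean())
    if metric == "mean_strength":
        return float(weighted_degree(net).mean())
    if metric == "cv_edge_weights":
        w = net.nonzero_edge_weights()
        if w.size == 0:
            raise ValueError("cv_edge_weights needs at least one nonzero edge")
        return float(w.std() / w.mean())
    if metric == "density":
        n = net.n_nodes
        if n < 2:
            return 0.0
        return float(2.0 * np.count_nonzero(net.upper_triangle()) / (n * (n - 1)))
    raise ValueError(f"unknown network metric {metric!r}")
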