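"""Permutation null models for social network data.

Two families are implemented, mirroring how each is used in the field:

* **Network permutations** randomise the mapping of phenotypes onto a fixed
  network: node permutations (optionally restricted within classes such as
  trapping location), and edge permutations which reassign the multiset of
  edge weights to new dyads.

* **Pre-network data permutations** randomise the raw observation data before
  network construction.  The classic data-stream method swaps a checkerboard
  pattern in the group-by-individual matrix (one observation of individual A
  moves from group a to group b and one of B the other way), exactly
  preserving group sizes and per-individual observation counts.  A focal-data
  variant swaps associates between two focal samples with different focals,
  and for autocorrelated movement data the day-shuffle null permutes the day
  labels of each individual's daily tracks within that individual —
  preserving each animal's space use while randomising temporal co-occurrence.
  The track-identity swap (reassigning whole daily tracks *between*
  individuals) is provided as a contrast method; it behaves like a node
  permutation and inherits its limitations.

`run_null_chain` packages both styles behind one runner: data-stream and
focal swaps form a serial Markov chain (the data are incrementally
randomised, so early permutations are close to the observed data — inspect
the stabilisation series before trusting small p-values), while node, edge,
day-shuffle and identity-swap statistics are independent redraws from the
original data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data_model import (
    FocalSample,
    FocalSampleSet,
    GroupByIndividualMatrix,
    NodeTable,
    PermutationResult,
    TrajectorySet,
    WeightedNetwork,
)

__all__ = [
    "SwapRestriction",
    "NullChainSpec",
    "node_permutation",
    "restricted_node_permutation",
    "edge_permutation",
    "find_checkerboard",
    "datastream_swap",
    "focal_swap",
    "trajectory_day_shuffle",
    "track_identity_swap",
    "run_null_chain",
    "SERIAL_METHODS",
    "INDEPENDENT_METHODS",
]

logger = logging.getLogger(__name__)

SERIAL_METHODS = frozenset({"datastream", "focal"})
INDEPENDENT_METHODS = frozenset(
    {"node", "node-restricted", "edge", "day-shuffle", "identity-swap"}
)

#: Default number of candidate draws before a swap search gives up.
DEFAULT_ATTEMPT_BUDGET = 10_000


@dataclass(frozen=True)
class SwapRestriction:
    """Predicates confining swaps to comparable observations.

    ``within_day`` / ``within_time`` / ``within_location`` require the two
    events (or focal samples) involved in a swap to share the respective
    metadata value.  ``within_class`` names a node attribute; only
    individuals sharing that attribute value may be swapped (for focal swaps
    the check applies to the two focal individuals; set
    ``class_applies_to_associates`` to extend it to the swapped associates).
    """

    within_day: bool = False
    within_time: bool = False
    within_location: bool = False
    within_class: str | None = None
    class_applies_to_associates: bool = False

    def validate_for_gbi(self, gbi: GroupByIndividualMatrix, nodes: NodeTable | None):
        if self.within_day and gbi.event_day is None:
            raise ValueError("within_day restriction but GBI has no event_day")
        if self.within_location and gbi.event_location is None:
            raise ValueError(
                "within_location restriction but GBI has no event_location"
            )
        if self.within_class is not None:
            if nodes is None:
                raise ValueError("within_class restriction requires a NodeTable")
            nodes.get(self.within_class)  # raises if absent

    def validate_for_focal(self, focals: FocalSampleSet, nodes: NodeTable | None):
        if self.within_location and any(s.location is None for s in focals):
            raise ValueError(
                "within_location restriction but some focal samples lack a location"
            )
        if self.within_class is not None:
            if nodes is None:
                raise ValueError("within_class restriction requires a NodeTable")
            nodes.get(self.within_class)


@dataclass(frozen=True)
class NullChainSpec:
    """Permutation-run configuration.

    ``n_permutations`` counts recorded statistics; for serial chains each
    record follows ``swaps_per_step`` incremental swaps, after ``burn_in``
    unrecorded swaps.  The default burn-in is 0: rather than imposing a
    hidden burn-in, inspect the stabilisation series and choose one
    explicitly.
    """

    n_permutations: int = 1000
    swaps_per_step: int = 1
    burn_in: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.swaps_per_step < 1:
            raise ValueError("swaps_per_step must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


# ---------------------------------------------------------------------------
# network permutations


def node_permutation(nodes: NodeTable, rng: np.random.Generator) -> NodeTable:
    """Randomise the phenotype-to-node mapping.

    All attribute vectors are permuted jointly by one uniform random
    permutation, so each node keeps a coherent (if reassigned) phenotype and
    the multiset of every attribute is preserved.  The network itself — and
    ``n_observations``, which describes sampling of the node rather than its
    phenotype — are untouched.
    """
    perm = rng.permutation(nodes.n_individuals)
    return NodeTable(
        list(nodes.individual_ids),
        {k: v[perm] for k, v in nodes.attributes.items()},
        None if nodes.n_observations is None else nodes.n_observations.copy(),
    )


def restricted_node_permutation(
    nodes: NodeTable, grouping, rng: np.random.Generator
) -> NodeTable:
    """Node permutation confined within classes of a grouping label.

    ``grouping`` is either the name of a node attribute or an explicit
    per-individual label vector (e.g. primary trapping location).  Attributes
    are permuted independently within each class, so phenotypes never cross
    class boundaries — the restricted swap design used when the null must
    preserve spatial structure.
    """
    if isinstance(grouping, str):
        labels = nodes.get(grouping)
    else:
        labels = np.asarray(grouping)
        if labels.shape != (nodes.n_individuals,):
            raise ValueError("grouping must assign one label per individual")
    perm = np.arange(nodes.n_individuals)
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        perm[members] = members[rng.permutation(members.size)]
    return NodeTable(
        list(nodes.individual_ids),
        {k: v[perm] for k, v in nodes.attributes.items()},
        None if nodes.n_observations is None else nodes.n_observations.copy(),
    )


def edge_permutation(net: WeightedNetwork, rng: np.random.Generator) -> WeightedNetwork:
    """Reassign the multiset of nonzero edge weights to dyads chosen uniformly.

    The number of edges and the weight multiset are preserved exactly;
    symmetry and the zero diagonal are maintained.
    """
    n = net.n_nodes
    iu = np.triu_indices(n, k=1)
    weights = net.adjacency[iu]
    nz = weights[weights > 0]
    if nz.size == 0:
        raise ValueError("edge permutation needs at least one edge")
    n_dyads = iu[0].size
    chosen = rng.choice(n_dyads, size=nz.size, replace=False)
    new = np.zeros((n, n))
    new[iu[0][chosen], iu[1][chosen]] = rng.permutation(nz)
    new = new + new.T
    return WeightedNetwork(new, list(net.individual_ids))


# ---------------------------------------------------------------------------
# data-stream (checkerboard) permutation


def _event_predicate_arrays(gbi, restriction, nodes):
    """Resolve restriction metadata into arrays for vectorised checks."""
    time = gbi.event_time if restriction.within_time else None
    day = gbi.event_day if restriction.within_day else None
    loc = gbi.event_location if restriction.within_location else None
    cls = None
    if restriction.within_class is not None and nodes is not None:
        cls = nodes.get(restriction.within_class)
    return time, day, loc, cls


def find_checkerboard(
    gbi: GroupByIndividualMatrix,
    restriction: SwapRestriction | None = None,
    rng: np.random.Generator | None = None,
    nodes: NodeTable | None = None,
    max_attempts: int = DEFAULT_ATTEMPT_BUDGET,
):
    """Draw a swappable checkerboard (i, j, a, b) by rejection sampling.

    Returns indices with membership[a, i] = 1, membership[a, j] = 0,
    membership[b, i] = 0, membership[b, j] = 1 satisfying every restriction
    predicate, drawn uniformly among candidates (each candidate tuple is
    equally likely on every draw).  Returns ``None`` if no candidate is found
    within ``max_attempts`` draws.
    """
    if rng is None:
        rng = np.random.default_rng()
    restriction = restriction or SwapRestriction()
    restriction.validate_for_gbi(gbi, nodes)
    m = gbi.membership
    k, n = m.shape
    if k < 2 or n < 2:
        return None
    time, day, loc, cls = _event_predicate_arrays(gbi, restriction, nodes)
    batch = 256
    drawn = 0
    while drawn < max_attempts:
        size = min(batch, max_attempts - drawn)
        drawn += size
        ii = rng.integers(0, n, size)
        jj = rng.integers(0, n, size)
        aa = rng.integers(0, k, size)
        bb = rng.integers(0, k, size)
        ok = (ii != jj) & (aa != bb)
        ok &= (m[aa, ii] == 1) & (m[aa, jj] == 0) & (m[bb, ii] == 0) & (m[bb, jj] == 1)
        if time is not None:
            ok &= time[aa] == time[bb]
        if day is not None:
            ok &= day[aa] == day[bb]
        if loc is not None:
            ok &= loc[aa] == loc[bb]
        if cls is not None:
            ok &= cls[ii] == cls[jj]
        hits = np.nonzero(ok)[0]
        if hits.size:
            h = hits[0]
            return int(ii[h]), int(jj[h]), int(aa[h]), int(bb[h])
    logger.debug("checkerboard search exhausted %d attempts", max_attempts)
    return None


def _apply_checkerboard_swap(membership: np.ndarray, i, j, a, b) -> None:
    membership[a, i] = 0
    membership[a, j] = 1
    membership[b, i] = 1
    membership[b, j] = 0


def datastream_swap(
    gbi: GroupByIndividualMatrix,
    restriction: SwapRestriction | None = None,
    rng: np.random.Generator | None = None,
    nodes: NodeTable | None = None,
    max_attempts: int = DEFAULT_ATTEMPT_BUDGET,
) -> GroupByIndividualMatrix:
    """One checkerboard swap applied to a copy of the GBI.

    Exactly four cells flip; all group sizes (row sums) and observation
    counts (column sums) are identical to the input.  If no checkerboard is
    found within the attempt budget the input is returned unchanged with a
    warning.
    """
    out = gbi.copy()
    found = find_checkerboard(out, restriction, rng, nodes, max_attempts)
    if found is None:
        warnings.warn(
            "no swappable checkerboard found within the attempt budget; "
            "data returned unchanged",
            stacklevel=2,
        )
        return out
    _apply_checkerboard_swap(out.membership, *found)
    return out


# ---------------------------------------------------------------------------
# focal-sample permutation


class _FocalWorkspace:
    """Mutable view of a FocalSampleSet for efficient serial swapping."""

    def __init__(self, focals: FocalSampleSet):
        self.template = focals
        self.focals = [s.focal_id for s in focals]
        self.assoc = [set(s.associate_ids) for s in focals]
        self.times = [s.time for s in focals]
        self.locations = [s.location for s in focals]

    def try_swap(self, restriction, rng, nodes, max_attempts) -> bool:
        """Attempt one associate swap; True on success.

        The swap moves associate x from sample a to sample b and associate y
        the other way, subject to: the focals differ, the four individuals
        {focal_a, focal_b, x, y} are distinct, and neither swapped individual
        already occurs in the destination sample (including as its focal).
        Per-sample associate counts and per-individual occurrence totals are
        conserved exactly.
        """
        n = len(self.focals)
        if n < 2:
            return False
        cls = None
        if restriction.within_class is not None and nodes is not None:
            values = nodes.get(restriction.within_class)
            cls = dict(zip(nodes.individual_ids, values))
        for _ in range(max_attempts):
            a, b = rng.integers(0, n, 2)
            if a == b or self.focals[a] == self.focals[b]:
                continue
            if restriction.within_time and self.times[a] != self.times[b]:
                continue
            if restriction.within_day and self.times[a] != self.times[b]:
                continue
            if restriction.within_location and self.locations[a] != self.locations[b]:
                continue
            if cls is not None and cls[self.focals[a]] != cls[self.focals[b]]:
                continue
            sa, sb = self.assoc[a], self.assoc[b]
            if not sa or not sb:
                continue
            x = _draw_from_set(sa, rng)
            y = _draw_from_set(sb, rng)
            if x == y:
                continue
            if x in (self.focals[a], self.focals[b]) or y in (
                self.focals[a],
                self.focals[b],
            ):
                continue
            if x in sb or y in sa:
                continue
            if cls is not None and restriction.class_applies_to_associates:
                if cls[x] != cls[y]:
                    continue
            sa.remove(x)
            sa.add(y)
            sb.remove(y)
            sb.add(x)
            return True
        return False

    def to_focal_set(self) -> FocalSampleSet:
        samples = [
            FocalSample(
                s.sample_id, self.focals[k], frozenset(self.assoc[k]), s.time, s.location
            )
            for k, s in enumerate(self.template)
        ]
        return FocalSampleSet(samples, list(self.template.individual_ids))


def _draw_from_set(s: set, rng: np.random.Generator):
    members = sorted(s)
    return members[rng.integers(0, len(members))]


def focal_swap(
    focals: FocalSampleSet,
    restriction: SwapRestriction | None = None,
    rng: np.random.Generator | None = None,
    nodes: NodeTable | None = None,
    max_attempts: int = DEFAULT_ATTEMPT_BUDGET,
) -> FocalSampleSet:
    """One associate swap between two focal samples, on a copy.

    See `_FocalWorkspace.try_swap` for the legality rules.  If no legal swap
    is found within the budget the input is returned unchanged with a
    warning.
    """
    if rng is None:
        rng = np.random.default_rng()
    restriction = restriction or SwapRestriction()
    restriction.validate_for_focal(focals, nodes)
    ws = _FocalWorkspace(focals)
    if not ws.try_swap(restriction, rng, nodes, max_attempts):
        warnings.warn(
            "no legal focal swap found within the attempt budget; "
            "data returned unchanged",
            stacklevel=2,
        )
    return ws.to_focal_set()


# ---------------------------------------------------------------------------
# trajectory permutations


def trajectory_day_shuffle(
    traj: TrajectorySet, rng: np.random.Generator
) -> TrajectorySet:
    """Permute the day labels of each individual's daily tracks, within individuals.

    Every individual keeps exactly its own multiset of daily tracks — hence
    its full spatial distribution and missingness pattern — but the temporal
    alignment between individuals is randomised.  This is the recommended
    null for autocorrelated movement data.
    """
    if traj.n_days < 2:
        raise ValueError("day shuffle needs at least 2 days")
    pos = traj.positions.copy()
    for i in range(traj.n_individuals):
        pos[i] = pos[i, rng.permutation(traj.n_days)]
    return TrajectorySet(list(traj.individual_ids), pos, tuple(traj.grid_shape))


def track_identity_swap(
    traj: TrajectorySet, rng: np.random.Generator
) -> TrajectorySet:
    """Within each day, reassign that day's tracks among individuals (contrast method).

    The set of tracks present on each day is unchanged, but an individual's
    own multiset of tracks is generally not preserved: whole chunks of data
    move between individuals, which makes this null behave like a node
    permutation (and share its blindness to individual-level sampling
    structure).  Provided for comparison, not recommendation.
    """
    pos = traj.positions.copy()
    for d in range(traj.n_days):
        pos[:, d] = pos[rng.permutation(traj.n_individuals), d]
    return TrajectorySet(list(traj.individual_ids), pos, tuple(traj.grid_shape))


# ---------------------------------------------------------------------------
# chain runner


def _record(statistic_value) -> float:
    v = float(statistic_value)
    return v if np.isfinite(v) else np.nan


def run_null_chain(
    data,
    method: str,
    chain: NullChainSpec,
    statistic: Callable,
    restriction: SwapRestriction | None = None,
    nodes: NodeTable | None = None,
    grouping=None,
    max_attempts: int = DEFAULT_ATTEMPT_BUDGET,
    statistic_name: str | None = None,
) -> PermutationResult:
    """Run a permutation null model and collect the null statistic series.

    ``statistic`` is called as ``statistic(data, nodes)`` and must return a
    real number; non-finite values are recorded as missing and excluded from
    the p-value denominators.  Serial methods (``datastream``, ``focal``)
    mutate a working copy cumulatively: ``chain.burn_in`` swaps are applied
    unrecorded, then the statistic is recorded every ``chain.swaps_per_step``
    swaps, ``chain.n_permutations`` times.  Independent methods (``node``,
    ``node-restricted``, ``edge``, ``day-shuffle``, ``identity-swap``) record
    each statistic on a fresh randomisation of the *original* data.

    A serial step on which no legal swap exists records the unchanged
    statistic and increments ``n_failed_swaps`` — the chain never silently
    loops forever.
    """
    rng = np.random.default_rng(chain.seed)
    restriction = restriction or SwapRestriction()
    observed = _record(statistic(data, nodes))
    nulls = np.empty(chain.n_permutations)
    n_failed = 0

    if method == "datastream":
        if not isinstance(data, GroupByIndividualMatrix):
            raise TypeError("datastream permutation requires a GroupByIndividualMatrix")
        restriction.validate_for_gbi(data, nodes)
        working = data.copy()

        def step() -> bool:
            found = find_checkerboard(working, restriction, rng, nodes, max_attempts)
            if found is None:
                return False
            _apply_checkerboard_swap(working.membership, *found)
            return True

        n_failed_swaps = _run_serial(step, chain, working, nodes, statistic, nulls)
    elif method == "focal":
        if not isinstance(data, FocalSampleSet):
            raise TypeError("focal permutation requires a FocalSampleSet")
        restriction.validate_for_focal(data, nodes)
        ws = _FocalWorkspace(data)

        def step() -> bool:
            return ws.try_swap(restriction, rng, nodes, max_attempts)

        def current():
            return ws.to_focal_set()

        n_failed_swaps = _run_serial_lazy(step, current, chain, nodes, statistic, nulls)
    elif method in INDEPENDENT_METHODS:
        for r in range(chain.n_permutations):
            if method == "node":
                if nodes is None:
                    raise ValueError("node permutation requires a NodeTable")
                nulls[r] = _record(statistic(data, node_permutation(nodes, rng)))
            elif method == "node-restricted":
                if nodes is None:
                    raise ValueError("restricted node permutation requires a NodeTable")
                g = grouping if grouping is not None else restriction.within_class
                if g is None:
                    raise ValueError(
                        "node-restricted needs a grouping label "
                        "(grouping= or restriction.within_class)"
                    )
                nulls[r] = _record(
                    statistic(data, restricted_node_permutation(nodes, g, rng))
                )
            elif method == "edge":
                if not isinstance(data, WeightedNetwork):
                    raise TypeError("edge permutation requires a WeightedNetwork")
                nulls[r] = _record(statistic(edge_permutation(data, rng), nodes))
            elif method == "day-shuffle":
                if not isinstance(data, TrajectorySet):
                    raise TypeError("day-shuffle requires a TrajectorySet")
                nulls[r] = _record(statistic(trajectory_day_shuffle(data, rng), nodes))
            elif method == "identity-swap":
                if not isinstance(data, TrajectorySet):
                    raise TypeError("identity-swap requires a TrajectorySet")
                nulls[r] = _record(statistic(track_identity_swap(data, rng), nodes))
        n_failed_swaps = 0
    else:
        raise ValueError(
            f"unknown null method {method!r}; choose from "
            f"{sorted(SERIAL_METHODS | INDEPENDENT_METHODS)}"
        )

    return PermutationResult.from_series(
        observed,
        nulls,
        seed=chain.seed,
        method=method,
        statistic_name=statistic_name,
        n_failed_swaps=n_failed_swaps,
    )


def _run_serial(step, chain, working, nodes, statistic, nulls) -> int:
    n_failed = 0
    for _ in range(chain.burn_in):
        if not step():
            n_failed += 1
    for r in range(chain.n_permutations):
        for _ in range(chain.swaps_per_step):
            if not step():
                n_failed += 1
        nulls[r] = _record(statistic(working, nodes))
    if n_failed:
        logger.warning("%d serial swap steps found no legal move", n_failed)
    return n_failed


def _run_serial_lazy(step, current, chain, nodes, statistic, nulls) -> int:
    n_failed = 0
    for _ in range(chain.burn_in):
        if not step():
            n_failed += 1
    for r in range(chain.n_permutations):
        for _ in range(chain.swaps_per_step):
            if not step():
                n_failed += 1
        nulls[r] = _record(statistic(current(), nodes))
    if n_failed:
        logger.warning("%d serial swap steps found no legal move", n_failed)
    return n_failed
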