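"""Domain types for observation-based animal social network analysis.

The canonical pre-network container is the group-by-individual (GBI) matrix:
a binary matrix with one row per sampling event (a recorded group) and one
column per individual, 1 meaning the individual was recorded in that event.
Under the gambit of the group, all individuals recorded in the same event are
assumed to be associating.  Focal-sample and trajectory containers cover the
two other common observation modes (focal follows and discretised GPS
tracking); both can be reduced to a GBI for network construction.

All containers validate their invariants on construction and are plain
dataclasses wrapping numpy arrays, so they are cheap to copy inside
permutation chains.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DataFormatError",
    "GroupByIndividualMatrix",
    "FocalSample",
    "FocalSampleSet",
    "TrajectorySet",
    "NodeTable",
    "WeightedNetwork",
    "PermutationResult",
    "MISSING_CELL",
]

#: Sentinel grid coordinate for an unobserved (deleted) trajectory point.
MISSING_CELL = -1


class DataFormatError(ValueError):
    """Raised when an input violates a structural invariant or file format."""


def _check_unique_ids(ids: Sequence[str]) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataFormatError(f"duplicate individual ids: {dupes}")
    return ids


@dataclass
class GroupByIndividualMatrix:
    """Binary event x individual membership matrix with event metadata.

    Parameters
    ----------
    membership
        (K, N) array with entries in {0, 1}; row k lists the members of
        sampling event k.  Every event must contain at least one individual.
        Individuals absent from an event are 0, never missing: the matrix is
        dense by construction (the checkerboard swap is defined on it).
    individual_ids
        N unique strings naming the columns.
    event_time
        (K,) integer sampling-period index.  "Same time period" swap
        restrictions compare these integers for equality; discretisation into
        periods is the data-preparation step's job.  Defaults to all zeros
        (a single period).
    event_day, event_location
        Optional (K,) per-event day index / categorical location label.
    """

    membership: np.ndarray
    individual_ids: list[str]
    event_time: np.ndarray | None = None
    event_day: np.ndarray | None = None
    event_location: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.membership)
        if m.ndim != 2:
            raise DataFormatError("membership must be a 2-D matrix")
        if m.size and not np.isin(m, (0, 1)).all():
            raise DataFormatError("membership entries must be 0 or 1")
        self.membership = m.astype(np.int8)
        self.individual_ids = _check_unique_ids(self.individual_ids)
        k, n = self.membership.shape
        if n != len(self.individual_ids):
            raise DataFormatError(
                f"{len(self.individual_ids)} ids for {n} membership columns"
            )
        if k and (self.membership.sum(axis=1) < 1).any():
            bad = np.where(self.membership.sum(axis=1) < 1)[0]
            raise DataFormatError(f"events with no members at rows {bad.tolist()}")
        if self.event_time is None:
            self.event_time = np.zeros(k, dtype=np.int64)
        else:
            self.event_time = np.asarray(self.event_time, dtype=np.int64)
        for name in ("event_time", "event_day", "event_location"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (k,):
                    raise DataFormatError(f"{name} must have length K={k}")
                setattr(self, name, v)
        if self.event_day is not None:
            self.event_day = np.asarray(self.event_day, dtype=np.int64)

    # -- convenience ------------------------------------------------------

    @property
    def n_events(self) -> int:
        return self.membership.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.membership.shape[1]

    @property
    def group_sizes(self) -> np.ndarray:
        """Per-event group size (row sums)."""
        return self.membership.sum(axis=1)

    @property
    def observation_counts(self) -> np.ndarray:
        """Per-individual number of events attended (column sums)."""
        return self.membership.sum(axis=0)

    def copy(self) -> "GroupByIndividualMatrix":
        return GroupByIndividualMatrix(
            self.membership.copy(),
            list(self.individual_ids),
            None if self.event_time is None else self.event_time.copy(),
            None if self.event_day is None else self.event_day.copy(),
            None if self.event_location is None else self.event_location.copy(),
        )

    def subset_events(self, keep: np.ndarray) -> "GroupByIndividualMatrix":
        """Return a GBI restricted to the events selected by boolean mask ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        return GroupByIndividualMatrix(
            self.membership[keep],
            list(self.individual_ids),
            self.event_time[keep] if self.event_time is not None else None,
            self.event_day[keep] if self.event_day is not None else None,
            self.event_location[keep] if self.event_location is not None else None,
        )


@dataclass(frozen=True)
class FocalSample:
    """One focal follow: a focal individual and the associates recorded with it."""

    sample_id: str
    focal_id: str
    associate_ids: frozenset[str]
    time: int = 0
    location: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "associate_ids", frozenset(self.associate_ids))
        if self.focal_id in self.associate_ids:
            raise DataFormatError(
                f"sample {self.sample_id!r}: focal {self.focal_id!r} listed "
                "among its own associates"
            )

    @property
    def members(self) -> frozenset[str]:
        return self.associate_ids | {self.focal_id}


@dataclass
class FocalSampleSet:
    """An ordered collection of focal samples.

    ``individual_ids`` is the universe of individuals; if omitted it is the
    sorted union of all ids appearing in the samples.
    """

    samples: list[FocalSample]
    individual_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise DataFormatError("duplicate sample_ids in focal data")
        seen = set()
        for s in self.samples:
            seen.add(s.focal_id)
            seen |= s.associate_ids
        if self.individual_ids is None:
            self.individual_ids = sorted(seen)
        else:
            self.individual_ids = _check_unique_ids(self.individual_ids)
            missing = seen - set(self.individual_ids)
            if missing:
                raise DataFormatError(
                    f"samples reference ids outside the universe: {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def occurrence_counts(self) -> dict[str, int]:
        """Total number of appearances (as focal or associate) per individual."""
        counts = {i: 0 for i in self.individual_ids}
        for s in self.samples:
            for i in s.members:
                counts[i] += 1
        return counts

    def copy(self) -> "FocalSampleSet":
        return FocalSampleSet(list(self.samples), list(self.individual_ids))


@dataclass
class TrajectorySet:
    """Per-individual daily tracks on an integer grid.

    ``positions`` has shape (N, n_days, steps_per_day, 2) holding (x, y) grid
    cells, 0-based.  A point may be *unobserved* (e.g. deleted by an
    observation-bias process), marked by ``MISSING_CELL`` in both coordinates;
    the individual was present but not recorded at that step.  Days and steps
    are 1-based in files and 0-based here.
    """

    individual_ids: list[str]
    positions: np.ndarray
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.individual_ids = _check_unique_ids(self.individual_ids)
        p = np.asarray(self.positions, dtype=np.int64)
        if p.ndim != 4 or p.shape[3] != 2 or p.shape[0] != len(self.individual_ids):
            raise DataFormatError(
                "positions must have shape (n_individuals, n_days, steps_per_day, 2)"
            )
        self.positions = p
        w, h = self.grid_shape
        obs = self.observed_mask()
        x, y = p[..., 0], p[..., 1]
        if ((x[obs] < 0) | (x[obs] >= w) | (y[obs] < 0) | (y[obs] >= h)).any():
            raise DataFormatError("trajectory coordinates outside the declared grid")
        miss = ~obs
        if not ((x[miss] == MISSING_CELL) & (y[miss] == MISSING_CELL)).all():
            raise DataFormatError("missing points must have both coordinates == -1")

    @property
    def n_individuals(self) -> int:
        return self.positions.shape[0]

    @property
    def n_days(self) -> int:
        return self.positions.shape[1]

    @property
    def steps_per_day(self) -> int:
        return self.positions.shape[2]

    def observed_mask(self) -> np.ndarray:
        """(N, n_days, steps_per_day) boolean mask of recorded points."""
        return self.positions[..., 0] != MISSING_CELL

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(
            list(self.individual_ids), self.positions.copy(), tuple(self.grid_shape)
        )

    def track(self, individual: str, day: int) -> np.ndarray:
        """The (steps_per_day, 2) track of one individual on one 0-based day."""
        return self.positions[self.individual_ids.index(individual), day]


@dataclass
class NodeTable:
    """Per-individual attributes (e.g. sex) for the nodes of a network.

    ``n_observations`` is an optional derived vector of per-individual
    observation counts; it describes the sampling of each node, not its
    phenotype, and is therefore *not* shuffled by node permutations.
    """

    individual_ids: list[str]
    attributes: dict[str, np.ndarray] = field(default_factory=dict)
    n_observations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_ids = _check_unique_ids(self.individual_ids)
        n = len(self.individual_ids)
        self.attributes = {
            k: np.asarray(v) for k, v in dict(self.attributes).items()
        }
        for k, v in self.attributes.items():
            if v.shape != (n,):
                raise DataFormatError(f"attribute {k!r} must have length N={n}")
        if self.n_observations is not None:
            self.n_observations = np.asarray(self.n_observations, dtype=np.int64)
            if self.n_observations.shape != (n,):
                raise DataFormatError("n_observations must have length N")
            if (self.n_observations < 0).any():
                raise DataFormatError("n_observations must be non-negative")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def get(self, attribute: str) -> np.ndarray:
        try:
            return self.attributes[attribute]
        except KeyError:
            raise KeyError(
                f"node attribute {attribute!r} not present "
                f"(have {sorted(self.attributes)})"
            ) from None

    def copy(self) -> "NodeTable":
        return NodeTable(
            list(self.individual_ids),
            {k: v.copy() for k, v in self.attributes.items()},
            None if self.n_observations is None else self.n_observations.copy(),
        )


@dataclass
class WeightedNetwork:
    """Symmetric weighted social network over named individuals.

    The adjacency matrix must be exactly symmetric with a zero diagonal and
    non-negative entries.  Association-index networks have weights in [0, 1];
    raw co-occurrence counts may exceed 1, so the upper bound is not enforced
    here.
    """

    adjacency: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=np.float64)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DataFormatError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise DataFormatError("adjacency must be exactly symmetric")
        if np.diagonal(a).any():
            raise DataFormatError("adjacency diagonal must be zero")
        if (a < 0).any():
            raise DataFormatError("edge weights must be non-negative")
        self.adjacency = a
        self.individual_ids = _check_unique_ids(self.individual_ids)
        if len(self.individual_ids) != a.shape[0]:
            raise DataFormatError("number of ids must match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Edge weights of each unordered dyad (i < j) as a flat vector."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.adjacency[iu]

    def nonzero_edge_weights(self) -> np.ndarray:
        w = self.upper_triangle()
        return w[w > 0]

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self.adjacency.copy(), list(self.individual_ids))


def _pvalue_triple(
    observed: float, null_statistics: np.ndarray
) -> tuple[float, float, float]:
    """Permutation p-values from a null series, ties counted in both tails.

    p_upper is the proportion of null values >= the observed statistic,
    p_lower the proportion <= it, and the two-tailed value is twice the
    smaller proportion, clamped at 1.  Missing (non-finite) null values are
    excluded from the denominator.
    """
    nulls = np.asarray(null_statistics, dtype=float)
    nulls = nulls[np.isfinite(nulls)]
    n = nulls.size
    if n == 0:
        raise ValueError("cannot compute p-values from an empty null series")
    p_upper = float(np.count_nonzero(nulls >= observed)) / n
    p_lower = float(np.count_nonzero(nulls <= observed)) / n
    p_two = min(1.0, 2.0 * min(p_upper, p_lower))
    return p_upper, p_lower, p_two


@dataclass
class PermutationResult:
    """Observed statistic, ordered null series and permutation p-values.

    ``null_statistics`` preserves permutation order so that stabilisation
    diagnostics (null statistic or running p against permutation number) can
    be computed.  ``n_missing`` counts permuted datasets on which the
    statistic was non-finite; those are recorded as NaN in the series and
    excluded from the p-value denominators.
    """

    observed_statistic: float
    null_statistics: np.ndarray
    p_upper: float
    p_lower: float
    p_two_tailed: float
    n_permutations: int
    seed: int | None = None
    method: str | None = None
    statistic_name: str | None = None
    n_missing: int = 0
    n_failed_swaps: int = 0

    @classmethod
    def from_series(
        cls,
        observed: float,
        null_statistics: Iterable[float],
        *,
        seed: int | None = None,
        method: str | None = None,
        statistic_name: str | None = None,
        n_failed_swaps: int = 0,
    ) -> "PermutationResult":
        nulls = np.asarray(list(null_statistics), dtype=float)
        p_upper, p_lower, p_two = _pvalue_triple(observed, nulls)
        return cls(
            observed_statistic=float(observed),
            null_statistics=nulls,
            p_upper=p_upper,
            p_lower=p_lower,
            p_two_tailed=p_two,
            n_permutations=int(nulls.size),
            seed=seed,
            method=method,
            statistic_name=statistic_name,
            n_missing=int(np.count_nonzero(~np.isfinite(nulls))),
            n_failed_swaps=n_failed_swaps,
        )

    def summary(self) -> dict:
        """JSON-serialisable summary (without the full null series)."""
        return {
            "observed_statistic": self.observed_statistic,
            "p_upper": self.p_upper,
            "p_lower": self.p_lower,
            "p_two_tailed": self.p_two_tailed,
            "n_permutations": self.n_permutations,
            "n_missing": self.n_missing,
            "n_failed_swaps": self.n_failed_swaps,
            "seed": self.seed,
            "method": self.method,
            "statistic": self.statistic_name,
        }
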