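"""CSV / GraphML readers and writers for all observation and network formats.

Conventions (this package's own; none of the field's tools fix one):

* GBI CSV: header ``event_id,event_time[,event_day][,event_location],<id1>,...``
  with 0/1 membership cells.  Metadata columns other than ``event_time`` are
  written only when present.
* Focal CSV: ``sample_id,focal_id,associates,time,location`` with the
  associates ``;``-separated (empty for a lone focal).
* Trajectory CSV (long): ``individual,day,step,x,y`` with day and step
  1-based in the file, 0-based in memory.  Unobserved points are simply
  absent from the file.
* Node CSV: ``individual,<attribute>,...`` (plus optional ``n_observations``).
* Networks: edge-list CSV ``id_i,id_j,weight`` (i < j, nonzero edges only),
  square adjacency CSV, or GraphML.

Round trips are lossless for ids and values to written precision, except the
edge-list format which, like any edge list, drops isolated nodes unless the
reader is given the full id list.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import (
    MISSING_CELL,
    DataFormatError,
    FocalSample,
    FocalSampleSet,
    GroupByIndividualMatrix,
    NodeTable,
    TrajectorySet,
    WeightedNetwork,
)

__all__ = [
    "read_gbi",
    "write_gbi",
    "read_focal",
    "write_focal",
    "read_trajectories",
    "write_trajectories",
    "read_nodes",
    "write_nodes",
    "read_network",
    "write_network",
]

_GBI_META = ("event_id", "event_time", "event_day", "event_location")
_FLOAT_FMT = "%.12g"


def _read_header(path) -> list[str]:
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise DataFormatError(f"duplicate columns in {path}: {dupes}")
    return header


def read_gbi(path, membership_columns: list[str] | None = None) -> GroupByIndividualMatrix:
    """Read a group-by-individual CSV.

    ``membership_columns`` overrides the header convention (every column not
    named in the reserved metadata set is a membership column).
    """
    header = _read_header(path)
    df = pd.read_csv(path, dtype={"event_location": str})
    if membership_columns is None:
        membership_columns = [c for c in header if c not in _GBI_META]
    if not membership_columns:
        raise DataFormatError(f"no membership columns found in {path}")
    block = df[membership_columns]
    values = block.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise DataFormatError(f"non-binary membership value in {path}")
    return GroupByIndividualMatrix(
        membership=values.astype(np.int8),
        individual_ids=list(membership_columns),
        event_time=df["event_time"].to_numpy() if "event_time" in df else None,
        event_day=df["event_day"].to_numpy() if "event_day" in df else None,
        event_location=(
            df["event_location"].to_numpy() if "event_location" in df else None
        ),
    )


def write_gbi(gbi: GroupByIndividualMatrix, path) -> None:
    data: dict = {"event_id": [f"e{k}" for k in range(gbi.n_events)]}
    data["event_time"] = gbi.event_time
    if gbi.event_day is not None:
        data["event_day"] = gbi.event_day
    if gbi.event_location is not None:
        data["event_location"] = gbi.event_location
    for j, ind in enumerate(gbi.individual_ids):
        data[ind] = gbi.membership[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_focal(path) -> FocalSampleSet:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "focal_id", "associates", "time"}
    if not required <= set(df.columns):
        raise DataFormatError(f"focal CSV {path} must have columns {sorted(required)}")
    samples = []
    for row in df.itertuples(index=False):
        assoc = [a for a in str(row.associates).split(";") if a]
        if len(assoc) != len(set(assoc)):
            raise DataFormatError(
                f"sample {row.sample_id!r}: duplicate associates in {path}"
            )
        loc = getattr(row, "location", "") or None
        samples.append(
            FocalSample(
                sample_id=row.sample_id,
                focal_id=row.focal_id,
                associate_ids=frozenset(assoc),
                time=int(row.time),
                location=loc,
            )
        )
    return FocalSampleSet(samples)


def write_focal(focals: FocalSampleSet, path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "focal_id": s.focal_id,
            "associates": ";".join(sorted(s.associate_ids)),
            "time": s.time,
            "location": "" if s.location is None else s.location,
        }
        for s in focals
    ]
    pd.DataFrame(rows, columns=["sample_id", "focal_id", "associates", "time", "location"]).to_csv(
        path, index=False
    )


def read_trajectories(
    path,
    grid_shape: tuple[int, int] | None = None,
    allow_missing: bool = False,
) -> TrajectorySet:
    """Read a long-format trajectory CSV.

    By default every (individual, day) track must be complete (one row per
    step); a shorter track is a format error.  ``allow_missing=True`` accepts
    absent (day, step) rows as unobserved points, which is how data thinned
    by an observation-bias process are stored.
    """
    df = pd.read_csv(path)
    required = {"individual", "day", "step", "x", "y"}
    if not required <= set(df.columns):
        raise DataFormatError(
            f"trajectory CSV {path} must have columns {sorted(required)}"
        )
    ids = sorted(df["individual"].astype(str).unique())
    n_days = int(df["day"].max())
    steps = int(df["step"].max())
    if df["day"].min() < 1 or df["step"].min() < 1:
        raise DataFormatError("day and step are 1-based in trajectory files")
    if grid_shape is None:
        grid_shape = (int(df["x"].max()) + 1, int(df["y"].max()) + 1)
    pos = np.full((len(ids), n_days, steps, 2), MISSING_CELL, dtype=np.int64)
    idx = {ind: i for i, ind in enumerate(ids)}
    rows_i = df["individual"].astype(str).map(idx).to_numpy()
    d = df["day"].to_numpy() - 1
    s = df["step"].to_numpy() - 1
    if pd.DataFrame({"i": rows_i, "d": d, "s": s}).duplicated().any():
        raise DataFormatError(f"duplicate (individual, day, step) rows in {path}")
    pos[rows_i, d, s, 0] = df["x"].to_numpy()
    pos[rows_i, d, s, 1] = df["y"].to_numpy()
    if not allow_missing and (pos[..., 0] == MISSING_CELL).any():
        raise DataFormatError(
            f"incomplete tracks in {path} (expected {steps} steps per day for "
            "every individual and day); pass allow_missing=True for thinned data"
        )
    return TrajectorySet(ids, pos, grid_shape)


def write_trajectories(traj: TrajectorySet, path) -> None:
    obs = traj.observed_mask()
    i, d, s = np.nonzero(obs)
    pd.DataFrame(
        {
            "individual": [traj.individual_ids[k] for k in i],
            "day": d + 1,
            "step": s + 1,
            "x": traj.positions[i, d, s, 0],
            "y": traj.positions[i, d, s, 1],
        }
    ).to_csv(path, index=False)


def read_nodes(path) -> NodeTable:
    df = pd.read_csv(path, dtype={"individual": str})
    if "individual" not in df.columns:
        raise DataFormatError(f"node CSV {path} must have an 'individual' column")
    ids = df["individual"].tolist()
    n_obs = None
    attrs = {}
    for col in df.columns:
        if col == "individual":
            continue
        if col == "n_observations":
            n_obs = df[col].to_numpy()
        else:
            attrs[col] = df[col].to_numpy()
    return NodeTable(ids, attrs, n_obs)


def write_nodes(nodes: NodeTable, path) -> None:
    data = {"individual": nodes.individual_ids}
    data.update({k: v for k, v in nodes.attributes.items()})
    if nodes.n_observations is not None:
        data["n_observations"] = nodes.n_observations
    pd.DataFrame(data).to_csv(path, index=False)


def write_network(net: WeightedNetwork, path, format: str = "adjacency") -> None:
    """Write a network as ``edgelist`` CSV, square ``adjacency`` CSV or ``graphml``."""
    path = Path(path)
    if format == "adjacency":
        pd.DataFrame(
            net.adjacency, index=net.individual_ids, columns=net.individual_ids
        ).to_csv(path, float_format=_FLOAT_FMT)
    elif format == "edgelist":
        i, j = np.triu_indices(net.n_nodes, k=1)
        w = net.adjacency[i, j]
        nz = w > 0
        pd.DataFrame(
            {
                "id_i": [net.individual_ids[a] for a in i[nz]],
                "id_j": [net.individual_ids[b] for b in j[nz]],
                "weight": w[nz],
            }
        ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.individual_ids)
        i, j = np.triu_indices(net.n_nodes, k=1)
        w = net.adjacency[i, j]
        for a, b, weight in zip(i, j, w):
            if weight > 0:
                g.add_edge(
                    net.individual_ids[a], net.individual_ids[b], weight=float(weight)
                )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(
    path, format: str = "adjacency", individual_ids: list[str] | None = None
) -> WeightedNetwork:
    path = Path(path)
    if format == "adjacency":
        df = pd.read_csv(path, index_col=0)
        ids = [str(c) for c in df.columns]
        if [str(r) for r in df.index] != ids:
            raise DataFormatError(f"adjacency CSV {path} rows and columns differ")
        return WeightedNetwork(df.to_numpy(dtype=float), ids)
    if format == "edgelist":
        df = pd.read_csv(path, dtype={"id_i": str, "id_j": str})
        ids = individual_ids or sorted(set(df["id_i"]) | set(df["id_j"]))
        idx = {ind: k for k, ind in enumerate(ids)}
        adj = np.zeros((len(ids), len(ids)))
        for row in df.itertuples(index=False):
            a, b = idx[row.id_i], idx[row.id_j]
            adj[a, b] = adj[b, a] = row.weight
        return WeightedNetwork(adj, list(ids))
    if format == "graphml":
        g = nx.read_graphml(path)
        ids = individual_ids or sorted(g.nodes)
        adj = np.zeros((len(ids), len(ids)))
        idx = {ind: k for k, ind in enumerate(ids)}
        for a, b, data in g.edges(data=True):
            adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = data.get("weight", 1.0)
        return WeightedNetwork(adj, list(ids))
    raise ValueError(f"unknown network format {format!r}")
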