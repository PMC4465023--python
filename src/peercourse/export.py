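"""Plain-text serialization of trajectories, networks and reports.

Trajectories are written as long-format CSV (t, agent, e, a, b, g);
network snapshots as weighted directed edge lists (source, target,
weight, time) and as GraphML.  An optional minimum-weight filter is
available for edge-list and GraphML export only: it is a display
convenience and never affects the dynamics.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .simulation import Trajectory


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the long-format trajectory table (t, agent, e, a, b, g)."""
    traj.to_frame().to_csv(path, index=False)


def read_trajectory_frame(path: str | Path) -> pd.DataFrame:
    """Read a trajectory table written by :func:`write_trajectory`."""
    return pd.read_csv(path)


def snapshots_to_edge_frame(
    traj: Trajectory, min_weight: float = 0.0
) -> pd.DataFrame:
    """All stored network snapshots as one (source, target, weight, time) table."""
    frames = []
    for t, weights in traj.network_snapshots:
        src, tgt = np.nonzero(weights > min_weight)
        frames.append(
            pd.DataFrame(
                {
                    "source": src,
                    "target": tgt,
                    "weight": weights[src, tgt],
                    "time": t,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["source", "target", "weight", "time"])
    return pd.concat(frames, ignore_index=True)


def write_edge_list(
    traj: Trajectory, path: str | Path, min_weight: float = 0.0
) -> None:
    snapshots_to_edge_frame(traj, min_weight).to_csv(path, index=False)


def snapshot_to_graph(
    weights: np.ndarray, min_weight: float = 0.0
) -> "nx.DiGraph":
    """One snapshot as a weighted directed graph (all agents as nodes)."""
    g = nx.DiGraph()
    g.add_nodes_from(range(weights.shape[0]))
    src, tgt = np.nonzero(weights > min_weight)
    g.add_weighted_edges_from(
        zip(src.tolist(), tgt.tolist(), weights[src, tgt].tolist())
    )
    return g


def write_graphml(
    traj: Trajectory, directory: str | Path, min_weight: float = 0.0
) -> list[Path]:
    """One GraphML file per stored snapshot; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, weights in traj.network_snapshots:
        p = directory / f"network_t{t:04d}.graphml"
        nx.write_graphml(snapshot_to_graph(weights, min_weight), p)
        paths.append(p)
    return paths
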