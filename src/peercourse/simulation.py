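"""T-step simulation driver and outcome summaries.

A run records the antisocial levels e_i(t) for t = 0..T (T+1 rows) and
the per-step reward, cost and net reward for t = 0..T-1.  Outcomes are
summarized by the adolescence-limited / life-course-persistent split:
an agent whose final antisocial level exceeds the classification
threshold (default 0.5) is life-course-persistent, otherwise
adolescence-limited.  The two emergent groups are usually separated by
a wide gap in final levels, which the largest-gap rule exploits to
identify the borderline members of each group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConnectionMatrix, step
from .initialization import InitialCondition, init_state, state_from_initial
from .params import ModelParams

#: network snapshot times mirroring ages 7, 15, 23 and 32 months into the run
DEFAULT_SNAPSHOT_TIMES = (1, 100, 200, 300)


@dataclass
class Trajectory:
    """Full record of one simulation run."""

    antisocial: np.ndarray  # (T+1, N): e_i(t) for t = 0..T
    reward: np.ndarray  # (T, N): a_i(t) for t = 0..T-1
    cost: np.ndarray  # (T, N)
    net_reward: np.ndarray  # (T, N)
    params: ModelParams
    initial: InitialCondition
    network_snapshots: list[tuple[int, np.ndarray]] = field(default_factory=list)

    @property
    def n_agents(self) -> int:
        return self.antisocial.shape[1]

    @property
    def final_antisocial(self) -> np.ndarray:
        return self.antisocial[-1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns t, agent, e, a, b, g.

        Diagnostics a, b, g are defined for t = 0..T-1; they are NaN on
        the final row block (t = T).
        """
        n_rows, n = self.antisocial.shape
        t_idx = np.repeat(np.arange(n_rows), n)
        agent = np.tile(np.arange(n), n_rows)
        pad = np.full((1, n), np.nan)
        return pd.DataFrame(
            {
                "t": t_idx,
                "agent": agent,
                "e": self.antisocial.ravel(),
                "a": np.vstack([self.reward, pad]).ravel(),
                "b": np.vstack([self.cost, pad]).ravel(),
                "g": np.vstack([self.net_reward, pad]).ravel(),
            }
        )


@dataclass
class OutcomeSummary:
    """Final-state classification of one run."""

    final_antisocial: np.ndarray
    al_indices: np.ndarray
    lcp_indices: np.ndarray
    al_fraction: float
    gap_location: float | None = None

    @property
    def n_lcp(self) -> int:
        return self.lcp_indices.size


def run(
    params: ModelParams,
    initial: InitialCondition | None = None,
    snapshot_times: tuple[int, ...] = (),
) -> Trajectory:
    """Simulate T steps from a fresh or supplied initial condition.

    Deterministic given (params, initial); with ``initial=None`` the
    initial condition is drawn from ``params.seed``, so the trajectory
    is reproducible from the parameter set alone.
    """
    if initial is None:
        state, conn, initial = init_state(params)
    else:
        if initial.n_agents != params.n_agents:
            raise ValueError(
                f"initial condition has {initial.n_agents} agents, "
                f"params say {params.n_agents}"
            )
        state, conn = state_from_initial(initial)

    t_total, n = params.n_steps, params.n_agents
    e_hist = np.empty((t_total + 1, n))
    a_hist = np.empty((t_total, n))
    b_hist = np.empty((t_total, n))
    g_hist = np.empty((t_total, n))
    e_hist[0] = state.antisocial
    snapshots: list[tuple[int, np.ndarray]] = []
    want = set(snapshot_times)
    if 0 in want:
        snapshots.append((0, conn.weights.copy()))
    for t in range(t_total):
        state, conn, diag = step(state, conn, params)
        e_hist[t + 1] = state.antisocial
        a_hist[t] = diag.reward
        b_hist[t] = diag.cost
        g_hist[t] = diag.net_reward
        if t + 1 in want:
            snapshots.append((t + 1, conn.weights.copy()))
    return Trajectory(
        antisocial=e_hist,
        reward=a_hist,
        cost=b_hist,
        net_reward=g_hist,
        params=params,
        initial=initial,
        network_snapshots=snapshots,
    )


def offending_curve(traj: Trajectory, threshold: float) -> np.ndarray:
    """Number of agents with e_i(t) > threshold at each recorded time.

    Returns a length T+1 integer vector (t = 0..T).  Strict inequality:
    an agent exactly at the threshold does not count as offending.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    return (traj.antisocial > threshold).sum(axis=1)


def classify(final_e: np.ndarray, threshold: float = 0.5) -> OutcomeSummary:
    """Split agents into adolescence-limited and life-course-persistent.

    Agent i is life-course-persistent iff its final antisocial level
    strictly exceeds the threshold; everyone else is adolescence-limited.
    """
    final_e = np.asarray(final_e, dtype=float)
    lcp = np.flatnonzero(final_e > threshold)
    al = np.flatnonzero(final_e <= threshold)
    gap = None
    if final_e.size >= 2:
        s = np.sort(final_e)
        diffs = np.diff(s)
        if diffs.max() > 0:
            k = int(np.argmax(diffs))
            gap = float((s[k] + s[k + 1]) / 2)
    return OutcomeSummary(
        final_antisocial=final_e,
        al_indices=al,
        lcp_indices=lcp,
        al_fraction=al.size / final_e.size,
        gap_location=gap,
    )


def largest_gap_split(final_e: np.ndarray) -> tuple[int, int]:
    """Locate the borderline agents on either side of the largest gap.

    Sorts the final antisocial levels ascending and finds the adjacent
    pair with the maximum difference; returns (index of the lower
    member, index of the higher member) as indices into ``final_e``.
    The lower member is the borderline adolescence-limited agent, the
    higher one the borderline life-course-persistent agent.  Ties on
    the gap size are broken toward the lowest sorted position.
    """
    final_e = np.asarray(final_e, dtype=float)
    if final_e.size < 2:
        raise ValueError("need at least 2 agents to find a gap")
    order = np.argsort(final_e, kind="stable")
    diffs = np.diff(final_e[order])
    if diffs.max() <= 0:
        raise ValueError("all antisocial levels identical: no gap exists")
    k = int(np.argmax(diffs))  # argmax takes the first maximum: lowest position
    return int(order[k]), int(order[k + 1])
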