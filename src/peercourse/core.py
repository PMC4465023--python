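"""Per-tick dynamical equations of the coupled agent/network model.

Each agent i carries an antisocial level e_i(t) in [0, 1] and a fixed
intrinsic prosocial level r_i = 1 - e_i(0).  Agents are linked by a
weighted directed connection matrix A_ij(t) in [0, 1] (zero diagonal).
One synchronous tick evaluates, from the time-t state:

1. the antisocial history h_i(t), the running mean of e_i over 0..t;
2. peer influence d_ij(t) = c A_ij(t) (e_j - e_i) for j != i;
3. the reward a_i(t) = min(gamma t / (r_i T), gamma t_p / (r_i T), 1),
   rising linearly through the maturity gap and constant after t_p;
4. the commitment cost b_i(t) = (1 - h_i(t)) f(t), with the sigmoid
   f(t) = 1 / (exp(-(t - t_p)/k) + 1) crossing 1/2 at the turning point;
5. the net reward g_i(t) = a_i(t) - b_i(t);
6. the connection update: within the mimicry window |e_j - e_i| < de,
   dA_ij = (g_i/de)(e_j - e_i), applied multiplicatively toward the
   absorbing bounds 1 (if dA >= 0) or 0 (if dA < 0);
7. the antisocial update e_i(t+1) = e_i(t) + (1/N) sum_j d_ij(t), where
   d_ii is the self contribution g_i(1-e_i) if g_i >= 0 else g_i e_i.

All operations are pure: they take the state and return new arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

#: slack for the boundedness assertion on e (no silent clipping beyond this)
_E_TOL = 1e-12


@dataclass
class PopulationState:
    """Per-agent state at a single time step.

    Attributes
    ----------
    time : int
        Current time step t (0 is the initial condition).
    antisocial : ndarray
        e_i(t), each in [0, 1].
    intrinsic_prosocial : ndarray
        r_i = 1 - e_i(0); fixed after construction.
    history_sum : ndarray
        Running sum of e_i over steps 0..t inclusive.
    """

    time: int
    antisocial: np.ndarray
    intrinsic_prosocial: np.ndarray
    history_sum: np.ndarray

    def __post_init__(self) -> None:
        self.antisocial = np.asarray(self.antisocial, dtype=float)
        self.intrinsic_prosocial = np.asarray(self.intrinsic_prosocial, dtype=float)
        self.intrinsic_prosocial.setflags(write=False)
        self.history_sum = np.asarray(self.history_sum, dtype=float)
        n = self.antisocial.size
        if self.intrinsic_prosocial.size != n or self.history_sum.size != n:
            raise ValueError("state vectors must have matching length")
        if np.any(self.antisocial < 0) or np.any(self.antisocial > 1):
            raise ValueError("antisocial levels must lie in [0, 1]")

    @property
    def n_agents(self) -> int:
        return self.antisocial.size

    def history_mean(self) -> np.ndarray:
        """h_i(t): mean antisocial level over steps 0..t (t+1 terms)."""
        return self.history_sum / (self.time + 1)

    @classmethod
    def _unchecked(
        cls,
        time: int,
        antisocial: np.ndarray,
        intrinsic_prosocial: np.ndarray,
        history_sum: np.ndarray,
    ) -> "PopulationState":
        # hot-path constructor: arrays produced by `step` are already valid
        obj = object.__new__(cls)
        obj.time = time
        obj.antisocial = antisocial
        obj.intrinsic_prosocial = intrinsic_prosocial
        obj.history_sum = history_sum
        return obj


@dataclass
class ConnectionMatrix:
    """Directed weighted peer network A_ij(t).

    A_ij is the strength with which agent i attends to (imitates) agent j.
    Entries lie in [0, 1]; the diagonal is fixed at 0 and never used.
    Symmetric at t = 0 only; the adaptive update is directional.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connection matrix must be square")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("connection weights must lie in [0, 1]")
        if np.any(np.diagonal(w) != 0):
            raise ValueError("connection matrix diagonal must be zero")

    @property
    def n_agents(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def _unchecked(cls, weights: np.ndarray) -> "ConnectionMatrix":
        # hot-path constructor: Eq-8 output is within bounds by construction
        obj = object.__new__(cls)
        obj.weights = weights
        return obj


@dataclass
class StepDiagnostics:
    """Intermediate quantities of one tick, for trajectory recording."""

    reward: np.ndarray
    cost: np.ndarray
    net_reward: np.ndarray
    peer_influence: np.ndarray
    self_contribution: np.ndarray
    sigmoid_value: float = field(default=0.0)


def sigmoid(t: float, params: ModelParams) -> float:
    """Cost sigmoid f(t) = 1 / (exp(-(t - t_p)/k) + 1); f(t_p) = 1/2."""
    x = (t - params.turning_point) / params.sigmoid_steepness
    if x >= 0:
        return 1.0 / (np.exp(-x) + 1.0)
    z = np.exp(x)  # stable for large negative arguments
    return z / (z + 1.0)


def reward(state: PopulationState, t: int, params: ModelParams) -> np.ndarray:
    """Reward a_i(t) = min(gamma t / (r_i T), gamma t_p / (r_i T), 1).

    Rises linearly with slope inversely proportional to the intrinsic
    prosocial level, plateaus at the turning point, capped at 1.
    """
    r = state.intrinsic_prosocial
    if np.any(r <= 0):
        raise ValueError("intrinsic prosocial levels must be strictly positive")
    slope = params.reward_rate / (r * params.n_steps)
    return np.minimum(slope * min(t, params.turning_point), 1.0)


def cost(state: PopulationState, t: int, params: ModelParams) -> np.ndarray:
    """Commitment cost b_i(t) = (1 - h_i(t)) f(t).

    h_i(t) is the running mean of e_i over steps 0..t inclusive (t+1
    terms), so b_i is bounded in [0, 1].  Requires ``state.history_sum``
    to be current through time t.
    """
    if t != state.time:
        raise ValueError(f"state is at time {state.time}, cost requested at {t}")
    return (1.0 - state.history_mean()) * sigmoid(t, params)


def peer_influence(
    state: PopulationState, conn: ConnectionMatrix, params: ModelParams
) -> np.ndarray:
    """Peer influence matrix d_ij = c A_ij (e_j - e_i), j != i; zero diagonal."""
    if conn.n_agents != state.n_agents:
        raise ValueError(
            f"state has {state.n_agents} agents but connection matrix "
            f"has {conn.n_agents}"
        )
    e = state.antisocial
    d = params.influence_rate * conn.weights * (e[np.newaxis, :] - e[:, np.newaxis])
    np.fill_diagonal(d, 0.0)
    return d


def self_contribution(g: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Self contribution d_ii = g_i (1 - e_i) if g_i >= 0 else g_i e_i.

    Scales the net reward by the headroom to the nearest bound, so that
    e_i + d_ii always stays inside [0, 1].
    """
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    return np.where(g >= 0, g * (1.0 - e), g * e)


def update_antisocial(
    state: PopulationState, d: np.ndarray, params: ModelParams
) -> np.ndarray:
    """e_i(t+1) = e_i(t) + (1/N) sum_j d_ij(t), diagonal included.

    ``d`` must carry peer influences off-diagonal and self contributions
    on the diagonal.  The result is asserted to lie in [0, 1]: a
    violation beyond floating-point slack signals a parameter regime
    where the model's bounds no longer hold, and raises rather than
    silently clipping.
    """
    n = state.n_agents
    if d.shape != (n, n):
        raise ValueError(f"contribution matrix must be {n}x{n}, got {d.shape}")
    e_new = state.antisocial + d.sum(axis=1) / n
    if np.any(e_new < -_E_TOL) or np.any(e_new > 1.0 + _E_TOL):
        worst = float(np.max(np.abs(e_new - 0.5)) - 0.5)
        raise FloatingPointError(
            "antisocial level left [0, 1] by "
            f"{worst:.3e}; the parameter regime violates the model's bounds"
        )
    return np.clip(e_new, 0.0, 1.0)


def update_connections(
    conn: ConnectionMatrix, e: np.ndarray, g: np.ndarray, params: ModelParams
) -> ConnectionMatrix:
    """Adapt the directed connection weights from time-t levels and rewards.

    For each ordered pair (i, j), i != j:

    * outside the mimicry window (|e_j - e_i| >= de): no change;
    * inside it: dA_ij = (g_i / de)(e_j - e_i), then
      A_ij <- A_ij + dA_ij (1 - A_ij) if dA_ij >= 0,
      A_ij <- A_ij + dA_ij A_ij       otherwise.

    The multiplicative form makes 0 and 1 absorbing, so weights stay in
    [0, 1].  The update is directional: row i is driven by agent i's
    net reward g_i.
    """
    de = params.mimicry_window
    ediff = e[np.newaxis, :] - e[:, np.newaxis]
    within = np.abs(ediff) < de
    delta = np.where(within, (g[:, np.newaxis] / de) * ediff, 0.0)
    a = conn.weights
    new = np.where(delta >= 0, a + delta * (1.0 - a), a + delta * a)
    np.fill_diagonal(new, 0.0)
    return ConnectionMatrix._unchecked(new)


def step(
    state: PopulationState, conn: ConnectionMatrix, params: ModelParams
) -> tuple[PopulationState, ConnectionMatrix, StepDiagnostics]:
    """Advance the model one synchronous tick.

    All quantities (history, peer influence, reward, cost, net reward)
    are evaluated from the time-t state; the network is updated before
    the antisocial levels, and both updates read time-t values only.
    """
    if conn.n_agents != state.n_agents:
        raise ValueError("state and connection matrix sizes differ")
    t = state.time
    d = peer_influence(state, conn, params)
    a = reward(state, t, params)
    b = cost(state, t, params)
    g = a - b
    conn_next = update_connections(conn, state.antisocial, g, params)
    d_self = self_contribution(g, state.antisocial)
    d_full = d.copy()
    np.fill_diagonal(d_full, d_self)
    e_next = update_antisocial(state, d_full, params)
    state_next = PopulationState._unchecked(
        time=t + 1,
        antisocial=e_next,
        intrinsic_prosocial=state.intrinsic_prosocial,
        history_sum=state.history_sum + e_next,
    )
    diag = StepDiagnostics(
        reward=a,
        cost=b,
        net_reward=g,
        peer_influence=d,
        self_contribution=d_self,
        sigmoid_value=float(sigmoid(t, params)),
    )
    return state_next, conn_next, diag
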