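"""Construction of the t = 0 population and peer network.

Initial antisocial levels are Normal(0.5, 0.1) draws, rejection-resampled
into [0, 1].  The initial network is fully connected: one Uniform(0, 1)
strength per unordered pair, mirrored to both directions, then rescaled
once by the intrinsic prosocial levels, A_ij = r_i r_j A_ij,unadjusted —
so the most antisocial agents start at the periphery.  The rescaling is
applied once at t = 0 and never again.

Draw order is fixed — antisocial levels first, then pair weights in
row-major upper-triangle order — so a single seed reproduces the full
initial condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import ConnectionMatrix, PopulationState
from .params import ModelParams

#: mean and sd of the initial antisocial-level distribution
INIT_MEAN = 0.5
INIT_SD = 0.1


@dataclass(frozen=True)
class InitialCondition:
    """A replayable t = 0 snapshot: levels, connections, and the seed."""

    antisocial0: np.ndarray
    connections0: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "antisocial0", np.asarray(self.antisocial0, dtype=float)
        )
        object.__setattr__(
            self, "connections0", np.asarray(self.connections0, dtype=float)
        )
        n = self.antisocial0.size
        if self.connections0.shape != (n, n):
            raise ValueError("connections0 shape must match antisocial0 length")
        if not np.array_equal(self.connections0, self.connections0.T):
            raise ValueError("connections0 must be symmetric at t = 0")

    @property
    def n_agents(self) -> int:
        return self.antisocial0.size

    def to_json(self, path: str | Path) -> None:
        """Serialize to a plain-text JSON snapshot (full double precision)."""
        payload = {
            "seed": self.seed,
            "antisocial0": [float.hex(float(x)) for x in self.antisocial0],
            "connections0": [
                [float.hex(float(x)) for x in row] for row in self.connections0
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "InitialCondition":
        payload = json.loads(Path(path).read_text())
        return cls(
            antisocial0=np.array([float.fromhex(x) for x in payload["antisocial0"]]),
            connections0=np.array(
                [[float.fromhex(x) for x in row] for row in payload["connections0"]]
            ),
            seed=payload["seed"],
        )


def draw_initial_antisocial(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n initial antisocial levels from Normal(0.5, 0.1) truncated to [0, 1].

    Out-of-range values are redrawn (rejection sampling); at five sigma
    from both bounds the truncation is negligible.
    """
    if n < 2:
        raise ValueError("need at least 2 agents")
    out = rng.normal(INIT_MEAN, INIT_SD, size=n)
    bad = (out < 0) | (out > 1)
    while bad.any():
        out[bad] = rng.normal(INIT_MEAN, INIT_SD, size=int(bad.sum()))
        bad = (out < 0) | (out > 1)
    return out


def init_connections(
    antisocial0: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Build the symmetric t = 0 connection matrix.

    One Uniform(0, 1) draw per unordered pair (row-major upper-triangle
    order), mirrored, then rescaled by r_i r_j with r = 1 - antisocial0.
    Diagonal fixed at 0.
    """
    antisocial0 = np.asarray(antisocial0, dtype=float)
    n = antisocial0.size
    iu, ju = np.triu_indices(n, k=1)
    a = np.zeros((n, n))
    a[iu, ju] = rng.uniform(0.0, 1.0, size=iu.size)
    a = a + a.T
    r = 1.0 - antisocial0
    a *= r[:, np.newaxis] * r[np.newaxis, :]
    np.fill_diagonal(a, 0.0)
    return a


def init_state(
    params: ModelParams, rng: np.random.Generator | None = None
) -> tuple[PopulationState, ConnectionMatrix, InitialCondition]:
    """Draw a fresh initial condition and package it as model state.

    If no generator is given, one is created from ``params.seed``, so
    the initial condition (and hence the whole trajectory) is
    reproducible from the parameter set alone.
    """
    seed = params.seed if rng is None else None
    if rng is None:
        rng = np.random.default_rng(params.seed)
    e0 = draw_initial_antisocial(params.n_agents, rng)
    a0 = init_connections(e0, rng)
    ic = InitialCondition(antisocial0=e0, connections0=a0, seed=seed)
    state, conn = state_from_initial(ic)
    return state, conn, ic


def state_from_initial(
    ic: InitialCondition,
) -> tuple[PopulationState, ConnectionMatrix]:
    """Rebuild model state from a saved initial condition (exact replay)."""
    e0 = ic.antisocial0.copy()
    state = PopulationState(
        time=0,
        antisocial=e0,
        intrinsic_prosocial=1.0 - e0,
        history_sum=e0.copy(),
    )
    return state, ConnectionMatrix(ic.connections0.copy())
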