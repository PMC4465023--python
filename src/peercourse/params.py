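"""Simulation parameters.

The benchmark parameter set models a classroom-sized cohort of 30 youths
followed monthly from age 7 to age 32 (300 steps), with the turning point
into adult roles at step 120 (age 17).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any


@dataclass(frozen=True)
class ModelParams:
    """The seven simulation parameters plus the RNG seed.

    Parameters
    ----------
    n_agents : int
        Number of agents N (benchmark: 30, roughly one school class).
    n_steps : int
        Total number of time steps T (benchmark: 300; one step = one month).
    turning_point : int
        Time step t_p at which agents start assuming adult roles: the
        reward for antisocial behavior plateaus and the commitment-cost
        sigmoid crosses its midpoint (benchmark: 120).
    sigmoid_steepness : float
        k, the steepness scale of the cost sigmoid (benchmark: 20).
    influence_rate : float
        c, proportionality constant limiting how fast agents imitate
        their peers' antisocial levels (benchmark: 0.1).
    reward_rate : float
        gamma, the rate of increase of the reward for antisocial
        behavior during the maturity gap (benchmark: 0.2).
    mimicry_window : float
        Delta-e, the window of antisocial-level difference within which
        social mimicry (connection adaptation) occurs (benchmark: 0.2).
    seed : int
        Seed for the simulation's random number generator.
    """

    n_agents: int = 30
    n_steps: int = 300
    turning_point: int = 120
    sigmoid_steepness: float = 20.0
    influence_rate: float = 0.1
    reward_rate: float = 0.2
    mimicry_window: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be at least 2")
        if self.n_steps < 1:
            raise ValueError("n_steps must be positive")
        if not 0 < self.turning_point < self.n_steps:
            raise ValueError(
                f"turning_point must lie in (0, n_steps); got "
                f"{self.turning_point} with n_steps={self.n_steps}"
            )
        for name in ("sigmoid_steepness", "influence_rate", "reward_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.mimicry_window <= 1:
            raise ValueError("mimicry_window must lie in (0, 1]")

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


#: Field names of the four parameters varied in the sensitivity analysis.
SENSITIVITY_PARAMS = (
    "sigmoid_steepness",
    "influence_rate",
    "reward_rate",
    "mimicry_window",
)
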