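"""Divergence-gradient sensitivity analysis of the ensemble outcome.

The macroscopic outcome monitored is the final adolescence-limited
fraction of a run.  Its distribution over an ensemble of runs with
fresh random initial conditions, F(p), is binned with width 1/N; the
sensitivity of the outcome to a parameter is the Jensen-Shannon
divergence between F at the benchmark parameter set and F at the
parameter perturbed by +-50%, divided by the perturbation size
(a forward or backward difference approximation to the JSD gradient
in parameter space).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .initialization import (
    InitialCondition,
    draw_initial_antisocial,
    init_connections,
)
from .params import ModelParams
from .simulation import classify, run

#: the +-50% perturbation sizes of the benchmark parameter set
DEFAULT_DELTAS = {
    "sigmoid_steepness": 10.0,
    "influence_rate": 0.05,
    "reward_rate": 0.1,
    "mimicry_window": 0.1,
}


@dataclass(frozen=True)
class ParamPerturbation:
    """A benchmark parameter set and per-parameter perturbation sizes."""

    base: ModelParams = field(default_factory=ModelParams)
    deltas: dict = field(default_factory=lambda: dict(DEFAULT_DELTAS))

    def perturbed(self, name: str, direction: str) -> ModelParams:
        """The parameter set with ``name`` shifted by +-delta."""
        if name not in self.deltas:
            raise KeyError(f"no perturbation size for parameter {name!r}")
        sign = {"forward": 1.0, "backward": -1.0}[direction]
        value = getattr(self.base, name) + sign * self.deltas[name]
        if value <= 0:
            raise ValueError(
                f"perturbed {name} = {value} is not strictly positive"
            )
        return self.base.replace(**{name: value})


@dataclass
class OutcomeDistribution:
    """Binned distribution of the final adolescence-limited fraction.

    The fraction of a run with N agents takes only the values m/N, so
    the histogram uses N+1 bins indexed by the adolescence-limited
    count m (bin width 1/N; a fraction of exactly 1 occupies the top
    bin).  Frequencies are relative and sum to 1.
    """

    frequencies: np.ndarray
    n_agents: int
    n_runs: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.size != self.n_agents + 1:
            raise ValueError("need n_agents + 1 bins")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be nonnegative")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")

    @property
    def bin_edges(self) -> np.ndarray:
        """Lower edges m/N of the count bins, m = 0..N."""
        return np.arange(self.n_agents + 1) / self.n_agents

    @property
    def mean_fraction(self) -> float:
        """Ensemble mean adolescence-limited fraction."""
        m = np.arange(self.n_agents + 1)
        return float(np.sum(self.frequencies * m) / self.n_agents)

    @property
    def mode_fraction(self) -> float:
        """Center of the modal bin, (m* + 1/2)/N; the top bin is the point 1."""
        m = int(np.argmax(self.frequencies))
        if m == self.n_agents:
            return 1.0
        return (m + 0.5) / self.n_agents


def outcome_distribution(
    params: ModelParams,
    n_runs: int,
    rng: np.random.Generator,
    threshold: float = 0.5,
) -> OutcomeDistribution:
    """Ensemble distribution of the final adolescence-limited fraction.

    Runs ``n_runs`` independent simulations, each from a fresh random
    initial condition drawn from ``rng``, classifies agents at the
    given threshold on the final antisocial levels, and bins the
    per-run adolescence-limited counts.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    counts = np.zeros(params.n_agents + 1, dtype=int)
    for _ in range(n_runs):
        traj = run(params, initial=_draw_initial(params, rng))
        n_al = classify(traj.final_antisocial, threshold).al_indices.size
        counts[n_al] += 1
    return OutcomeDistribution(
        frequencies=counts / n_runs, n_agents=params.n_agents, n_runs=n_runs
    )


def _draw_initial(params: ModelParams, rng: np.random.Generator) -> InitialCondition:
    """One fresh random initial condition drawn from the given generator."""
    e0 = draw_initial_antisocial(params.n_agents, rng)
    return InitialCondition(antisocial0=e0, connections0=init_connections(e0, rng))


def kld(p: OutcomeDistribution, q: OutcomeDistribution) -> float:
    """Kullback-Leibler divergence sum_i p_i ln(p_i / q_i), in nats.

    Zero-bin convention: a term with q_i = 0 contributes 0 (the log
    argument is treated as 1), as does a term with p_i = 0.  Under
    this convention the divergence of disjoint distributions is 0, so
    it is only meaningful for overlapping histograms; the symmetrized
    ``jsd`` avoids the issue because its reference mixture is nonzero
    wherever p is.
    """
    pf, qf = _check_binning(p, q)
    mask = (pf > 0) & (qf > 0)
    return float(np.sum(pf[mask] * np.log(pf[mask] / qf[mask])))


def jsd(p: OutcomeDistribution, q: OutcomeDistribution) -> float:
    """Jensen-Shannon divergence (nats): symmetric, bounded by ln 2.

    JSD(p, q) = [KLD(p||m) + KLD(q||m)] / 2 with m the elementwise
    average of p and q.
    """
    pf, qf = _check_binning(p, q)
    m = OutcomeDistribution(
        frequencies=(pf + qf) / 2.0, n_agents=p.n_agents, n_runs=p.n_runs + q.n_runs
    )
    return (kld(p, m) + kld(q, m)) / 2.0


def _check_binning(p, q):
    if p.n_agents != q.n_agents or p.frequencies.size != q.frequencies.size:
        raise ValueError("distributions are binned differently")
    return p.frequencies, q.frequencies


def sensitivity_gradient(
    pert: ParamPerturbation,
    n_runs: int,
    direction: str,
    rng: np.random.Generator,
    base_distribution: OutcomeDistribution | None = None,
) -> dict[str, float]:
    """JSD-gradient entries, one per perturbed parameter.

    Builds the benchmark distribution F(p0) once (unless supplied),
    then for each parameter an ensemble at the perturbed set, and
    returns JSD(F(p0), F(p+-)) / delta for each parameter.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    f0 = base_distribution
    if f0 is None:
        f0 = outcome_distribution(pert.base, n_runs, rng)
    out = {}
    for name in pert.deltas:
        fp = outcome_distribution(pert.perturbed(name, direction), n_runs, rng)
        out[name] = jsd(f0, fp) / pert.deltas[name]
    return out


@dataclass
class SensitivityReport:
    """Full 8-way perturbation study (4 parameters x 2 directions)."""

    base_distribution: OutcomeDistribution
    distributions: dict  # (name, direction) -> OutcomeDistribution
    jsd_values: dict  # (name, direction) -> float
    gradients: dict  # (name, direction) -> float
    deltas: dict
    n_runs: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": name,
                "direction": direction,
                "delta": self.deltas[name],
                "jsd": self.jsd_values[(name, direction)],
                "gradient": self.gradients[(name, direction)],
            }
            for (name, direction) in self.gradients
        ]
        return pd.DataFrame(rows)


def sensitivity_study(
    pert: ParamPerturbation,
    n_runs: int,
    rng: np.random.Generator,
    directions: tuple[str, ...] = ("forward", "backward"),
) -> SensitivityReport:
    """Run the benchmark ensemble once and all perturbed ensembles.

    F(p0) is computed once and shared across all comparisons.
    """
    f0 = outcome_distribution(pert.base, n_runs, rng)
    dists, jsds, grads = {}, {}, {}
    for name in pert.deltas:
        for direction in directions:
            fp = outcome_distribution(pert.perturbed(name, direction), n_runs, rng)
            key = (name, direction)
            dists[key] = fp
            jsds[key] = jsd(f0, fp)
            grads[key] = jsds[key] / pert.deltas[name]
    return SensitivityReport(
        base_distribution=f0,
        distributions=dists,
        jsd_values=jsds,
        gradients=grads,
        deltas=dict(pert.deltas),
        n_runs=n_runs,
    )


__all__ = [
    "DEFAULT_DELTAS",
    "OutcomeDistribution",
    "ParamPerturbation",
    "SensitivityReport",
    "jsd",
    "kld",
    "outcome_distribution",
    "sensitivity_gradient",
    "sensitivity_study",
]
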