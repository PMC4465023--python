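"""In-silico transplant intervention experiment.

The experiment asks whether a youth's life-course outcome is fixed by
their intrinsic disposition or shaped by their peer network.  It pairs
"rough" networks (initial conditions whose simulation ends with at
least five agents above the classification threshold) with "mild" ones
(no agent above it), both found by rejection sampling.  From each rough
network four focal agents are selected on the final antisocial levels:

* guaranteed adolescence-limited (lowest final level),
* borderline adolescence-limited / borderline life-course-persistent
  (the two members of the largest adjacent gap in sorted final levels),
* guaranteed life-course-persistent (highest final level).

Each focal agent is transplanted, one at a time, into the paired mild
network: a new agent is added carrying only the focal agent's initial
antisocial level, with fresh random connections rescaled by the
intrinsic prosocial levels, and the enlarged (N+1)-agent network is
re-simulated.  The intervention effect is the paired reduction: the
focal agent's final level in its native rough run minus the transplant's
final level in the mild run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .initialization import InitialCondition
from .params import ModelParams
from .simulation import Trajectory, largest_gap_split, run

#: scenario labels, in the order alpha_1 .. alpha_4
SCENARIOS = (
    "guaranteed_al",
    "borderline_al",
    "borderline_lcp",
    "guaranteed_lcp",
)

#: a rough network ends with at least this many agents above threshold
ROUGH_MIN_LCP = 5


@dataclass
class NetworkSearchResult:
    """A found network with its replayable initial condition."""

    initial: InitialCondition
    trajectory: Trajectory
    n_attempts: int
    kind: str  # "rough" | "mild"


@dataclass
class FocalSelection:
    """The four focal agents of a rough network (indices + levels)."""

    indices: dict  # scenario -> agent index
    initial_levels: dict  # scenario -> e_i(0)
    final_levels: dict  # scenario -> e_i(T)


@dataclass
class TransplantResult:
    """Outcome of one transplant scenario in one network pair."""

    scenario: str
    alpha_index: int
    alpha_initial: float
    native_final: float
    transplanted_final: float

    @property
    def reduction(self) -> float:
        return self.native_final - self.transplanted_final


def satisfies(kind: str, final_e: np.ndarray, threshold: float = 0.5) -> bool:
    """Rough/mild predicate on a run's final antisocial levels."""
    n_lcp = int(np.sum(final_e > threshold))
    if kind == "rough":
        return n_lcp >= ROUGH_MIN_LCP
    if kind == "mild":
        return n_lcp == 0
    raise ValueError(f"unknown network kind {kind!r}")


def find_network(
    params: ModelParams,
    kind: str,
    rng: np.random.Generator,
    max_attempts: int = 5000,
    threshold: float = 0.5,
) -> NetworkSearchResult:
    """Rejection-sample initial conditions until the predicate holds.

    Each attempt draws a fresh random initial condition (antisocial
    levels and connections), simulates it to T, and checks the final
    state.  Raises with the observed life-course-persistent count
    distribution if ``max_attempts`` is exhausted.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be at least 1")
    if kind not in ("rough", "mild"):
        raise ValueError(f"unknown network kind {kind!r}")
    lcp_counts: list[int] = []
    for attempt in range(1, max_attempts + 1):
        seed = int(rng.integers(0, 2**31))
        traj = run(params.replace(seed=seed))
        final = traj.final_antisocial
        if satisfies(kind, final, threshold):
            return NetworkSearchResult(
                initial=traj.initial,
                trajectory=traj,
                n_attempts=attempt,
                kind=kind,
            )
        lcp_counts.append(int(np.sum(final > threshold)))
    counts = np.bincount(lcp_counts, minlength=params.n_agents + 1)
    raise RuntimeError(
        f"no {kind} network found in {max_attempts} attempts; observed "
        f"life-course-persistent counts (count: runs): "
        + ", ".join(f"{k}: {v}" for k, v in enumerate(counts) if v)
    )


def select_focal(rough: Trajectory) -> FocalSelection:
    """Pick the four focal agents from a rough run's final levels.

    The guaranteed agents are the argmin/argmax of the final antisocial
    level (ties broken toward the lowest index); the borderline pair
    straddles the largest adjacent gap in the sorted final levels.  The
    initial antisocial level of each is recorded: it is the only
    quantity transferred by a transplant.
    """
    final = rough.final_antisocial
    lo, hi = largest_gap_split(final)
    idx = {
        "guaranteed_al": int(np.argmin(final)),
        "borderline_al": lo,
        "borderline_lcp": hi,
        "guaranteed_lcp": int(np.argmax(final)),
    }
    e0 = rough.initial.antisocial0
    return FocalSelection(
        indices=idx,
        initial_levels={s: float(e0[i]) for s, i in idx.items()},
        final_levels={s: float(final[i]) for s, i in idx.items()},
    )


def transplant(
    mild: InitialCondition,
    alpha_initial_e: float,
    params: ModelParams,
    rng: np.random.Generator,
) -> Trajectory:
    """Add one agent to a mild network and re-simulate with N+1 agents.

    The mild network's own initial levels and connections are reused
    bit-for-bit; the new agent (index N) gets the focal agent's initial
    antisocial level and fresh symmetric connections, one Uniform(0, 1)
    draw per existing agent rescaled by r_beta * r_j with the t = 0
    intrinsic prosocial levels.
    """
    if not 0 <= alpha_initial_e < 1:
        raise ValueError("transplanted initial antisocial level must be in [0, 1)")
    n = mild.n_agents
    e0 = np.append(mild.antisocial0, alpha_initial_e)
    conn = np.zeros((n + 1, n + 1))
    conn[:n, :n] = mild.connections0
    r = 1.0 - e0
    beta_weights = rng.uniform(0.0, 1.0, size=n) * r[n] * r[:n]
    conn[n, :n] = beta_weights
    conn[:n, n] = beta_weights
    enlarged = InitialCondition(antisocial0=e0, connections0=conn)
    return run(params.replace(n_agents=n + 1), initial=enlarged)


@dataclass
class PairedExperimentResult:
    """Per-pair transplant outcomes and per-scenario summaries."""

    results: pd.DataFrame  # pair, scenario, alpha_initial, finals, reduction
    pair_seeds: pd.DataFrame  # pair, rough_seed, mild_seed, attempts
    n_pairs: int

    def summary(self) -> pd.DataFrame:
        """Mean, sample sd and n of the reduction, per scenario."""
        g = self.results.groupby("scenario", sort=False)["reduction"]
        out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
        return out.reindex(list(SCENARIOS))

    def mean_reduction(self, scenario: str) -> float:
        sel = self.results.loc[self.results["scenario"] == scenario, "reduction"]
        return float(sel.mean())


def paired_experiment(
    params: ModelParams,
    n_pairs: int = 50,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 5000,
    threshold: float = 0.5,
) -> PairedExperimentResult:
    """Run the full paired rough-to-mild transplant experiment.

    For each of ``n_pairs`` pairs: find a rough and a mild network by
    rejection sampling, select the four focal agents of the rough run,
    and transplant each into the mild network (one at a time; the four
    scenarios share the mild base but use independent draws for the new
    agent's connections).  Reports the per-pair reductions and records
    every seed for exact replay.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be at least 1")
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    rows = []
    seed_rows = []
    for pair in range(n_pairs):
        rough = find_network(params, "rough", rng, max_attempts, threshold)
        mild = find_network(params, "mild", rng, max_attempts, threshold)
        focal = select_focal(rough.trajectory)
        seed_rows.append(
            {
                "pair": pair,
                "rough_seed": rough.initial.seed,
                "mild_seed": mild.initial.seed,
                "rough_attempts": rough.n_attempts,
                "mild_attempts": mild.n_attempts,
            }
        )
        for scenario in SCENARIOS:
            traj = transplant(
                mild.initial, focal.initial_levels[scenario], params, rng
            )
            result = TransplantResult(
                scenario=scenario,
                alpha_index=focal.indices[scenario],
                alpha_initial=focal.initial_levels[scenario],
                native_final=focal.final_levels[scenario],
                transplanted_final=float(traj.final_antisocial[-1]),
            )
            rows.append(
                {
                    "pair": pair,
                    "scenario": scenario,
                    "alpha_index": result.alpha_index,
                    "alpha_initial": result.alpha_initial,
                    "native_final": result.native_final,
                    "transplanted_final": result.transplanted_final,
                    "reduction": result.reduction,
                }
            )
    return PairedExperimentResult(
        results=pd.DataFrame(rows),
        pair_seeds=pd.DataFrame(seed_rows),
        n_pairs=n_pairs,
    )


__all__ = [
    "SCENARIOS",
    "ROUGH_MIN_LCP",
    "FocalSelection",
    "NetworkSearchResult",
    "PairedExperimentResult",
    "TransplantResult",
    "find_network",
    "paired_experiment",
    "satisfies",
    "select_focal",
    "transplant",
]
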