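"""Benchmark protocols on random N-K networks and scenario sweeps.

Three synthetic benchmarks, all reproducible bit-for-bit from one master
seed:

* **Trial counts** — how many start vectors the prior-guided enumeration
  examines before reaching a target state, as a function of network size and
  prior confidence.  A target attractor state is obtained by simulating a
  seeded N-K network from a random state; each replicate perturbs it into a
  guess (each bit kept with probability p) and the trial number is computed
  in closed form as S(n,k) plus the within-weight colexicographic rank —
  mathematically identical to counting trials one by one, but feasible at
  means of order 10^10.  The analytic expectation E(n, p) is the exact mean
  of this statistic.

* **Trajectory lengths** — mean transient (steps before the cycle, period
  excluded) from uniform random starts, by network size.

* **Prior vs random restarts** — total transient steps spent until the
  target attractor is found, restarting either from prior-ordered start
  vectors (guided) or from uniform random states (unguided).

The scenario sweep reproduces the biological protocol: fix some nodes at
confidence 1, fill the remaining guess bits with a scenario constant (all ON
or all OFF), sweep the confidence of the filled bits, and collect attractors
under limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import extract_attractor, simulate_to_attractor
from .network import BooleanNetwork, State
from .search import (
    AttractorCriteria,
    SearchConfig,
    attapriori_search,
    canonicalize_prior,
    iterate_start_vectors,
    trial_index_of_target,
    uniform_prior,
)
from .synthetic import NKConfig, derive_seed, generate_nk, perturb_state, random_state
from .theory import theoretical_trial_bound

__all__ = [
    "TrialsExperimentSpec",
    "ScenarioSpec",
    "run_trials_experiment",
    "run_trajectory_length_experiment",
    "run_comparison_experiment",
    "run_scenario_sweep",
]


@dataclass(frozen=True)
class TrialsExperimentSpec:
    """Trial-count benchmark: sizes, indegree, confidences, replicates, seed."""

    n_values: tuple[int, ...]
    p_values: tuple[float, ...]
    k: int = 2
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _target_state(n: int, k: int, seed: int, step_cap: int | None = None) -> State:
    """One state of an attractor of a seeded N-K network (via simulation)."""
    net = generate_nk(NKConfig(n=n, k=k, seed=derive_seed(seed, "net", n)))
    start = random_state(n, derive_seed(seed, "start", n))
    traj = simulate_to_attractor(net, start, step_cap)
    att = extract_attractor(traj)
    return att.cycle[0]


def run_trials_experiment(spec: TrialsExperimentSpec) -> pd.DataFrame:
    """Mean closed-form trial counts per (N, p), with standard errors.

    Per replicate the guess is the target state with each bit independently
    kept with probability p; the count is the exact trial index at which the
    enumeration would examine the target.  Columns: n, p, mean_trials, se,
    theory_envelope, replicates, seed.
    """
    rows = []
    for n in spec.n_values:
        target = _target_state(n, spec.k, spec.seed)
        for p in spec.p_values:
            counts = np.empty(spec.replicates, dtype=float)
            for r in range(spec.replicates):
                guess = perturb_state(
                    target, p, derive_seed(spec.seed, "perturb", n, int(p * 1000), r)
                )
                prior = uniform_prior([f"x{i+1}" for i in range(n)], guess, p if p < 1 else 1.0)
                counts[r] = trial_index_of_target(prior, target)
            envelope = theoretical_trial_bound(n, p) if p < 1 else float("nan")
            rows.append(
                {
                    "n": n,
                    "p": p,
                    "mean_trials": counts.mean(),
                    "se": counts.std(ddof=1) / math.sqrt(spec.replicates)
                    if spec.replicates > 1
                    else 0.0,
                    "theory_envelope": envelope,
                    "replicates": spec.replicates,
                    "seed": spec.seed,
                }
            )
    return pd.DataFrame(rows)


def run_trajectory_length_experiment(
    n_values: Sequence[int],
    k: int = 2,
    replicates: int = 100,
    seed: int = 0,
    step_cap: int | None = None,
) -> pd.DataFrame:
    """Mean transient and period lengths from random starts, by network size.

    Each replicate draws a fresh seeded N-K network and a uniform random
    start.  Transients exclude the cycle.  Trials truncated by the step cap
    are counted and excluded from the means.
    """
    rows = []
    for n in n_values:
        transients: list[int] = []
        periods: list[int] = []
        truncated = 0
        for r in range(replicates):
            net = generate_nk(NKConfig(n=n, k=k, seed=derive_seed(seed, "net", n, r)))
            start = random_state(n, derive_seed(seed, "start", n, r))
            traj = simulate_to_attractor(net, start, step_cap)
            if traj.truncated:
                truncated += 1
                continue
            transients.append(traj.transient_length)
            periods.append(extract_attractor(traj).period)
        arr = np.asarray(transients, dtype=float)
        rows.append(
            {
                "n": n,
                "mean_transient": arr.mean() if arr.size else float("nan"),
                "se": arr.std(ddof=1) / math.sqrt(arr.size) if arr.size > 1 else 0.0,
                "mean_period": float(np.mean(periods)) if periods else float("nan"),
                "truncated": truncated,
                "replicates": replicates,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def run_comparison_experiment(
    n_values: Sequence[int],
    p: float = 0.9,
    replicates: int = 100,
    k: int = 2,
    seed: int = 0,
    step_cap: int | None = None,
    restart_cap: int = 100_000,
) -> pd.DataFrame:
    """Total transient steps to reach the target attractor, guided vs unguided.

    Per replicate a fresh seeded N-K network is drawn and its target
    attractor fixed by simulation from a random state.  The unguided method
    restarts from uniform random states until the canonical target attractor
    is reached; the guided method restarts from prior-ordered start vectors
    around a perturbed guess.  Both sum transient steps (periods excluded).
    Runs hitting ``restart_cap`` are flagged and excluded from means.
    """
    rows = []
    names_cache: dict[int, list[str]] = {}
    for n in n_values:
        guided_totals: list[int] = []
        random_totals: list[int] = []
        capped = 0
        for r in range(replicates):
            net = generate_nk(NKConfig(n=n, k=k, seed=derive_seed(seed, "cmpnet", n, r)))
            start = random_state(n, derive_seed(seed, "cmpstart", n, r))
            target = extract_attractor(simulate_to_attractor(net, start, step_cap))

            # unguided: uniform random restarts
            rng = np.random.default_rng(derive_seed(seed, "cmprng", n, r))
            total_random = 0
            ok_random = False
            for _ in range(restart_cap):
                s = tuple(int(b) for b in rng.integers(0, 2, size=n))
                traj = simulate_to_attractor(net, s, step_cap)
                if traj.truncated:
                    continue
                total_random += traj.transient_length
                if extract_attractor(traj) == target:
                    ok_random = True
                    break

            # guided: prior-ordered restarts around the perturbed target state
            guess = perturb_state(
                target.cycle[0], p, derive_seed(seed, "cmpperturb", n, r)
            )
            names = names_cache.setdefault(n, [f"x{i+1}" for i in range(n)])
            prior = uniform_prior(names, guess, p)
            total_guided = 0
            ok_guided = False
            for trial, s in enumerate(iterate_start_vectors(prior)):
                if trial >= restart_cap:
                    break
                traj = simulate_to_attractor(net, s, step_cap)
                if traj.truncated:
                    continue
                total_guided += traj.transient_length
                if extract_attractor(traj) == target:
                    ok_guided = True
                    break

            if ok_random and ok_guided:
                guided_totals.append(total_guided)
                random_totals.append(total_random)
            else:
                capped += 1
        g = np.asarray(guided_totals, dtype=float)
        u = np.asarray(random_totals, dtype=float)
        rows.append(
            {
                "n": n,
                "p": p,
                "mean_total_steps_apriori": g.mean() if g.size else float("nan"),
                "se_apriori": g.std(ddof=1) / math.sqrt(g.size) if g.size > 1 else 0.0,
                "mean_total_steps_random": u.mean() if u.size else float("nan"),
                "se_random": u.std(ddof=1) / math.sqrt(u.size) if u.size > 1 else 0.0,
                "capped": capped,
                "replicates": replicates,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioSpec:
    """A scenario sweep: fixed bits at confidence 1, a fill value for the rest,
    and the confidences to sweep for the filled bits."""

    fixed: Mapping[str, int]
    fill: int
    confidences: tuple[float, ...]
    scenario_id: str = ""
    criteria: AttractorCriteria = field(
        default_factory=lambda: AttractorCriteria(accept_any=True)
    )
    max_trials: int | None = None
    time_limit: float | None = None
    step_cap: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fill not in (0, 1):
            raise ValueError("fill must be 0 or 1")


def run_scenario_sweep(net: BooleanNetwork, spec: ScenarioSpec) -> pd.DataFrame:
    """Collect-all searches, one per swept confidence, for one scenario.

    Fixed nodes get their assigned bit at confidence 1; every other node is
    guessed at the scenario fill value with the swept confidence.  Output has
    one row per detected attractor with its period and criteria verdict.
    """
    missing = [name for name in spec.fixed if name not in net.node_names]
    if missing:
        raise ValueError(f"fixed nodes not in network: {missing}")
    rows = []
    for conf in spec.confidences:
        guesses = []
        probs = []
        for name in net.node_names:
            if name in spec.fixed:
                guesses.append(spec.fixed[name])
                probs.append(1.0)
            else:
                guesses.append(spec.fill)
                probs.append(conf)
        prior = canonicalize_prior(net.node_names, guesses, probs)
        config = SearchConfig(
            step_cap=spec.step_cap,
            max_trials=spec.max_trials,
            time_limit=spec.time_limit,
            seed=spec.seed,
            mode="collect_all",
        )
        result = attapriori_search(net, prior, AttractorCriteria(accept_any=True), config)
        for att in result.attractors:
            rows.append(
                {
                    "scenario": spec.scenario_id,
                    "fill": spec.fill,
                    "confidence": conf,
                    "period": att.period,
                    "cycle": ["".join(map(str, s)) for s in att.cycle],
                    "meets_criteria": spec.criteria.matches(att, net.node_names),
                    "trials_used": result.trials_used,
                    "termination": result.termination_reason,
                }
            )
        if not result.attractors:
            rows.append(
                {
                    "scenario": spec.scenario_id,
                    "fill": spec.fill,
                    "confidence": conf,
                    "period": None,
                    "cycle": [],
                    "meets_criteria": False,
                    "trials_used": result.trials_used,
                    "termination": result.termination_reason,
                }
            )
    return pd.DataFrame(rows)
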