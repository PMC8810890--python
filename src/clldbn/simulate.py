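"""Ancestral (forward) sampling of patient trajectories.

Sampling draws whole trajectories from the unrolled joint — slice 0 from
the prior model, subsequent slices from the transition model, each variable
after its parents.  It is the package's independent Monte-Carlo check on
the exact engine (:func:`compare_mc_exact`) and a synthetic-cohort
generator.

Randomness comes from counter-based Philox streams, one per
(variable, slice) sampling step, keyed by the user seed.  Each step draws
exactly one uniform per trajectory from the start of its stream, so runs
are bitwise reproducible and the first 100 trajectories of an N=1000 run
equal the N=100 run (prefix stability).

Interventions are applied as CPT surgery before sampling, with exactly the
inference module's semantics.  Hard evidence is not supported here:
sampling is prediction-only (conditioning would require weighting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DynamicBayesianNetwork, topological_order, unrolled_parents
from .inference import InterventionSet, predict_marginals

__all__ = [
    "TrajectorySamples",
    "CohortSummary",
    "sample_trajectories",
    "summarize_cohort",
    "compare_mc_exact",
]


@dataclass
class TrajectorySamples:
    """N sampled trajectories as state indices, plus the labels to decode them."""

    network: str
    seed: int
    states: dict[str, tuple[str, ...]]
    data: dict[tuple[str, int], np.ndarray]  # (var, slice) -> int array of shape (N,)

    @property
    def n(self) -> int:
        return len(next(iter(self.data.values())))

    @property
    def n_slices(self) -> int:
        return max(t for _, t in self.data) + 1

    def labels(self, var: str, t: int) -> np.ndarray:
        return np.asarray(self.states[var], dtype=object)[self.data[(var, t)]]

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (trajectory, slice), one column per variable."""
        T = self.n_slices
        n = self.n
        frames = []
        for t in range(T):
            cols = {"trajectory": np.arange(n), "slice": t}
            for var in self.states:
                cols[var] = self.labels(var, t)
            frames.append(pd.DataFrame(cols))
        return pd.concat(frames, ignore_index=True).sort_values(
            ["trajectory", "slice"], kind="stable", ignore_index=True
        )


@dataclass
class CohortSummary:
    network: str
    n: int
    frequencies: dict[tuple[str, int], np.ndarray]  # empirical state distribution
    survival: np.ndarray | None  # empirical P(Survival = yes) per slice


def _step_rng(seed: int, step: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=(np.uint64(seed), np.uint64(step))))


def sample_trajectories(
    dbn: DynamicBayesianNetwork,
    n: int,
    T: int,
    seed: int,
    interventions: InterventionSet | None = None,
) -> TrajectorySamples:
    """Draw ``n`` i.i.d. trajectories over slices 0..T from the (intervened) joint."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T}")
    interventions = interventions if interventions is not None else InterventionSet()
    interventions.validate_against(dbn)
    order = topological_order(dbn, T + 1)  # validates the network
    data: dict[tuple[str, int], np.ndarray] = {}
    # CPT arrays cached per (var, effective model, intervention state)
    for step, (var, t) in enumerate(order):
        cpt = interventions.cpt_for(dbn, var, t)
        child = dbn.variable(var)
        parent_nodes = unrolled_parents(dbn, var, t)
        parent_vars = [dbn.variable(v) for v, _ in parent_nodes]
        shape = tuple(v.cardinality for v in parent_vars) + (child.cardinality,)
        arr = np.empty(shape)
        for key, row in cpt.table.items():
            arr[tuple(v.state_index(s) for v, s in zip(parent_vars, key))] = row
        rows = arr[tuple(data[node] for node in parent_nodes)] if parent_nodes else np.broadcast_to(
            arr, (n,) + arr.shape
        )
        cdf = np.cumsum(rows, axis=-1)
        u = _step_rng(seed, step).random(n)
        idx = np.minimum((u[:, None] >= cdf).sum(axis=1), child.cardinality - 1)
        data[(var, t)] = idx.astype(np.int64)
    states = {v.name: v.states for v in dbn.variables.values()}
    return TrajectorySamples(dbn.name, seed, states, data)


def summarize_cohort(samples: TrajectorySamples, survival_variable: str | None = "Survival") -> CohortSummary:
    """Empirical per-slice state frequencies and the survival proportion series."""
    n = samples.n
    freqs: dict[tuple[str, int], np.ndarray] = {}
    for (var, t), idx in samples.data.items():
        card = len(samples.states[var])
        freqs[(var, t)] = np.bincount(idx, minlength=card) / n
    survival = None
    if survival_variable is not None and survival_variable in samples.states:
        yes = samples.states[survival_variable].index("yes")
        T = samples.n_slices
        survival = np.array([freqs[(survival_variable, t)][yes] for t in range(T)])
    return CohortSummary(samples.network, n, freqs, survival)


def compare_mc_exact(
    dbn: DynamicBayesianNetwork,
    n: int,
    T: int,
    seed: int,
    query: list[str] | str,
    interventions: InterventionSet | None = None,
    sigmas: float = 4.0,
) -> pd.DataFrame:
    """Empirical vs exact marginals, with the Monte-Carlo tolerance per entry.

    One row per (variable, slice, state): empirical frequency, exact
    probability, absolute deviation, the binomial standard error
    sqrt(p(1-p)/n) under the exact p, and a flag marking deviations beyond
    ``sigmas`` standard errors (a tiny absolute floor guards p = 0/1 rows,
    where the binomial error vanishes but rounding does not).
    """
    query_vars = [query] if isinstance(query, str) else list(query)
    samples = sample_trajectories(dbn, n, T, seed, interventions)
    summary = summarize_cohort(samples, survival_variable=None)
    exact = predict_marginals(dbn, T, query_vars, interventions=interventions)
    records = []
    for var in query_vars:
        traj = exact[var]
        for t in range(T + 1):
            emp = summary.frequencies[(var, t)]
            for i, state in enumerate(traj.states):
                p = traj.probabilities[t, i]
                se = float(np.sqrt(p * (1 - p) / n))
                dev = abs(emp[i] - p)
                records.append(
                    {
                        "variable": var,
                        "slice": t,
                        "state": state,
                        "empirical": emp[i],
                        "exact": p,
                        "abs_deviation": dev,
                        "mc_se": se,
                        "flagged": dev > sigmas * se + 1e-12,
                    }
                )
    return pd.DataFrame.from_records(records)
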