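"""Shared fixtures: toy networks and the shipped CLL networks."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from clldbn.networks import load_network
from clldbn.networks._build import NetworkBuilder, det


@pytest.fixture(scope="session")
def hsn():
    return load_network("hsn")


@pytest.fixture(scope="session")
def ten():
    return load_network("ten")


def make_single_var_net(p_yes: float = 0.3, p_stay_yes: float = 0.9):
    """One binary variable: prior P(yes), transition P(yes | yes)=p_stay, P(yes | no)=0.1."""
    b = NetworkBuilder("single")
    b.variable("X", ("yes", "no"))
    b.prior_cpt("X", [], {(): (p_yes, 1 - p_yes)})
    b.transition_cpt(
        "X", [("X", -1)], {("yes",): (p_stay_yes, 1 - p_stay_yes), ("no",): (0.1, 0.9)}
    )
    return b.build()


def make_chain_net():
    """A -> B intra-slice chain with persistence edges A@t-1 -> A@t, B@t-1 -> B@t."""
    b = NetworkBuilder("chain")
    b.variable("A", ("yes", "no"))
    b.variable("B", ("yes", "no"))
    b.prior_cpt("A", [], {(): (0.6, 0.4)})
    b.prior_cpt("B", [("A", 0)], {("yes",): (0.7, 0.3), ("no",): (0.2, 0.8)})
    b.transition_cpt("A", [("A", -1)], {("yes",): (0.8, 0.2), ("no",): (0.3, 0.7)})
    b.transition_cpt(
        "B",
        [("A", 0), ("B", -1)],
        {
            ("yes", "yes"): (0.9, 0.1),
            ("yes", "no"): (0.5, 0.5),
            ("no", "yes"): (0.4, 0.6),
            ("no", "no"): (0.1, 0.9),
        },
    )
    return b.build()


def make_geometric_death_net(hazard: float = 0.1):
    """Alive at t=0; per-slice death probability ``hazard``; death absorbing."""
    b = NetworkBuilder("geometric", survival_variable="Survival")
    b.variable("Survival", ("yes", "no"))
    b.prior_cpt("Survival", [], {(): (1.0, 0.0)})
    b.transition_cpt(
        "Survival",
        [("Survival", -1)],
        {("yes",): (1 - hazard, hazard), ("no",): (0.0, 1.0)},
    )
    return b.build()


def make_deterministic_net():
    """Every CPT row degenerate: exactly one trajectory has probability 1."""
    b = NetworkBuilder("det")
    b.variable("A", ("a0", "a1"))
    b.variable("B", ("b0", "b1"))
    b.prior_cpt("A", [], {(): det(("a0", "a1"), "a1")})
    b.prior_cpt("B", [("A", 0)], lambda a: det(("b0", "b1"), "b0" if a == "a1" else "b1"))
    b.transition_cpt("A", [("A", -1)], lambda a: det(("a0", "a1"), a))
    b.transition_cpt("B", [("A", 0)], lambda a: det(("b0", "b1"), "b0" if a == "a1" else "b1"))
    return b.build()


def make_random_net(rng: np.random.Generator, n_vars: int | None = None, allow_three_states: bool = True):
    """A random small DBN with dense-ish random structure and Dirichlet rows."""
    if n_vars is None:
        n_vars = int(rng.integers(3, 6))
    b = NetworkBuilder("toy")
    names = [f"V{i}" for i in range(n_vars)]
    three = int(rng.integers(0, n_vars)) if allow_three_states else -1
    for i, nm in enumerate(names):
        k = 3 if i == three else 2
        b.variable(nm, tuple(f"s{j}" for j in range(k)))

    def rand_rows(child, parents):
        pstates = [b.states(v) for v, _ in parents]
        return {
            key: tuple(rng.dirichlet(np.ones(len(b.states(child)))))
            for key in itertools.product(*pstates)
        }

    for i, nm in enumerate(names):
        parents = [(names[j], 0) for j in range(i) if rng.random() < 0.5]
        b.prior_cpt(nm, parents, rand_rows(nm, parents))
    for i, nm in enumerate(names):
        parents = [(names[j], -1) for j in range(n_vars) if rng.random() < 0.4]
        parents += [(names[j], 0) for j in range(i) if rng.random() < 0.4]
        b.transition_cpt(nm, parents, rand_rows(nm, parents))
    return b.build()
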