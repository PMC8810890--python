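"""Helpers for authoring network definitions in code.

The shipped YAML documents are generated from the builder modules
(:mod:`._hsn`, :mod:`._ten`) via ``scripts/regenerate_networks.py``; the
round-trip is covered by tests so code and documents cannot drift.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterable

from ..core import (
    ConditionalProbabilityTable,
    DynamicBayesianNetwork,
    PriorSliceModel,
    SlicedRef,
    TransitionModel,
    Variable,
)

YES, NO = "yes", "no"


def det(states: Iterable[str], chosen: str) -> tuple[float, ...]:
    """A degenerate (one-hot) distribution putting all mass on ``chosen``."""
    states = tuple(states)
    if chosen not in states:
        raise ValueError(f"{chosen!r} not among {states}")
    return tuple(1.0 if s == chosen else 0.0 for s in states)


def bern(p_yes: float) -> tuple[float, float]:
    """Distribution over a (yes, no) variable with P(yes) = p_yes."""
    return (p_yes, round(1.0 - p_yes, 12))


def table_from_fn(
    parent_states: list[tuple[str, ...]],
    fn: Callable[..., tuple[float, ...]],
) -> dict[tuple[str, ...], tuple[float, ...]]:
    """Enumerate all parent assignments and build rows with ``fn(*states)``."""
    return {
        key: tuple(fn(*key)) for key in itertools.product(*parent_states)
    }


class NetworkBuilder:
    def __init__(self, name: str, survival_variable: str | None = None):
        self.name = name
        self.survival_variable = survival_variable
        self.variables: dict[str, Variable] = {}
        self.prior = PriorSliceModel()
        self.transition = TransitionModel()

    def variable(self, name: str, states: Iterable[str], description: str = "") -> Variable:
        if name in self.variables:
            raise ValueError(f"duplicate variable {name!r}")
        v = Variable(name, tuple(states), description)
        self.variables[name] = v
        return v

    def states(self, name: str) -> tuple[str, ...]:
        return self.variables[name].states

    def _add(
        self,
        model,
        child: str,
        parents: list[tuple[str, int]],
        rows,
        provenance: str,
        structure: str,
    ) -> None:
        refs = tuple(SlicedRef(v, off) for v, off in parents)
        if callable(rows):
            rows = table_from_fn([self.states(v) for v, _ in parents], rows)
        model.cpts[child] = ConditionalProbabilityTable(
            child=child,
            parents=refs,
            table=rows,
            provenance=provenance,
            structure=structure,
        )

    def prior_cpt(self, child, parents, rows, provenance="placeholder", structure="inferred"):
        self._add(self.prior, child, parents, rows, provenance, structure)

    def transition_cpt(self, child, parents, rows, provenance="placeholder", structure="inferred"):
        self._add(self.transition, child, parents, rows, provenance, structure)

    def build(self) -> DynamicBayesianNetwork:
        return DynamicBayesianNetwork(
            name=self.name,
            variables=dict(self.variables),
            prior=self.prior,
            transition=self.transition,
            slice_duration_months=6.0,
            survival_variable=self.survival_variable,
        )
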