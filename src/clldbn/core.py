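"""Discrete two-slice dynamic Bayesian networks.

A DBN here is a pair of Bayesian networks over the same variable catalog:
a *prior* network B0 describing the initial slice (t = 0) and a *transition*
network describing slice t conditioned on slice t-1.  Time is first-order
Markov: a parent lives either in the current slice (offset 0) or the
previous one (offset -1).  The joint over an unrolled horizon 0..T factorises
as the product of the prior-slice CPT entries at t = 0 and the transition
CPT entries at t = 1..T.

Variables are purely categorical; each node carries a conditional
probability table (CPT) with one row (a distribution over the child's
states) per combination of parent states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

ROW_SUM_TOL = 1e-9

__all__ = [
    "Variable",
    "SlicedRef",
    "ConditionalProbabilityTable",
    "PriorSliceModel",
    "TransitionModel",
    "DynamicBayesianNetwork",
    "ValidationReport",
    "ValidationError",
    "validate_network",
    "parents_of",
    "topological_order",
    "joint_probability",
]


class ValidationError(ValueError):
    """Raised when an operation requires a valid network and gets an invalid one."""


@dataclass(frozen=True)
class Variable:
    """A named discrete node with an ordered state space.

    State order is significant: CPT rows and probability vectors follow it,
    and it survives serialization round-trips.
    """

    name: str
    states: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise ValueError(f"variable {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate state labels")

    @property
    def cardinality(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown state {state!r} for variable {self.name!r}") from None


@dataclass(frozen=True, order=True)
class SlicedRef:
    """Reference to a variable in the current (offset 0) or previous (offset -1) slice."""

    var: str
    offset: int = 0

    def __post_init__(self) -> None:
        if self.offset not in (-1, 0):
            raise ValueError(
                f"parent offset must be -1 or 0 (first-order Markov), got {self.offset}"
            )

    def __str__(self) -> str:
        return f"{self.var}@t{self.offset}" if self.offset else f"{self.var}@t"


@dataclass
class ConditionalProbabilityTable:
    """P(child | parents): one probability vector per full parent assignment.

    ``table`` maps a tuple of parent state labels (in ``parents`` order; the
    empty tuple for root nodes) to a tuple of probabilities in the child's
    state order.  ``provenance`` records where the numbers come from
    (``paper`` or ``placeholder``) and ``structure`` where the parent set
    comes from (``paper`` or ``inferred``).
    """

    child: str
    parents: tuple[SlicedRef, ...]
    table: dict[tuple[str, ...], tuple[float, ...]]
    provenance: str = "placeholder"
    structure: str = "inferred"

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.table = {tuple(k): tuple(float(x) for x in v) for k, v in self.table.items()}

    def row(self, *parent_states: str) -> tuple[float, ...]:
        key = tuple(parent_states)
        if key not in self.table:
            raise KeyError(f"no CPT row for parent assignment {key!r} of {self.child!r}")
        return self.table[key]

    def probability(self, child_state_index: int, parent_states: tuple[str, ...]) -> float:
        return self.row(*parent_states)[child_state_index]


@dataclass
class PriorSliceModel:
    """B0: one CPT per variable, all parents in the same slice (offset 0)."""

    cpts: dict[str, ConditionalProbabilityTable] = field(default_factory=dict)


@dataclass
class TransitionModel:
    """B->: one CPT per slice-t variable, parents drawn from slices t-1 and t."""

    cpts: dict[str, ConditionalProbabilityTable] = field(default_factory=dict)


@dataclass
class DynamicBayesianNetwork:
    name: str
    variables: dict[str, Variable]
    prior: PriorSliceModel
    transition: TransitionModel
    slice_duration_months: float = 6.0
    survival_variable: str | None = None
    schema_version: int = 1

    def variable(self, name: str) -> Variable:
        try:
            return self.variables[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r} in network {self.name!r}") from None

    @property
    def n_variables(self) -> int:
        return len(self.variables)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.is_valid

    def __str__(self) -> str:
        if self.is_valid:
            return "valid"
        return "\n".join(self.violations)


def _check_cpt(
    dbn: DynamicBayesianNetwork,
    cpt: ConditionalProbabilityTable,
    where: str,
    allow_prev_slice: bool,
    out: list[str],
) -> None:
    if cpt.child not in dbn.variables:
        out.append(f"{where}: CPT child {cpt.child!r} is not a declared variable")
        return
    child = dbn.variables[cpt.child]
    parent_vars = []
    for ref in cpt.parents:
        if ref.var not in dbn.variables:
            out.append(f"{where}/{cpt.child}: dangling parent reference {ref.var!r}")
            return
        if ref.offset == -1 and not allow_prev_slice:
            out.append(
                f"{where}/{cpt.child}: prior-slice CPT may not reference slice t-1 ({ref})"
            )
            return
        parent_vars.append(dbn.variables[ref.var])

    expected = set(
        itertools.product(*(v.states for v in parent_vars)) if parent_vars else [()]
    )
    seen = set(cpt.table)
    for key in seen - expected:
        out.append(f"{where}/{cpt.child}: unexpected parent assignment {key!r}")
    for key in sorted(expected - seen):
        out.append(f"{where}/{cpt.child}: missing parent assignment {key!r}")
    for key in seen & expected:
        row = cpt.table[key]
        if len(row) != child.cardinality:
            out.append(
                f"{where}/{cpt.child}: row {key!r} has {len(row)} entries, "
                f"expected {child.cardinality}"
            )
            continue
        if any(p < 0 for p in row):
            out.append(f"{where}/{cpt.child}: row {key!r} has a negative probability")
        s = sum(row)
        if abs(s - 1.0) > ROW_SUM_TOL:
            out.append(f"{where}/{cpt.child}: row sum {s:.10g} for parent assignment {key!r}")


def _intra_slice_graph(cpts: dict[str, ConditionalProbabilityTable]) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(cpts)
    for cpt in cpts.values():
        for ref in cpt.parents:
            if ref.offset == 0:
                g.add_edge(ref.var, cpt.child)
    return g


def validate_network(dbn: DynamicBayesianNetwork) -> ValidationReport:
    """Structural and numerical validation; violations are reported, not raised.

    Checks: every variable has a prior and a transition CPT; CPT rows cover
    each parent combination exactly once and sum to 1 within ``ROW_SUM_TOL``;
    all references resolve; parent offsets are legal; the intra-slice
    (offset-0) graphs of both the prior and the transition model are acyclic.
    """
    out: list[str] = []
    for name in dbn.variables:
        if name not in dbn.prior.cpts:
            out.append(f"prior: variable {name!r} has no CPT")
        if name not in dbn.transition.cpts:
            out.append(f"transition: variable {name!r} has no CPT")
    for name, cpt in dbn.prior.cpts.items():
        if name != cpt.child:
            out.append(f"prior: CPT keyed {name!r} declares child {cpt.child!r}")
        _check_cpt(dbn, cpt, "prior", allow_prev_slice=False, out=out)
    for name, cpt in dbn.transition.cpts.items():
        if name != cpt.child:
            out.append(f"transition: CPT keyed {name!r} declares child {cpt.child!r}")
        _check_cpt(dbn, cpt, "transition", allow_prev_slice=True, out=out)

    for label, model in (("prior", dbn.prior), ("transition", dbn.transition)):
        g = _intra_slice_graph(model.cpts)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            out.append(f"{label}: cycle among intra-slice edges ({path})")

    if dbn.survival_variable is not None and dbn.survival_variable not in dbn.variables:
        out.append(f"survival_variable {dbn.survival_variable!r} is not a declared variable")
    return ValidationReport(out)


def parents_of(
    dbn: DynamicBayesianNetwork, variable: str, slice_kind: str = "transition"
) -> tuple[SlicedRef, ...]:
    """The CPT's ordered parent list for ``variable``; empty for root nodes."""
    dbn.variable(variable)
    if slice_kind == "prior":
        return dbn.prior.cpts[variable].parents
    if slice_kind == "transition":
        return dbn.transition.cpts[variable].parents
    raise ValueError(f"slice_kind must be 'prior' or 'transition', got {slice_kind!r}")


def unrolled_parents(
    dbn: DynamicBayesianNetwork, variable: str, t: int
) -> tuple[tuple[str, int], ...]:
    """Parents of variable-at-slice-t as absolute (name, slice) pairs."""
    cpt = dbn.prior.cpts[variable] if t == 0 else dbn.transition.cpts[variable]
    return tuple((ref.var, t + ref.offset) for ref in cpt.parents)


def topological_order(dbn: DynamicBayesianNetwork, n_slices: int) -> list[tuple[str, int]]:
    """A parent-before-child order over the network unrolled to ``n_slices``.

    Slices are numbered 0..n_slices-1; deterministic (lexicographic
    tie-break on slice then name).
    """
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    report = validate_network(dbn)
    if not report:
        raise ValidationError(str(report))
    g = nx.DiGraph()
    for t in range(n_slices):
        for name in dbn.variables:
            g.add_node((name, t))
            for pref in unrolled_parents(dbn, name, t):
                g.add_edge(pref, (name, t))
    return list(nx.lexicographical_topological_sort(g, key=lambda n: (n[1], n[0])))


def joint_probability(
    dbn: DynamicBayesianNetwork, assignment: dict[tuple[str, int], str]
) -> float:
    """Probability of one full trajectory: the literal product of CPT entries.

    ``assignment`` maps (variable name, slice index) to a state label and
    must cover every variable in every slice 0..T, where T is the largest
    slice index present.  This is the brute-force oracle for the unrolled
    joint; it never marginalizes.
    """
    if not assignment:
        raise ValueError("empty assignment")
    n_slices = max(t for _, t in assignment) + 1
    for t in range(n_slices):
        for name in dbn.variables:
            if (name, t) not in assignment:
                raise ValueError(f"assignment missing {(name, t)!r}")
    p = 1.0
    for t in range(n_slices):
        cpts = dbn.prior.cpts if t == 0 else dbn.transition.cpts
        for name, cpt in cpts.items():
            child = dbn.variable(name)
            idx = child.state_index(assignment[(name, t)])
            key = tuple(assignment[(ref.var, t + ref.offset)] for ref in cpt.parents)
            p *= cpt.probability(idx, key)
    return p
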