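"""Exact inference on the unrolled two-slice DBN.

The network is unrolled over slices 0..T into one factor per
variable-slice (its CPT, with parents resolved to absolute slice indices).
Queries are answered by variable elimination with a min-fill ordering and a
deterministic (name, slice) tie-break, after restricting to the ancestral
closure of the query and evidence nodes (barren-node pruning — descendants
of the query carrying no evidence integrate to one and are dropped).

Two kinds of conditioning are supported and composable:

- *evidence*: hard observation of a variable's state at a slice
  (posterior conditioning);
- *interventions*: replacement of a node's CPT at selected slices before
  any message passing — "a priori knowledge" surgery, used e.g. to model
  patient groups whose transition behaviour differs from the average.

:func:`brute_force_marginals` answers the same queries by summing the
unrolled joint over the full assignment space; it exists as an independent
oracle for tests and is only feasible for small networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ConditionalProbabilityTable,
    DynamicBayesianNetwork,
    ValidationError,
    unrolled_parents,
    validate_network,
)

__all__ = [
    "Evidence",
    "EvidenceSet",
    "Intervention",
    "InterventionSet",
    "MarginalTrajectory",
    "SurvivalCurve",
    "InconsistentEvidenceError",
    "IntractableError",
    "predict_marginals",
    "brute_force_marginals",
    "survival_curve",
]

MAX_FACTOR_SIZE = 5_000_000
MAX_BRUTE_FORCE_SIZE = 10_000_000

Node = tuple[str, int]  # (variable name, slice index)


class InconsistentEvidenceError(ValueError):
    """The supplied evidence has probability zero under the (intervened) model."""


class IntractableError(RuntimeError):
    """An intermediate factor would exceed the configured state-space cap."""


@dataclass(frozen=True)
class Evidence:
    var: str
    slice: int
    state: str


class EvidenceSet:
    """Per-slice hard assignments; at most one entry per (variable, slice)."""

    def __init__(self, entries: list[Evidence] | None = None):
        self._by_node: dict[Node, str] = {}
        for e in entries or []:
            self.add(e.var, e.slice, e.state)

    def add(self, var: str, slice: int, state: str) -> "EvidenceSet":
        if slice < 0:
            raise ValueError(f"evidence slice must be >= 0, got {slice}")
        node = (var, slice)
        if node in self._by_node and self._by_node[node] != state:
            raise ValueError(f"conflicting evidence for {var!r} at slice {slice}")
        self._by_node[node] = state
        return self

    def items(self):
        return self._by_node.items()

    def nodes(self) -> set[Node]:
        return set(self._by_node)

    def __len__(self) -> int:
        return len(self._by_node)

    def __bool__(self) -> bool:
        return bool(self._by_node)


@dataclass
class Intervention:
    """Replace ``var``'s CPT at the given slices before inference.

    ``slices`` is "all" or an explicit list of slice indices.  ``cpt`` is
    the replacement for transition slices (t >= 1) and must declare the same
    parent set as the variable's transition CPT; ``prior_cpt`` (same
    contract against the prior model) is used when slice 0 is targeted.
    """

    var: str
    slices: str | list[int]
    cpt: ConditionalProbabilityTable | None = None
    prior_cpt: ConditionalProbabilityTable | None = None

    def applies_to(self, t: int) -> bool:
        if self.slices == "all":
            return True
        return t in self.slices


class InterventionSet:
    def __init__(self, entries: list[Intervention] | None = None):
        self.entries: list[Intervention] = list(entries or [])

    def add(self, intervention: Intervention) -> "InterventionSet":
        self.entries.append(intervention)
        return self

    def __len__(self) -> int:
        return len(self.entries)

    def __bool__(self) -> bool:
        return bool(self.entries)

    def cpt_for(self, dbn: DynamicBayesianNetwork, var: str, t: int):
        """The CPT in force for ``var`` at slice ``t`` after surgery."""
        base = dbn.prior.cpts[var] if t == 0 else dbn.transition.cpts[var]
        for iv in self.entries:
            if iv.var != var or not iv.applies_to(t):
                continue
            replacement = iv.prior_cpt if t == 0 else iv.cpt
            if replacement is None:
                continue
            _check_replacement(base, replacement)
            base = replacement
        return base

    def validate_against(self, dbn: DynamicBayesianNetwork) -> None:
        for iv in self.entries:
            if iv.var not in dbn.variables:
                raise KeyError(f"intervention targets unknown variable {iv.var!r}")
            if iv.cpt is None and iv.prior_cpt is None:
                raise ValueError(f"intervention on {iv.var!r} carries no replacement CPT")


def _check_replacement(base, replacement) -> None:
    if replacement.child != base.child:
        raise ValueError(
            f"replacement CPT child {replacement.child!r} != target {base.child!r}"
        )
    if tuple(replacement.parents) != tuple(base.parents):
        raise ValueError(
            f"replacement CPT for {base.child!r} must keep the declared parent set "
            f"{[str(p) for p in base.parents]}"
        )
    if set(replacement.table) != set(base.table):
        raise ValueError(f"replacement CPT for {base.child!r} must cover the same rows")
    for key, row in replacement.table.items():
        if len(row) != len(base.table[key]):
            raise ValueError(f"replacement row {key!r} has wrong length")
        if any(p < 0 for p in row) or abs(sum(row) - 1.0) > 1e-9:
            raise ValueError(f"replacement row {key!r} is not a distribution")


def force_state_cpt(
    cpt: ConditionalProbabilityTable, state_index: int
) -> ConditionalProbabilityTable:
    """A copy of ``cpt`` whose every row puts all mass on ``state_index``."""
    n = len(next(iter(cpt.table.values())))
    row = tuple(1.0 if i == state_index else 0.0 for i in range(n))
    return ConditionalProbabilityTable(
        child=cpt.child,
        parents=cpt.parents,
        table={k: row for k in cpt.table},
        provenance="intervention",
        structure=cpt.structure,
    )


def zero_state_cpt(
    cpt: ConditionalProbabilityTable, state_index: int
) -> ConditionalProbabilityTable:
    """A copy of ``cpt`` with ``state_index`` zeroed in every row.

    Remaining mass is renormalized; a row that had all its mass on the
    zeroed state distributes it uniformly over the other states (for a
    binary node: everything moves to the other state).
    """
    table = {}
    for key, row in cpt.table.items():
        rest = [p if i != state_index else 0.0 for i, p in enumerate(row)]
        total = sum(rest)
        if total > 0:
            table[key] = tuple(p / total for p in rest)
        else:
            others = len(row) - 1
            table[key] = tuple(
                0.0 if i == state_index else 1.0 / others for i in range(len(row))
            )
    return ConditionalProbabilityTable(
        child=cpt.child,
        parents=cpt.parents,
        table=table,
        provenance="intervention",
        structure=cpt.structure,
    )


@dataclass
class MarginalTrajectory:
    """Per-slice posterior distributions for one query variable."""

    variable: str
    states: tuple[str, ...]
    probabilities: np.ndarray  # shape (T+1, n_states)

    def at(self, t: int) -> dict[str, float]:
        return dict(zip(self.states, self.probabilities[t]))

    def series(self, state: str) -> np.ndarray:
        return self.probabilities[:, self.states.index(state)]


@dataclass
class SurvivalCurve:
    """Proportion alive on a time grid in months."""

    months: np.ndarray
    survival: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.months = np.asarray(self.months, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.months.shape != self.survival.shape:
            raise ValueError("months and survival must have equal length")
        if len(self.months) and np.any(np.diff(self.months) <= 0):
            raise ValueError("time points must be strictly increasing")
        if len(self.survival) and (self.survival.min() < -1e-12 or self.survival.max() > 1 + 1e-12):
            raise ValueError("survival values must lie in [0, 1]")


# ---------------------------------------------------------------- factors


@dataclass
class _Factor:
    vars: tuple[Node, ...]
    values: np.ndarray  # shape = cardinalities of vars, in order


def _cpt_factor(dbn: DynamicBayesianNetwork, cpt, t: int) -> _Factor:
    child = dbn.variable(cpt.child)
    parent_nodes = tuple((ref.var, t + ref.offset) for ref in cpt.parents)
    parent_vars = [dbn.variable(ref.var) for ref in cpt.parents]
    shape = tuple(v.cardinality for v in parent_vars) + (child.cardinality,)
    arr = np.empty(shape)
    for key, row in cpt.table.items():
        idx = tuple(v.state_index(s) for v, s in zip(parent_vars, key))
        arr[idx] = row
    return _Factor(parent_nodes + ((cpt.child, t),), arr)


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    union = list(a.vars) + [v for v in b.vars if v not in a.vars]
    size = 1
    dims_a = {v: a.values.shape[i] for i, v in enumerate(a.vars)}
    dims_b = {v: b.values.shape[i] for i, v in enumerate(b.vars)}
    for v in union:
        size *= dims_a.get(v, dims_b.get(v))
    if size > MAX_FACTOR_SIZE:
        raise IntractableError(
            f"intermediate factor over {len(union)} variables would hold {size} entries "
            f"(cap {MAX_FACTOR_SIZE}); exact inference refused rather than approximated"
        )

    def _expand(f: _Factor) -> np.ndarray:
        src = list(f.vars)
        arr = f.values
        # append missing axes then order to `union`
        for v in union:
            if v not in src:
                arr = arr[..., None]
                src.append(v)
        return np.moveaxis(arr, [src.index(v) for v in union], range(len(union)))

    return _Factor(tuple(union), _expand(a) * _expand(b))


def _marginalize(f: _Factor, node: Node) -> _Factor:
    ax = f.vars.index(node)
    return _Factor(f.vars[:ax] + f.vars[ax + 1 :], f.values.sum(axis=ax))


def _reduce(f: _Factor, node: Node, state_index: int) -> _Factor:
    ax = f.vars.index(node)
    return _Factor(f.vars[:ax] + f.vars[ax + 1 :], np.take(f.values, state_index, axis=ax))


def _min_fill_order(factors: list[_Factor], keep: set[Node]) -> list[Node]:
    """Elimination order minimizing fill-in, ties broken on (name, slice)."""
    neighbors: dict[Node, set[Node]] = {}
    for f in factors:
        for v in f.vars:
            neighbors.setdefault(v, set()).update(u for u in f.vars if u != v)
    to_eliminate = set(neighbors) - keep
    order: list[Node] = []
    while to_eliminate:
        best = None
        best_key = None
        for v in to_eliminate:
            nb = neighbors[v] - {v}
            fill = 0
            nb_list = list(nb)
            for i, x in enumerate(nb_list):
                for y in nb_list[i + 1 :]:
                    if y not in neighbors[x]:
                        fill += 1
            key = (fill, v[0], v[1])
            if best_key is None or key < best_key:
                best, best_key = v, key
        order.append(best)
        nb = neighbors[best] - {best}
        for x in nb:
            neighbors[x].update(nb - {x})
            neighbors[x].discard(best)
        del neighbors[best]
        to_eliminate.discard(best)
    return order


def _eliminate(factors: list[_Factor], keep: set[Node]) -> _Factor:
    factors = list(factors)
    for node in _min_fill_order(factors, keep):
        bucket = [f for f in factors if node in f.vars]
        factors = [f for f in factors if node not in f.vars]
        if not bucket:
            continue
        prod = bucket[0]
        for f in bucket[1:]:
            prod = _multiply(prod, f)
        factors.append(_marginalize(prod, node))
    result = _Factor((), np.array(1.0))
    for f in factors:
        result = _multiply(result, f)
    # order axes canonically by (slice, name) for reproducibility
    if result.vars:
        want = tuple(sorted(result.vars, key=lambda n: (n[1], n[0])))
        perm = [result.vars.index(v) for v in want]
        result = _Factor(want, np.transpose(result.values, perm))
    return result


# ---------------------------------------------------------------- queries


def _prepare(dbn, T, evidence, interventions):
    report = validate_network(dbn)
    if not report:
        raise ValidationError(str(report))
    if T < 0:
        raise ValueError(f"T must be >= 0, got {T}")
    evidence = evidence if evidence is not None else EvidenceSet()
    interventions = interventions if interventions is not None else InterventionSet()
    interventions.validate_against(dbn)
    for (var, t), state in evidence.items():
        if t > T:
            raise ValueError(f"evidence on {var!r} at slice {t} lies beyond horizon T={T}")
        dbn.variable(var).state_index(state)  # validates both names
    return evidence, interventions


def _ancestral_closure(dbn, T, targets: set[Node]) -> set[Node]:
    closure: set[Node] = set()
    stack = list(targets)
    while stack:
        node = stack.pop()
        if node in closure:
            continue
        closure.add(node)
        name, t = node
        stack.extend(unrolled_parents(dbn, name, t))
    return closure


def _posterior_factor(dbn, T, target: Node, evidence, interventions) -> np.ndarray:
    relevant = _ancestral_closure(dbn, T, {target} | evidence.nodes())
    factors = []
    for name, t in relevant:
        cpt = interventions.cpt_for(dbn, name, t)
        factors.append(_cpt_factor(dbn, cpt, t))
    for (var, t), state in evidence.items():
        idx = dbn.variable(var).state_index(state)
        factors = [
            _reduce(f, (var, t), idx) if (var, t) in f.vars else f for f in factors
        ]
    result = _eliminate(factors, keep={target} if target not in evidence.nodes() else set())
    if target in evidence.nodes():
        # conditioning on the query itself: degenerate posterior
        total = float(result.values)
        if total <= 0.0:
            raise InconsistentEvidenceError(
                "evidence has probability zero under the model"
            )
        out = np.zeros(dbn.variable(target[0]).cardinality)
        out[dbn.variable(target[0]).state_index(dict(evidence.items())[target])] = 1.0
        return out
    vec = np.asarray(result.values, dtype=float).reshape(-1)
    total = vec.sum()
    if total <= 0.0:
        raise InconsistentEvidenceError("evidence has probability zero under the model")
    return vec / total


def predict_marginals(
    dbn: DynamicBayesianNetwork,
    T: int,
    query: list[str] | str,
    evidence: EvidenceSet | None = None,
    interventions: InterventionSet | None = None,
) -> dict[str, MarginalTrajectory]:
    """Exact posterior marginals P(X^(t) | evidence, intervened CPTs), t = 0..T.

    Interventions replace CPTs before elimination; evidence conditions the
    resulting joint.  Raises :class:`InconsistentEvidenceError` if the
    evidence has probability zero and :class:`IntractableError` if an
    intermediate factor would exceed the state-space cap.
    """
    query_vars = [query] if isinstance(query, str) else list(query)
    evidence, interventions = _prepare(dbn, T, evidence, interventions)
    out: dict[str, MarginalTrajectory] = {}
    for qv in query_vars:
        var = dbn.variable(qv)
        probs = np.empty((T + 1, var.cardinality))
        for t in range(T + 1):
            probs[t] = _posterior_factor(dbn, T, (qv, t), evidence, interventions)
        out[qv] = MarginalTrajectory(qv, var.states, probs)
    return out


def brute_force_marginals(
    dbn: DynamicBayesianNetwork,
    T: int,
    query: list[str] | str,
    evidence: EvidenceSet | None = None,
    interventions: InterventionSet | None = None,
    *,
    max_size: int = MAX_BRUTE_FORCE_SIZE,
) -> dict[str, MarginalTrajectory]:
    """Marginals by direct summation of the unrolled joint over all assignments.

    Builds the full joint table (product of every CPT entry, broadcast over
    the complete assignment grid), zeroes assignments contradicting the
    evidence, and sums out everything but the query.  Independent of the
    elimination engine; refuses state spaces above ``max_size``.
    """
    query_vars = [query] if isinstance(query, str) else list(query)
    evidence, interventions = _prepare(dbn, T, evidence, interventions)

    nodes: list[Node] = [(name, t) for t in range(T + 1) for name in dbn.variables]
    cards = [dbn.variable(name).cardinality for name, _ in nodes]
    size = 1
    for c in cards:
        size *= c
    if size > max_size:
        raise IntractableError(f"assignment space of {size} exceeds cap {max_size}")
    axis = {node: i for i, node in enumerate(nodes)}

    joint = np.ones(cards)
    for name, t in nodes:
        cpt = interventions.cpt_for(dbn, name, t)
        f = _cpt_factor(dbn, cpt, t)
        shape = [1] * len(nodes)
        src_axes = [axis[v] for v in f.vars]
        for v, dim in zip(f.vars, f.values.shape):
            shape[axis[v]] = dim
        # permute factor axes into global order, then broadcast
        order = np.argsort(src_axes)
        joint = joint * np.transpose(f.values, order).reshape(shape)

    for (var, t), state in evidence.items():
        idx = dbn.variable(var).state_index(state)
        card = dbn.variable(var).cardinality
        mask_shape = [1] * len(nodes)
        mask_shape[axis[(var, t)]] = card
        joint = joint * (np.arange(card) == idx).astype(float).reshape(mask_shape)

    total = joint.sum()
    if total <= 0.0:
        raise InconsistentEvidenceError("evidence has probability zero under the model")

    out: dict[str, MarginalTrajectory] = {}
    for qv in query_vars:
        var = dbn.variable(qv)
        probs = np.empty((T + 1, var.cardinality))
        for t in range(T + 1):
            keep_ax = axis[(qv, t)]
            marg = joint.sum(axis=tuple(i for i in range(len(nodes)) if i != keep_ax))
            probs[t] = marg / total
        out[qv] = MarginalTrajectory(qv, var.states, probs)
    return out


def survival_curve(
    dbn: DynamicBayesianNetwork,
    T: int,
    evidence: EvidenceSet | None = None,
    interventions: InterventionSet | None = None,
    label: str = "",
) -> SurvivalCurve:
    """P(Survival = yes) at t = 0..T on the network's slice grid, in months.

    The network must designate a survival variable with a "yes" state
    (``survival_variable`` in the document).
    """
    sv = dbn.survival_variable
    if sv is None or sv not in dbn.variables:
        raise KeyError(f"network {dbn.name!r} declares no survival variable")
    yes = next((s for s in dbn.variable(sv).states if s.lower() == "yes"), None)
    if yes is None:
        raise KeyError(f"survival variable {sv!r} has no 'yes' state")
    traj = predict_marginals(dbn, T, sv, evidence, interventions)[sv]
    months = np.arange(T + 1) * dbn.slice_duration_months
    return SurvivalCurve(months, traj.series(yes), label or dbn.name)
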