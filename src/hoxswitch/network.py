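"""Qualitative-network engine.

A qualitative network (QN) is a discrete dynamical system: each variable
holds an integer level in a bounded range (by convention 0 = inactive,
1 = intermediate/healthy, 2 = overactive) and owns a target function of its
regulators.  Under the synchronous unit-step semantics used here, at every
tick each unclamped variable moves one level toward its evaluated target,
all variables updating simultaneously from the same input state.  Clamped
variables (mutations) are frozen at their clamp level.

Because the state space is finite and updates are deterministic, every
trajectory ends in an attractor: a fixpoint or a cycle.  Fixpoints can also
be enumerated globally, either by brute force over the state space or by a
constraint-propagation solver that prunes per-variable domains and splits
(branch and prune); both are guaranteed to return the same set.

Numerical conventions, fixed because they change attractors:

* fractional targets (``avg`` can be fractional) are rounded half-up,
  ``floor(x + 1/2)``;
* the default target function (when a variable has none) is
  ``avg(activator levels) - avg(inhibitor levels)``, an empty set
  contributing 0;
* targets are clipped to the variable's range after rounding;
* a cycle is stored starting from its lexicographically smallest state, so
  attractor equality is well defined.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Dict, List, Mapping, Optional, Set, Tuple

from .expr import TargetExpression

ACTIVATOR = "activator"
INHIBITOR = "inhibitor"

DEFAULT_ENUMERATION_BOUND = 10_000_000


class ModelError(ValueError):
    """Raised when a model or state violates a structural invariant."""


@dataclass(frozen=True)
class QNVariable:
    id: str
    name: str = ""
    range_min: int = 0
    range_max: int = 2
    target: Optional[TargetExpression] = None
    clamp: Optional[int] = None

    def __post_init__(self):
        if self.range_min > self.range_max:
            raise ModelError(
                f"variable {self.id!r}: range_min {self.range_min} > range_max {self.range_max}"
            )
        if self.clamp is not None and not (self.range_min <= self.clamp <= self.range_max):
            raise ModelError(
                f"variable {self.id!r}: clamp {self.clamp} outside range "
                f"[{self.range_min}, {self.range_max}]"
            )

    @property
    def levels(self) -> range:
        return range(self.range_min, self.range_max + 1)


@dataclass(frozen=True)
class QNEdge:
    source: str
    target: str
    sign: str  # ACTIVATOR or INHIBITOR

    def __post_init__(self):
        if self.sign not in (ACTIVATOR, INHIBITOR):
            raise ModelError(
                f"edge {self.source}->{self.target}: sign must be "
                f"{ACTIVATOR!r} or {INHIBITOR!r}, got {self.sign!r}"
            )


class NetworkState(Mapping):
    """An immutable assignment of levels to all model variables.

    Hashable and ordered (lexicographically in model variable order) so
    attractors can be canonicalised and stored in sets.
    """

    __slots__ = ("_ids", "_levels")

    def __init__(self, ids: Tuple[str, ...], levels: Tuple[int, ...]):
        self._ids = ids
        self._levels = levels

    @property
    def levels(self) -> Tuple[int, ...]:
        return self._levels

    def __getitem__(self, key: str) -> int:
        try:
            return self._levels[self._ids.index(key)]
        except ValueError:
            raise KeyError(key) from None

    def __iter__(self):
        return iter(self._ids)

    def __len__(self):
        return len(self._ids)

    def as_dict(self) -> Dict[str, int]:
        return dict(zip(self._ids, self._levels))

    def __eq__(self, other):
        if not isinstance(other, NetworkState):
            return NotImplemented
        return self._ids == other._ids and self._levels == other._levels

    def __hash__(self):
        return hash((self._ids, self._levels))

    def __lt__(self, other: "NetworkState"):
        return self._levels < other._levels

    def __repr__(self):
        inner = ", ".join(f"{i}={l}" for i, l in zip(self._ids, self._levels))
        return f"NetworkState({inner})"


@dataclass(frozen=True)
class Attractor:
    """A fixpoint (one state) or a cycle of states under synchronous update."""

    kind: str  # "fixpoint" or "cycle"
    states: Tuple[NetworkState, ...]
    basin_seed: Optional[NetworkState] = field(default=None, compare=False)

    @property
    def is_fixpoint(self) -> bool:
        return self.kind == "fixpoint"

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def fixpoint(self) -> NetworkState:
        if not self.is_fixpoint:
            raise ValueError(f"attractor is a cycle of period {self.period}, not a fixpoint")
        return self.states[0]


@dataclass(frozen=True)
class QNModel:
    name: str
    variables: Tuple[QNVariable, ...]
    edges: Tuple[QNEdge, ...]

    def __post_init__(self):
        ids = [v.id for v in self.variables]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ModelError(f"duplicate variable ids: {sorted(dupes)}")
        idset = set(ids)
        for e in self.edges:
            if e.source not in idset:
                raise ModelError(f"edge {e.source}->{e.target}: unknown source {e.source!r}")
            if e.target not in idset:
                raise ModelError(f"edge {e.source}->{e.target}: unknown target {e.target!r}")
        for v in self.variables:
            if v.target is None:
                continue
            missing = v.target.references() - idset
            if missing:
                raise ModelError(
                    f"variable {v.id!r}: target references unknown variables {sorted(missing)}"
                )
            for ref, signs in v.target.polarities().items():
                for s in signs:
                    want = ACTIVATOR if s > 0 else INHIBITOR
                    if not any(
                        e.source == ref and e.target == v.id and e.sign == want
                        for e in self.edges
                    ):
                        raise ModelError(
                            f"variable {v.id!r}: target references {ref!r} with "
                            f"{'positive' if s > 0 else 'negative'} polarity but no "
                            f"{want} edge {ref}->{v.id} exists"
                        )

    # -- lookups ---------------------------------------------------------

    @property
    def variable_ids(self) -> Tuple[str, ...]:
        return tuple(v.id for v in self.variables)

    def variable(self, vid: str) -> QNVariable:
        for v in self.variables:
            if v.id == vid:
                return v
        raise ModelError(f"unknown variable id {vid!r}")

    def has_variable(self, vid: str) -> bool:
        return any(v.id == vid for v in self.variables)

    def regulators(self, vid: str, sign: str) -> Tuple[str, ...]:
        return tuple(e.source for e in self.edges if e.target == vid and e.sign == sign)

    def has_edge(self, source: str, target: str, sign: Optional[str] = None) -> bool:
        return any(
            e.source == source and e.target == target and (sign is None or e.sign == sign)
            for e in self.edges
        )

    def state_space_size(self) -> int:
        size = 1
        for v in self.variables:
            size *= 1 if v.clamp is not None else len(v.levels)
        return size

    # -- state construction ---------------------------------------------

    def state(self, levels: Mapping[str, int]) -> NetworkState:
        """Build and validate a state from a mapping of all variable levels."""
        vals = []
        for v in self.variables:
            if v.id not in levels:
                raise ModelError(f"state missing variable {v.id!r}")
            lvl = int(levels[v.id])
            if v.clamp is not None and lvl != v.clamp:
                raise ModelError(
                    f"state sets clamped variable {v.id!r} to {lvl}, clamp is {v.clamp}"
                )
            if not (v.range_min <= lvl <= v.range_max):
                raise ModelError(
                    f"state level {lvl} for {v.id!r} outside range "
                    f"[{v.range_min}, {v.range_max}]"
                )
            vals.append(lvl)
        extra = set(levels) - set(self.variable_ids)
        if extra:
            raise ModelError(f"state names unknown variables {sorted(extra)}")
        return NetworkState(self.variable_ids, tuple(vals))

    def uniform_state(self, level: int) -> NetworkState:
        """All variables at `level` (clamped variables at their clamps)."""
        return self.state(
            {v.id: (v.clamp if v.clamp is not None else level) for v in self.variables}
        )

    # -- derived models --------------------------------------------------

    def replace_variable(self, vid: str, **changes) -> "QNModel":
        self.variable(vid)  # raises for unknown id
        new_vars = tuple(
            replace(v, **changes) if v.id == vid else v for v in self.variables
        )
        return QNModel(name=self.name, variables=new_vars, edges=self.edges)


def _round_half_up(x: Fraction) -> int:
    return math.floor(x + Fraction(1, 2))


def _target_value(model: QNModel, var: QNVariable, lookup: Callable[[str], int]) -> int:
    """Evaluate var's target on arbitrary levels, rounded and clipped."""
    if var.clamp is not None:
        return var.clamp
    if var.target is not None:
        raw = var.target.evaluate(lookup)
    else:
        acts = model.regulators(var.id, ACTIVATOR)
        inhs = model.regulators(var.id, INHIBITOR)
        a = sum(Fraction(lookup(s)) for s in acts) / len(acts) if acts else Fraction(0)
        i = sum(Fraction(lookup(s)) for s in inhs) / len(inhs) if inhs else Fraction(0)
        raw = a - i
    return min(max(_round_half_up(raw), var.range_min), var.range_max)


def evaluate_target(model: QNModel, state: NetworkState, vid: str) -> int:
    """The level variable `vid` is driven toward in `state`.

    Returns the clamp for clamped variables; otherwise the target function
    (or the default avg(activators) - avg(inhibitors)) evaluated on the
    state, rounded half-up and clipped to the variable's range.
    """
    return _target_value(model, model.variable(vid), state.__getitem__)


def step_synchronous(model: QNModel, state: NetworkState) -> NetworkState:
    """One synchronous unit step: every variable moves one level toward its
    target, all reading the same input state."""
    new_levels = []
    for v in model.variables:
        cur = state[v.id]
        tgt = _target_value(model, v, state.__getitem__)
        new_levels.append(cur + (tgt > cur) - (tgt < cur))
    return NetworkState(model.variable_ids, tuple(new_levels))


def _canonical_cycle(states: List[NetworkState]) -> Tuple[NetworkState, ...]:
    k = min(range(len(states)), key=lambda i: states[i].levels)
    return tuple(states[k:] + states[:k])


def simulate_to_attractor(
    model: QNModel, initial: NetworkState, max_steps: Optional[int] = None
) -> Attractor:
    """Iterate synchronous steps from `initial` until a state repeats.

    The walk is deterministic, and the state space finite, so with
    ``max_steps`` of at least the state-space size it always terminates.
    When ``max_steps`` is None it defaults to that bound plus one.
    """
    if max_steps is None:
        max_steps = model.state_space_size() + 1
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    seen: Dict[NetworkState, int] = {}
    trail: List[NetworkState] = []
    state = model.state(initial.as_dict())  # validates against this model
    for _ in range(max_steps + 1):
        if state in seen:
            cycle = trail[seen[state] :]
            return Attractor(
                kind="fixpoint" if len(cycle) == 1 else "cycle",
                states=_canonical_cycle(cycle),
                basin_seed=initial,
            )
        seen[state] = len(trail)
        trail.append(state)
        state = step_synchronous(model, state)
    raise RuntimeError(
        f"no revisit within max_steps={max_steps}; the state space has "
        f"{model.state_space_size()} states, so a bound of at least that size terminates"
    )


def is_fixpoint(model: QNModel, state: NetworkState) -> bool:
    return all(
        _target_value(model, v, state.__getitem__) == state[v.id] for v in model.variables
    )


def _brute_force_fixpoints(model: QNModel) -> Set[NetworkState]:
    free = [v for v in model.variables if v.clamp is None]
    out: Set[NetworkState] = set()
    for combo in itertools.product(*(v.levels for v in free)):
        levels = {v.id: v.clamp for v in model.variables if v.clamp is not None}
        levels.update(zip((v.id for v in free), combo))
        lookup = levels.__getitem__
        if all(_target_value(model, v, lookup) == levels[v.id] for v in model.variables):
            out.add(NetworkState(model.variable_ids, tuple(levels[i] for i in model.variable_ids)))
    return out


def _target_support(model: QNModel, var: QNVariable) -> Tuple[str, ...]:
    """Variables the target of `var` actually reads."""
    if var.clamp is not None:
        return ()
    if var.target is not None:
        return tuple(sorted(var.target.references()))
    return tuple(sorted(set(model.regulators(var.id, ACTIVATOR))
                        | set(model.regulators(var.id, INHIBITOR))))


def _propagation_fixpoints(model: QNModel) -> Set[NetworkState]:
    """Iterated per-variable domain pruning with branch-and-prune splitting.

    A level l stays in var v's domain only if some assignment of v's
    regulators within their current domains makes v's target equal l (with
    v itself held at l when self-referencing).  Returns exactly the brute
    force fixpoint set.
    """
    supports = {v.id: _target_support(model, v) for v in model.variables}
    out: Set[NetworkState] = set()

    def feasible(v: QNVariable, lvl: int, domains: Dict[str, Set[int]]) -> bool:
        others = [r for r in supports[v.id] if r != v.id]
        for combo in itertools.product(*(sorted(domains[r]) for r in others)):
            levels = dict(zip(others, combo))
            levels[v.id] = lvl

            def lookup(name, _levels=levels):
                return _levels[name]

            if _target_value(model, v, lookup) == lvl:
                return True
        return False

    def prune(domains: Dict[str, Set[int]]) -> bool:
        """Shrink domains to a local fixpoint; False if any becomes empty."""
        changed = True
        while changed:
            changed = False
            for v in model.variables:
                if v.clamp is not None:
                    continue
                dom = domains[v.id]
                keep = {l for l in dom if feasible(v, l, domains)}
                if keep != dom:
                    domains[v.id] = keep
                    changed = True
                if not keep:
                    return False
        return True

    def solve(domains: Dict[str, Set[int]]) -> None:
        if not prune(domains):
            return
        open_vars = [v for v in model.variables if len(domains[v.id]) > 1]
        if not open_vars:
            state = NetworkState(
                model.variable_ids,
                tuple(next(iter(domains[i])) for i in model.variable_ids),
            )
            if is_fixpoint(model, state):
                out.add(state)
            return
        split = min(open_vars, key=lambda v: len(domains[v.id]))
        for lvl in sorted(domains[split.id]):
            sub = {k: set(d) for k, d in domains.items()}
            sub[split.id] = {lvl}
            solve(sub)

    domains = {
        v.id: ({v.clamp} if v.clamp is not None else set(v.levels)) for v in model.variables
    }
    solve(domains)
    return out


def enumerate_fixpoints(
    model: QNModel,
    bound: int = DEFAULT_ENUMERATION_BOUND,
    propagate: bool = False,
) -> Set[NetworkState]:
    """All states s with target(s, v) == s(v) for every variable.

    Brute force enumerates the full state space and requires it to be at
    most `bound`; `propagate=True` switches to the constraint-propagation
    solver, which returns the identical set without the bound.
    """
    if propagate:
        return _propagation_fixpoints(model)
    size = model.state_space_size()
    if size > bound:
        raise ModelError(
            f"state space has {size} states, over the enumeration bound {bound}; "
            "raise the bound or enable constraint propagation"
        )
    return _brute_force_fixpoints(model)
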