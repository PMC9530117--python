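"""Mutations, mutation-order experiments and phenotype-specification checks.

A mutation is represented as a clamp: loss of function pins a variable at
its minimum level, constitutive activation at its maximum.  Disease
attractors are defined by sequential-acquisition reachability — the model
starts at the wild-type state, stabilises, acquires the first mutation,
re-stabilises from where it was, and so on — mirroring how a clone accrues
mutations over time.  This is what makes mutation *order* matter: a
genotype's endpoint depends on the attractor inherited from the previous
stage, and a positive feedback loop downstream of both mutations can store
that history.

`bifurcation_analysis` runs every order of a mutation set and collects the
distinct final attractors; more than one distinct attractor is a
bifurcation.  `check_specification` compares the model's five canonical
genotype columns (wild type, each single mutant, and both orders of the
double mutant) against a table of expected phenotype levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .network import (
    Attractor,
    ModelError,
    NetworkState,
    QNModel,
    simulate_to_attractor,
)

LOSS = "loss"
ACTIVATION = "constitutive_activation"

#: Genotype columns of the specification table, in printed order.
SPEC_COLUMNS = ("WT", "TET2", "JAK2", "TET2_first", "JAK2_first")


@dataclass(frozen=True)
class Mutation:
    variable: str
    kind: str  # LOSS or ACTIVATION

    def __post_init__(self):
        if self.kind not in (LOSS, ACTIVATION):
            raise ValueError(f"mutation kind must be {LOSS!r} or {ACTIVATION!r}, got {self.kind!r}")

    def level(self, model: QNModel) -> int:
        var = model.variable(self.variable)
        return var.range_min if self.kind == LOSS else var.range_max


@dataclass(frozen=True)
class Genotype:
    """An ordered list of mutations; order encodes acquisition history."""

    mutations: Tuple[Mutation, ...]

    def __post_init__(self):
        seen = [m.variable for m in self.mutations]
        dupes = {v for v in seen if seen.count(v) > 1}
        if dupes:
            raise ValueError(f"variables mutated more than once: {sorted(dupes)}")

    def __len__(self):
        return len(self.mutations)


@dataclass(frozen=True)
class OrderExperimentResult:
    """Trajectory of (genotype so far, attractor) pairs, wild type included."""

    stages: Tuple[Tuple[Genotype, Attractor], ...]
    unstable: bool  # True if any intermediate attractor was a cycle

    @property
    def final_attractor(self) -> Attractor:
        return self.stages[-1][1]

    @property
    def trajectory(self) -> Tuple[Tuple[Genotype, Attractor], ...]:
        return self.stages


def apply_mutation(model: QNModel, mutation: Mutation, allow_reclamp: bool = False) -> QNModel:
    """A copy of the model with the mutated variable clamped; the original
    model is left untouched."""
    var = model.variable(mutation.variable)
    if var.clamp is not None and not allow_reclamp:
        raise ModelError(
            f"variable {mutation.variable!r} is already clamped at {var.clamp}; "
            "applying the same mutation twice is not allowed"
        )
    return model.replace_variable(mutation.variable, clamp=mutation.level(model))


def order_experiment(
    model: QNModel,
    wildtype_init: NetworkState,
    mutations: Sequence[Mutation],
    max_steps: Optional[int] = None,
) -> OrderExperimentResult:
    """Sequentially acquire `mutations` in the given order.

    Each stage clamps the next mutation and re-stabilises from the previous
    stage's fixpoint.  If an intermediate attractor is a cycle the run
    proceeds from the cycle's canonical (lexicographically smallest) state
    and the result is flagged unstable: the model is not stabilising the
    way a fixpoint specification table assumes.
    """
    Genotype(tuple(mutations))  # validates no-double-mutation up front
    current = model
    attractor = simulate_to_attractor(current, wildtype_init, max_steps)
    stages: List[Tuple[Genotype, Attractor]] = [(Genotype(()), attractor)]
    unstable = not attractor.is_fixpoint
    acquired: List[Mutation] = []
    for mut in mutations:
        current = apply_mutation(current, mut)
        seed_levels = attractor.states[0].as_dict()
        seed_levels[mut.variable] = mut.level(current)
        attractor = simulate_to_attractor(current, current.state(seed_levels), max_steps)
        unstable = unstable or not attractor.is_fixpoint
        acquired.append(mut)
        stages.append((Genotype(tuple(acquired)), attractor))
    return OrderExperimentResult(stages=tuple(stages), unstable=unstable)


def bifurcation_analysis(
    model: QNModel,
    wildtype_init: NetworkState,
    mutation_set: Iterable[Mutation],
    max_steps: Optional[int] = None,
) -> Dict[Tuple[Mutation, ...], Attractor]:
    """Final attractor for every permutation of `mutation_set`.

    Returns a mapping order -> final attractor; the set of distinct values
    (attractor equality is canonical) is the bifurcation outcome.  All k!
    orders are evaluated.
    """
    muts = tuple(mutation_set)
    if len(muts) < 2:
        raise ValueError("bifurcation analysis needs at least two mutations")
    results: Dict[Tuple[Mutation, ...], Attractor] = {}
    for order in itertools.permutations(muts):
        results[order] = order_experiment(model, wildtype_init, order, max_steps).final_attractor
    return results


def distinct_final_attractors(results: Mapping[Tuple[Mutation, ...], Attractor]) -> List[Attractor]:
    out: List[Attractor] = []
    for att in results.values():
        if att not in out:
            out.append(att)
    return out


@dataclass(frozen=True)
class SpecificationTable:
    """Expected phenotype levels per canonical genotype column."""

    phenotypes: Tuple[str, ...]
    expected: Mapping[Tuple[str, str], int]  # (phenotype, column) -> level

    def __post_init__(self):
        for phen in self.phenotypes:
            for col in SPEC_COLUMNS:
                if (phen, col) not in self.expected:
                    raise ValueError(f"specification missing cell ({phen!r}, {col!r})")

    def level(self, phenotype: str, column: str) -> int:
        return self.expected[(phenotype, column)]

    @property
    def n_cells(self) -> int:
        return len(self.phenotypes) * len(SPEC_COLUMNS)


@dataclass(frozen=True)
class CellResult:
    phenotype: str
    column: str
    expected: int
    observed: Optional[int]
    passed: bool
    reason: str = ""


@dataclass(frozen=True)
class SpecificationReport:
    cells: Tuple[CellResult, ...]

    @property
    def n_pass(self) -> int:
        return sum(c.passed for c in self.cells)

    @property
    def n_total(self) -> int:
        return len(self.cells)

    @property
    def all_pass(self) -> bool:
        return self.n_pass == self.n_total

    def failures(self) -> Tuple[CellResult, ...]:
        return tuple(c for c in self.cells if not c.passed)


def column_mutations(column: str) -> Tuple[Mutation, ...]:
    """Mutation sequence defining a specification-table genotype column."""
    tet2 = Mutation("TET2", LOSS)
    jak2 = Mutation("JAK2", ACTIVATION)
    return {
        "WT": (),
        "TET2": (tet2,),
        "JAK2": (jak2,),
        "TET2_first": (tet2, jak2),
        "JAK2_first": (jak2, tet2),
    }[column]


def check_specification(
    model: QNModel,
    spec: SpecificationTable,
    wildtype_init: NetworkState,
    max_steps: Optional[int] = None,
) -> SpecificationReport:
    """Compare the model's genotype-column fixpoints with a specification.

    Each column is computed by sequential acquisition from `wildtype_init`
    (the wild-type column with no mutations).  Cells in a column whose
    attractor is a cycle fail with reason "unstable".  The model is not
    modified.  Comparison is exact integer equality.
    """
    missing = [p for p in spec.phenotypes if not model.has_variable(p)]
    if missing:
        raise ModelError(f"specification phenotypes absent from model: {missing}")
    cells: List[CellResult] = []
    for col in SPEC_COLUMNS:
        result = order_experiment(model, wildtype_init, column_mutations(col), max_steps)
        att = result.final_attractor
        for phen in spec.phenotypes:
            expected = spec.level(phen, col)
            if not att.is_fixpoint:
                cells.append(
                    CellResult(phen, col, expected, None, False, reason="unstable")
                )
                continue
            observed = att.fixpoint[phen]
            cells.append(
                CellResult(
                    phen, col, expected, observed, observed == expected,
                    reason="" if observed == expected else "level mismatch",
                )
            )
    return SpecificationReport(cells=tuple(cells))
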