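"""The JAK2/TET2/HOXA9 myeloproliferative-neoplasm network.

The packaged model captures how the order of two driver mutations —
constitutive activation of the kinase JAK2 and loss of the demethylase
TET2 — commits a haematopoietic clone to one of two stable programmes.
HOXA9 sits downstream of both drivers and activates itself; that
self-positive feedback loop lets it store which mutation came first.
JAK2 activation (via STAT5) lifts HOXA9 to a level it can then sustain on
its own, so subsequent TET2 loss no longer matters; TET2 loss first drops
HOXA9 below the self-sustaining threshold, so subsequent JAK2 activation
cannot rescue it.  The double mutant therefore bifurcates: HOXA9
overactive in the JAK2-first clone, silent in the TET2-first clone.

Around this switch, thirteen gene nodes and six phenotype read-outs (stem
cell self-renewal, CMP/GMP/MEP expansion, GMP and erythroid
differentiation) encode the haematopoietic circuitry: RUNX1 tracks the
HOXA9 memory and drives the SPI1/GATA1 pair, which in turn set MYB (the
CMP-expansion marker), KLF1 and MYC; JAK2 promotes GMP expansion by
suppressing NOTCH through MAPK and ITCH.  Every variable uses the 0/1/2
level convention: 1 healthy, 0 lowered/inactive, 2 overactive.

`ablate_self_loop` builds the three variants used to probe the role of the
HOXA9 self-loop (plain removal, basal-dependence, mutation compensation);
all three abolish the mutation-order bifurcation.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional

from .expr import TargetExpression
from .genotypes import (
    ACTIVATION,
    LOSS,
    Mutation,
    SpecificationTable,
    bifurcation_analysis,
    check_specification,
    column_mutations,
    distinct_final_attractors,
    order_experiment,
)
from .io import model_from_dict, read_specification_table
from .network import (
    ACTIVATOR,
    Attractor,
    ModelError,
    NetworkState,
    QNEdge,
    QNModel,
    QNVariable,
    simulate_to_attractor,
)

GENE_NODES = (
    "JAK2", "TET2", "STAT5", "HOXA9", "RUNX1", "SPI1", "GATA1",
    "MYB", "MYC", "KLF1", "MAPK", "ITCH", "NOTCH",
)
PHENOTYPE_NODES = (
    "SC_self_renewal", "CMP_expansion", "GMP_expansion",
    "GMP_differentiation", "Erythroid_differentiation", "MEP_expansion",
)

#: Wiring that must be present for the model to be meaningful.
REQUIRED_EDGES = (
    ("HOXA9", "HOXA9", "activator"),
    ("JAK2", "STAT5", "activator"),
    ("STAT5", "HOXA9", "activator"),
    ("TET2", "HOXA9", "activator"),
    ("JAK2", "MAPK", "activator"),
    ("MAPK", "ITCH", "activator"),
    ("ITCH", "NOTCH", "inhibitor"),
    ("NOTCH", "GMP_expansion", "inhibitor"),
    ("TET2", "KLF1", "activator"),
    ("RUNX1", "SPI1", "activator"),
    ("RUNX1", "GATA1", "activator"),
    ("SPI1", "MYB", "inhibitor"),
    ("GATA1", "MYB", "inhibitor"),
    ("SPI1", "GATA1", "inhibitor"),
    ("GATA1", "SPI1", "inhibitor"),
    ("MYB", "CMP_expansion", "activator"),
)

JAK2_ACTIVATION = Mutation("JAK2", ACTIVATION)
TET2_LOSS = Mutation("TET2", LOSS)


class AblationMode(str, enum.Enum):
    """Possible consequences of removing the HOXA9 self-activation loop."""

    REMOVE = "remove"            # JAK2 dominates: stable overexpression
    BASAL_DEPENDENT = "basal_dependent"  # self-input was essential: null activity
    COMPENSATED = "compensated"  # mutations balance out to the healthy level


#: HOXA9 replacement targets per ablation mode (JAK2 acts directly here).
_ABLATION_TARGETS = {
    AblationMode.REMOVE: "2*JAK2 + TET2 - 2",
    AblationMode.BASAL_DEPENDENT: "0",
    AblationMode.COMPENSATED: "JAK2 + TET2 - 1",
}


def _load_packaged(name: str):
    return resources.files("hoxswitch.data").joinpath(name)


def mpn_specification() -> SpecificationTable:
    """The six-phenotype, five-genotype specification table."""
    with resources.as_file(_load_packaged("table1.tsv")) as path:
        return read_specification_table(path)


def wildtype_state(model: QNModel) -> NetworkState:
    """The healthy starting state: every variable at the intermediate level 1."""
    return model.uniform_state(1)


def build_mpn_network(validate: bool = True) -> QNModel:
    """Load the packaged MPN network and (by default) self-validate it
    against the specification table from the all-ones wild-type state."""
    import json

    model = model_from_dict(json.loads(_load_packaged("mpn_model.json").read_text()))
    if validate:
        for src, dst, sign in REQUIRED_EDGES:
            if not model.has_edge(src, dst, sign):
                raise ModelError(f"packaged model missing required edge {src}-({sign})->{dst}")
        report = check_specification(model, mpn_specification(), wildtype_state(model))
        if not report.all_pass:
            lines = ", ".join(
                f"({c.phenotype},{c.column}) expected {c.expected} got {c.observed}"
                for c in report.failures()
            )
            raise ModelError(f"packaged model fails its specification: {lines}")
    return model


def build_motif() -> QNModel:
    """The minimal three-node JAK2/TET2/HOXA9 switch motif.

    HOXA9's target clip(JAK2 + TET2 + HOXA9 - 2) is the smallest function
    with the memory property: activation of JAK2 lifts HOXA9 into a
    self-sustaining high state, loss of TET2 collapses it.
    """
    t1 = TargetExpression.parse("1")
    return QNModel(
        name="JAK2/TET2/HOXA9 motif",
        variables=(
            QNVariable("JAK2", "JAK2", target=t1),
            QNVariable("TET2", "TET2", target=t1),
            QNVariable("HOXA9", "HOXA9", target=TargetExpression.parse("JAK2 + TET2 + HOXA9 - 2")),
        ),
        edges=(
            QNEdge("JAK2", "HOXA9", "activator"),
            QNEdge("TET2", "HOXA9", "activator"),
            QNEdge("HOXA9", "HOXA9", "activator"),
        ),
    )


def ablate_self_loop(model: QNModel, mode: AblationMode) -> QNModel:
    """Variant with the HOXA9 self-edge removed and its target replaced.

    The replacement encodes one hypothesis about what self-loop removal
    does: ``remove`` leaves a JAK2-dominant input (stable overexpression in
    the double mutant), ``basal_dependent`` silences HOXA9 outright, and
    ``compensated`` balances the two mutations back to the healthy level.
    """
    try:
        mode = AblationMode(mode)
    except ValueError:
        raise ValueError(f"unknown ablation mode {mode!r}") from None
    if not model.has_edge("HOXA9", "HOXA9", ACTIVATOR):
        raise ModelError("model has no HOXA9 self-activation edge to ablate")
    edges = tuple(
        e for e in model.edges if not (e.source == "HOXA9" and e.target == "HOXA9")
    )
    if mode is not AblationMode.BASAL_DEPENDENT and not model.has_edge("JAK2", "HOXA9", ACTIVATOR):
        edges = edges + (QNEdge("JAK2", "HOXA9", ACTIVATOR),)
    target = TargetExpression.parse(_ABLATION_TARGETS[mode])
    variables = tuple(
        QNVariable(v.id, v.name, v.range_min, v.range_max, target, v.clamp)
        if v.id == "HOXA9" else v
        for v in model.variables
    )
    return QNModel(name=f"{model.name} [self-loop {mode.value}]", variables=variables, edges=edges)


# ---------------------------------------------------------------------------
# Prediction checks


@dataclass(frozen=True)
class Runx1Report:
    """RUNX1 levels across genotypes and the two ruxolitinib-relevant checks.

    ``tet2_invariant``: RUNX1 is unchanged when JAK2 activation follows
    TET2 loss (the HOXA9 switch has already locked the downstream state,
    explaining why JAK2 inhibition helps TET2-first patients less).
    ``jak2_responsive_in_wt``: RUNX1 does respond to JAK2 activation on a
    TET2 wild-type background.
    """

    levels: Dict[str, Optional[int]]  # column -> RUNX1 level (None if unstable)
    tet2_invariant: Optional[bool]
    jak2_responsive_in_wt: Optional[bool]

    @property
    def conclusive(self) -> bool:
        return self.tet2_invariant is not None and self.jak2_responsive_in_wt is not None

    @property
    def all_hold(self) -> bool:
        return bool(self.tet2_invariant) and bool(self.jak2_responsive_in_wt)


def _column_fixpoints(model: QNModel, columns=None) -> Dict[str, Optional[NetworkState]]:
    init = wildtype_state(model)
    out: Dict[str, Optional[NetworkState]] = {}
    for col in columns or ("WT", "TET2", "JAK2", "TET2_first", "JAK2_first"):
        att = order_experiment(model, init, column_mutations(col)).final_attractor
        out[col] = att.fixpoint if att.is_fixpoint else None
    return out


def runx1_invariance_check(model: QNModel) -> Runx1Report:
    fps = _column_fixpoints(model)
    levels = {col: (fp["RUNX1"] if fp is not None else None) for col, fp in fps.items()}
    tet2_invariant = (
        None
        if levels["TET2"] is None or levels["TET2_first"] is None
        else levels["TET2"] == levels["TET2_first"]
    )
    jak2_responsive = (
        None
        if levels["WT"] is None or levels["JAK2"] is None
        else levels["WT"] != levels["JAK2"]
    )
    return Runx1Report(
        levels=levels, tet2_invariant=tet2_invariant, jak2_responsive_in_wt=jak2_responsive
    )


@dataclass(frozen=True)
class DoubleMutantContrast:
    """Gene levels in the two double-mutant fixpoints.

    The JAK2-first programme shows higher RUNX1, KLF1 and GATA1 and lower
    MYC than the TET2-first programme — the elevated-differentiation
    signature of JAK2-first patients.
    """

    jak2_first: Dict[str, int]
    tet2_first: Dict[str, int]

    @property
    def holds(self) -> bool:
        up = all(self.jak2_first[g] > self.tet2_first[g] for g in ("RUNX1", "KLF1", "GATA1"))
        down = self.jak2_first["MYC"] < self.tet2_first["MYC"]
        return up and down


def double_mutant_contrast(model: QNModel) -> DoubleMutantContrast:
    fps = _column_fixpoints(model, ("JAK2_first", "TET2_first"))
    for col, fp in fps.items():
        if fp is None:
            raise ModelError(f"double mutant column {col} did not stabilise to a fixpoint")
    genes = ("RUNX1", "KLF1", "GATA1", "MYC", "HOXA9")
    return DoubleMutantContrast(
        jak2_first={g: fps["JAK2_first"][g] for g in genes},
        tet2_first={g: fps["TET2_first"][g] for g in genes},
    )


def double_mutant_bifurcation(model: QNModel) -> List[Attractor]:
    """Distinct final attractors of the double mutant across both orders."""
    results = bifurcation_analysis(
        model, wildtype_state(model), (JAK2_ACTIVATION, TET2_LOSS)
    )
    return distinct_final_attractors(results)


def find_compensated_instability(model: QNModel, max_steps: int = 200) -> Optional[Attractor]:
    """Search the double-mutant state space for a non-fixpoint attractor.

    In the compensated self-loop variant the SPI1/GATA1 mutual inhibition
    admits a synchronous 2-cycle that is not reached from the wild type;
    this scans all SPI1 x GATA1 initial levels around the order-reachable
    double-mutant baseline and returns the first cycle found.
    """
    dm = model
    for mut in (JAK2_ACTIVATION, TET2_LOSS):
        dm = dm.replace_variable(mut.variable, clamp=mut.level(model))
    baseline = order_experiment(
        model, wildtype_state(model), (JAK2_ACTIVATION, TET2_LOSS)
    ).final_attractor.states[0]
    spi1 = dm.variable("SPI1")
    gata1 = dm.variable("GATA1")
    for s_lvl, g_lvl in itertools.product(spi1.levels, gata1.levels):
        levels = baseline.as_dict()
        levels.update(SPI1=s_lvl, GATA1=g_lvl, JAK2=2, TET2=0)
        att = simulate_to_attractor(dm, dm.state(levels), max_steps)
        if not att.is_fixpoint:
            return att
    return None
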