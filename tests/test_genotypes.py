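"""Mutation application, order experiments, bifurcation, specification checks."""

import pytest

from hoxswitch.expr import TargetExpression
from hoxswitch.genotypes import (
    ACTIVATION,
    LOSS,
    SPEC_COLUMNS,
    Genotype,
    Mutation,
    SpecificationTable,
    apply_mutation,
    bifurcation_analysis,
    check_specification,
    distinct_final_attractors,
    order_experiment,
)
from hoxswitch.network import (
    ModelError,
    QNEdge,
    QNModel,
    QNVariable,
    simulate_to_attractor,
)
from hoxswitch.synth import RandomQNConfig, generate_random_qn

JAK2_ACT = Mutation("JAK2", ACTIVATION)
TET2_LOSS = Mutation("TET2", LOSS)


class TestApplyMutation:
    def test_loss_clamps_to_minimum(self, motif):
        mutant = apply_mutation(motif, TET2_LOSS)
        assert mutant.variable("TET2").clamp == 0
        assert motif.variable("TET2").clamp is None  # original untouched

    def test_activation_clamps_to_maximum(self, motif):
        assert apply_mutation(motif, JAK2_ACT).variable("JAK2").clamp == 2

    def test_double_application_rejected(self, motif):
        mutant = apply_mutation(motif, JAK2_ACT)
        with pytest.raises(ModelError, match="already clamped"):
            apply_mutation(mutant, JAK2_ACT)

    def test_unknown_variable_rejected(self, motif):
        with pytest.raises(ModelError, match="NOPE"):
            apply_mutation(motif, Mutation("NOPE", LOSS))

    def test_genotype_rejects_repeat_mutation(self):
        with pytest.raises(ValueError, match="more than once"):
            Genotype((JAK2_ACT, Mutation("JAK2", LOSS)))


class TestOrderExperiment:
    def test_jak2_first_locks_hoxa9_high(self, motif):
        result = order_experiment(motif, motif.uniform_state(1), [JAK2_ACT, TET2_LOSS])
        assert result.final_attractor.fixpoint["HOXA9"] == 2
        assert not result.unstable

    def test_tet2_first_locks_hoxa9_low(self, motif):
        result = order_experiment(motif, motif.uniform_state(1), [TET2_LOSS, JAK2_ACT])
        assert result.final_attractor.fixpoint["HOXA9"] == 0

    def test_empty_mutation_list_gives_wildtype_attractor(self, motif):
        result = order_experiment(motif, motif.uniform_state(1), [])
        assert len(result.stages) == 1
        assert result.final_attractor.fixpoint == motif.uniform_state(1)

    def test_trajectory_includes_wildtype_plus_each_stage(self, motif):
        result = order_experiment(motif, motif.uniform_state(1), [JAK2_ACT, TET2_LOSS])
        assert len(result.stages) == 3
        assert [len(g) for g, _ in result.stages] == [0, 1, 2]


class TestBifurcation:
    def test_motif_double_mutant_bifurcates(self, motif):
        results = bifurcation_analysis(motif, motif.uniform_state(1), [JAK2_ACT, TET2_LOSS])
        assert len(results) == 2  # both orders evaluated
        distinct = distinct_final_attractors(results)
        assert {a.fixpoint["HOXA9"] for a in distinct} == {0, 2}

    def test_memoryless_chain_has_single_outcome(self):
        # A -> B feed-forward: no feedback loop, no memory, order cannot matter
        model = QNModel(
            name="chain",
            variables=(
                QNVariable("A", target=TargetExpression.parse("1")),
                QNVariable("B", target=TargetExpression.parse("A")),
            ),
            edges=(QNEdge("A", "B", "activator"),),
        )
        results = bifurcation_analysis(
            model,
            model.uniform_state(1),
            [Mutation("A", ACTIVATION), Mutation("B", LOSS)],
        )
        assert len(distinct_final_attractors(results)) == 1

    def test_requires_at_least_two_mutations(self, motif):
        with pytest.raises(ValueError, match="two"):
            bifurcation_analysis(motif, motif.uniform_state(1), [JAK2_ACT])

    @pytest.mark.parametrize("seed", range(50))
    def test_acyclic_networks_never_bifurcate(self, seed):
        """Order sensitivity requires a feedback loop: feed-forward networks
        reach one attractor regardless of mutation order."""
        model = generate_random_qn(
            RandomQNConfig(n_vars=5, edge_density=0.5, acyclic=True, seed=seed)
        )
        muts = [Mutation("v0", ACTIVATION), Mutation("v1", LOSS)]
        results = bifurcation_analysis(model, model.uniform_state(1), muts)
        assert len(distinct_final_attractors(results)) == 1


def tiny_spec(phenotype="P", levels=(1, 1, 1, 1, 1)):
    expected = {(phenotype, col): lvl for col, lvl in zip(SPEC_COLUMNS, levels)}
    return SpecificationTable(phenotypes=(phenotype,), expected=expected)


class TestCheckSpecification:
    def _model(self):
        # JAK2/TET2 inputs plus a phenotype that copies HOXA9's motif value
        t1 = TargetExpression.parse("1")
        return QNModel(
            name="m",
            variables=(
                QNVariable("JAK2", target=t1),
                QNVariable("TET2", target=t1),
                QNVariable("HOXA9", target=TargetExpression.parse("JAK2 + TET2 + HOXA9 - 2")),
                QNVariable("P", target=TargetExpression.parse("HOXA9")),
            ),
            edges=(
                QNEdge("JAK2", "HOXA9", "activator"),
                QNEdge("TET2", "HOXA9", "activator"),
                QNEdge("HOXA9", "HOXA9", "activator"),
                QNEdge("HOXA9", "P", "activator"),
            ),
        )

    def test_motif_phenotype_levels(self):
        model = self._model()
        spec = tiny_spec(levels=(1, 0, 2, 0, 2))  # P follows the HOXA9 switch
        report = check_specification(model, spec, model.uniform_state(1))
        assert report.all_pass and report.n_total == 5

    def test_mismatch_reported_per_cell(self):
        model = self._model()
        report = check_specification(model, tiny_spec(), model.uniform_state(1))
        failed = {c.column for c in report.failures()}
        assert failed == {"TET2", "JAK2", "TET2_first", "JAK2_first"}

    def test_missing_phenotype_variables_named(self, motif):
        with pytest.raises(ModelError, match="P"):
            check_specification(motif, tiny_spec(), motif.uniform_state(1))

    def test_model_unchanged_by_check(self):
        model = self._model()
        check_specification(model, tiny_spec(), model.uniform_state(1))
        assert all(v.clamp is None for v in model.variables)

    def test_unstable_columns_fail_with_reason(self):
        # phenotype flip-flops: X copies Y, Y copies 2 - X, driven nowhere
        t1 = TargetExpression.parse("1")
        model = QNModel(
            name="unstable",
            variables=(
                QNVariable("JAK2", target=t1),
                QNVariable("TET2", target=t1),
                QNVariable("P", target=TargetExpression.parse("Q")),
                QNVariable("Q", target=TargetExpression.parse("2 - P")),
            ),
            edges=(QNEdge("Q", "P", "activator"), QNEdge("P", "Q", "inhibitor")),
        )
        init = model.state({"JAK2": 1, "TET2": 1, "P": 0, "Q": 2})
        report = check_specification(model, tiny_spec(), init)
        assert not report.all_pass
        assert all(c.reason == "unstable" for c in report.failures())


def test_specification_table_requires_all_cells():
    with pytest.raises(ValueError, match="missing cell"):
        SpecificationTable(phenotypes=("P",), expected={("P", "WT"): 1})
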