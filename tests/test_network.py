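"""Engine semantics: target evaluation, unit-step dynamics, attractors and
fixpoint enumeration (brute force vs constraint propagation)."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from hoxswitch.expr import TargetExpression
from hoxswitch.network import (
    ModelError,
    NetworkState,
    QNEdge,
    QNModel,
    QNVariable,
    enumerate_fixpoints,
    evaluate_target,
    is_fixpoint,
    simulate_to_attractor,
    step_synchronous,
)
from hoxswitch.synth import RandomQNConfig, generate_random_qn


def clamped_motif(jak2=None, tet2=None):
    """Three-node switch motif with optional clamps on the inputs."""
    t1 = TargetExpression.parse("1")
    return QNModel(
        name="motif",
        variables=(
            QNVariable("JAK2", target=t1, clamp=jak2),
            QNVariable("TET2", target=t1, clamp=tet2),
            QNVariable("HOXA9", target=TargetExpression.parse("JAK2 + TET2 + HOXA9 - 2")),
        ),
        edges=(
            QNEdge("JAK2", "HOXA9", "activator"),
            QNEdge("TET2", "HOXA9", "activator"),
            QNEdge("HOXA9", "HOXA9", "activator"),
        ),
    )


def two_node(sign_ab="inhibitor", sign_ba="inhibitor"):
    return QNModel(
        name="pair",
        variables=(QNVariable("A"), QNVariable("B")),
        edges=(QNEdge("A", "B", sign_ab), QNEdge("B", "A", sign_ba)),
    )


class TestEvaluateTarget:
    def test_motif_reference_function(self, motif):
        s = motif.state({"JAK2": 1, "TET2": 1, "HOXA9": 1})
        assert evaluate_target(motif, s, "HOXA9") == 1

    def test_motif_clips_to_range(self, motif):
        s = motif.state({"JAK2": 2, "TET2": 1, "HOXA9": 2})
        assert evaluate_target(motif, s, "HOXA9") == 2  # 3 clipped to 2

    def test_default_target_balances_activator_and_inhibitor(self):
        model = QNModel(
            name="t",
            variables=(QNVariable("A"), QNVariable("I"), QNVariable("X")),
            edges=(QNEdge("A", "X", "activator"), QNEdge("I", "X", "inhibitor")),
        )
        s = model.state({"A": 2, "I": 2, "X": 0})
        assert evaluate_target(model, s, "X") == 0

    def test_clamp_wins(self):
        model = clamped_motif(jak2=2)
        s = model.state({"JAK2": 2, "TET2": 0, "HOXA9": 0})
        assert evaluate_target(model, s, "JAK2") == 2

    def test_unknown_variable_named_in_error(self, motif):
        s = motif.uniform_state(1)
        with pytest.raises(ModelError, match="NOPE"):
            evaluate_target(motif, s, "NOPE")

    def test_rounding_is_half_up(self):
        # avg of levels 1 and 2 is 1.5 -> rounds to 2
        model = QNModel(
            name="t",
            variables=(QNVariable("A"), QNVariable("B"), QNVariable("X")),
            edges=(QNEdge("A", "X", "activator"), QNEdge("B", "X", "activator")),
        )
        s = model.state({"A": 1, "B": 2, "X": 0})
        assert evaluate_target(model, s, "X") == 2


class TestStepSynchronous:
    def test_unit_step_toward_distant_target(self):
        model = clamped_motif(jak2=2, tet2=2)
        s = model.state({"JAK2": 2, "TET2": 2, "HOXA9": 0})
        assert step_synchronous(model, s)["HOXA9"] == 1  # target 2, one step

    def test_fixpoint_is_identity(self, motif):
        s = motif.uniform_state(1)
        assert step_synchronous(motif, s) == s

    def test_convergence_from_any_start(self):
        # JAK2=2, TET2=1: HOXA9 converges to 2 from every start level
        model = clamped_motif(jak2=2, tet2=1)
        for h0 in (0, 1, 2):
            att = simulate_to_attractor(
                model, model.state({"JAK2": 2, "TET2": 1, "HOXA9": h0})
            )
            assert att.is_fixpoint and att.fixpoint["HOXA9"] == 2


class TestSimulateToAttractor:
    def test_tet2_loss_extinguishes_hoxa9(self):
        model = clamped_motif(jak2=1, tet2=0)
        att = simulate_to_attractor(model, model.state({"JAK2": 1, "TET2": 0, "HOXA9": 1}))
        assert att.is_fixpoint and att.fixpoint["HOXA9"] == 0

    def test_mutual_inhibitors_default_targets(self):
        # with empty activator sets the default target is -avg(inhibitors),
        # clipped to 0; the only fixpoint is (0, 0) and (2, 0) drains to it
        model = two_node()
        assert enumerate_fixpoints(model) == {model.state({"A": 0, "B": 0})}
        att = simulate_to_attractor(model, model.state({"A": 2, "B": 0}))
        assert att.is_fixpoint and att.fixpoint.as_dict() == {"A": 0, "B": 0}

    def test_fully_clamped_model_is_its_own_fixpoint(self):
        model = QNModel(
            name="c",
            variables=(QNVariable("A", clamp=2), QNVariable("B", clamp=1)),
            edges=(),
        )
        att = simulate_to_attractor(model, model.state({"A": 2, "B": 1}))
        assert att.is_fixpoint and att.fixpoint.as_dict() == {"A": 2, "B": 1}

    def test_max_steps_exhaustion_reports_bound(self):
        model = clamped_motif(jak2=2, tet2=2)
        s = model.state({"JAK2": 2, "TET2": 2, "HOXA9": 0})
        with pytest.raises(RuntimeError, match="max_steps=1"):
            simulate_to_attractor(model, s, max_steps=1)

    def test_cycle_detection_and_canonical_rotation(self):
        # negated self-loop: X -> 2 - X flips between 0 and 2 ... via 1;
        # target 2-X from 0 is 2, unit step to 1, then target 1 -> fixpoint.
        # Use a two-variable flip-flop instead: X copies Y, Y copies 2 - X.
        model = QNModel(
            name="flip",
            variables=(
                QNVariable("X", target=TargetExpression.parse("Y")),
                QNVariable("Y", target=TargetExpression.parse("2 - X")),
            ),
            edges=(QNEdge("Y", "X", "activator"), QNEdge("X", "Y", "inhibitor")),
        )
        att = simulate_to_attractor(model, model.state({"X": 0, "Y": 2}))
        assert att.kind == "cycle"
        assert att.states[0] == min(att.states)  # canonical start
        # one synchronous step maps states[i] to states[i+1 mod n]
        for i, s in enumerate(att.states):
            assert step_synchronous(model, s) == att.states[(i + 1) % att.period]


class TestEnumerateFixpoints:
    def test_degenerate_double_mutant_line_of_fixpoints(self):
        model = clamped_motif(jak2=2, tet2=0)
        fps = enumerate_fixpoints(model)
        assert {fp["HOXA9"] for fp in fps} == {0, 1, 2}

    def test_jak2_single_mutant_unique_fixpoint(self):
        model = clamped_motif(jak2=2, tet2=1)
        fps = enumerate_fixpoints(model)
        assert len(fps) == 1 and next(iter(fps))["HOXA9"] == 2

    def test_fully_clamped_has_exactly_one(self):
        model = QNModel(
            name="c", variables=(QNVariable("A", clamp=1),), edges=()
        )
        assert len(enumerate_fixpoints(model)) == 1

    def test_bound_enforced(self):
        model = generate_random_qn(RandomQNConfig(n_vars=6, seed=0))
        with pytest.raises(ModelError, match="bound"):
            enumerate_fixpoints(model, bound=10)

    @pytest.mark.parametrize("seed", range(25))
    def test_propagation_matches_brute_force(self, seed):
        cfg = RandomQNConfig(n_vars=6, edge_density=0.4, seed=seed)
        model = generate_random_qn(cfg)
        assert enumerate_fixpoints(model) == enumerate_fixpoints(model, propagate=True)

    def test_propagation_matches_on_expression_models(self):
        for jak2, tet2 in itertools.product((0, 1, 2), repeat=2):
            model = clamped_motif(jak2=jak2, tet2=tet2)
            assert enumerate_fixpoints(model) == enumerate_fixpoints(model, propagate=True)


@st.composite
def random_models_and_states(draw):
    seed = draw(st.integers(0, 10_000))
    n = draw(st.integers(2, 6))
    density = draw(st.sampled_from([0.2, 0.4, 0.8]))
    model = generate_random_qn(RandomQNConfig(n_vars=n, edge_density=density, seed=seed))
    levels = {v.id: draw(st.integers(v.range_min, v.range_max)) for v in model.variables}
    return model, model.state(levels)


class TestProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(random_models_and_states())
    def test_unit_step_and_determinism(self, model_state):
        model, state = model_state
        nxt = step_synchronous(model, state)
        assert all(abs(nxt[v] - state[v]) <= 1 for v in model.variable_ids)
        assert step_synchronous(model, state) == nxt  # pure function

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(random_models_and_states())
    def test_termination_within_state_space_bound(self, model_state):
        model, state = model_state
        att = simulate_to_attractor(model, state, max_steps=model.state_space_size() + 1)
        assert att.period >= 1
        if att.is_fixpoint:
            assert is_fixpoint(model, att.fixpoint)

    def test_clamp_dominance_in_attractors(self):
        for seed in range(10):
            model = generate_random_qn(RandomQNConfig(n_vars=5, seed=seed))
            model = model.replace_variable("v0", clamp=2)
            att = simulate_to_attractor(model, model.uniform_state(1))
            assert all(s["v0"] == 2 for s in att.states)


class TestStateValidation:
    def test_missing_variable_rejected(self, motif):
        with pytest.raises(ModelError, match="missing"):
            motif.state({"JAK2": 1, "TET2": 1})

    def test_out_of_range_rejected(self, motif):
        with pytest.raises(ModelError, match="range"):
            motif.state({"JAK2": 3, "TET2": 1, "HOXA9": 1})

    def test_clamp_violation_rejected(self):
        model = clamped_motif(jak2=2)
        with pytest.raises(ModelError, match="clamp"):
            model.state({"JAK2": 0, "TET2": 1, "HOXA9": 1})

    def test_target_reference_needs_matching_edge(self):
        with pytest.raises(ModelError, match="activator"):
            QNModel(
                name="bad",
                variables=(
                    QNVariable("A"),
                    QNVariable("B", target=TargetExpression.parse("A")),
                ),
                edges=(QNEdge("A", "B", "inhibitor"),),
            )
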