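import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ceatree import (
    Branch,
    ChanceNode,
    EvaluationError,
    Strategy,
    TerminalNode,
    outcome_probability,
    rollback,
    validate_tree,
)
from ceatree.tree import iter_paths

# Hand-rolled expectations for the bundled two-level model:
# P(depressed | no intervention) = 0.76*0.314 + 0.24*0.16 = 0.27704
# P(depressed | supplementation) = 0.172*0.314 + 0.828*0.16 = 0.186488
P_DEP_NOINT = 0.27704
P_DEP_SUPP = 0.186488
COST_NOINT = P_DEP_NOINT * 335.4                 # 92.9192016
COST_SUPP = P_DEP_SUPP * 335.4 + 0.604           # 63.1520752
EFF_NOINT = P_DEP_NOINT * 0.545 + (1 - P_DEP_NOINT) * 0.76   # 0.7004364
EFF_SUPP = P_DEP_SUPP * 0.545 + (1 - P_DEP_SUPP) * 0.76      # 0.71990508


def two_level_strategy(p_deficient, upfront=0.0, name="arm"):
    def status_node(p_dep):
        return ChanceNode(
            (
                Branch(p_dep, TerminalNode(335.4, 0.545, frozenset({"depressed"}))),
                Branch(1 - p_dep, TerminalNode(0.0, 0.76)),
            ),
            label="depression_status",
        )

    root = ChanceNode(
        (
            Branch(p_deficient, status_node(0.314), label="deficient"),
            Branch(1 - p_deficient, status_node(0.16), label="sufficient"),
        ),
        label="vitamin_d_status",
    )
    return Strategy(name, root, upfront)


class TestValidateTree:
    def test_bundled_strategies_are_valid(self, model):
        values = model.base_values()
        for s in model.strategies:
            assert validate_tree(s, values) == []

    def test_unnormalized_branch_pair_flagged(self):
        node = ChanceNode(
            (
                Branch(0.172, TerminalNode(0, 0.5)),
                Branch(0.872, TerminalNode(0, 0.5)),
            )
        )
        violations = validate_tree(Strategy("x", node))
        assert len(violations) == 1
        assert "sum" in violations[0]

    def test_single_branch_node_is_structural_violation(self):
        node = ChanceNode((Branch(1.0, TerminalNode(0, 0.5)),))
        assert any(">= 2 branches" in v for v in validate_tree(Strategy("x", node)))

    def test_bad_payoffs_flagged(self):
        node = ChanceNode(
            (
                Branch(0.5, TerminalNode(-1.0, 0.5)),
                Branch(0.5, TerminalNode(0.0, 1.5)),
            )
        )
        violations = validate_tree(Strategy("x", node))
        assert len(violations) == 2

    def test_dangling_reference_reported_not_raised(self):
        node = ChanceNode(
            (
                Branch("p_missing", TerminalNode(0, 0.5)),
                Branch(0.5, TerminalNode(0, 0.5)),
            )
        )
        assert any("p_missing" in v for v in validate_tree(Strategy("x", node), {}))


class TestRollback:
    def test_no_intervention_expectations(self):
        res = rollback(two_level_strategy(0.76), {})
        assert res.expected_cost == pytest.approx(COST_NOINT, rel=1e-12)
        assert res.expected_effect == pytest.approx(EFF_NOINT, rel=1e-12)

    def test_supplementation_expectations(self):
        res = rollback(two_level_strategy(0.172, upfront=0.604), {})
        assert res.expected_cost == pytest.approx(COST_SUPP, rel=1e-12)
        assert res.expected_effect == pytest.approx(EFF_SUPP, rel=1e-12)

    def test_bundled_model_matches_hand_rollback(self, base_results):
        res_int, res_comp = base_results
        assert res_comp.expected_cost == pytest.approx(COST_NOINT, rel=1e-12)
        assert res_comp.expected_effect == pytest.approx(EFF_NOINT, rel=1e-12)
        assert res_int.expected_cost == pytest.approx(COST_SUPP, rel=1e-12)
        assert res_int.expected_effect == pytest.approx(EFF_SUPP, rel=1e-12)

    def test_terminal_root(self):
        res = rollback(Strategy("t", TerminalNode(5.0, 0.9), upfront_cost=1.0), {})
        assert res.expected_cost == 6.0
        assert res.expected_effect == 0.9

    def test_unresolved_reference_raises(self):
        with pytest.raises(EvaluationError, match="c_missing"):
            rollback(Strategy("t", TerminalNode("c_missing", 0.9)), {})

    def test_vectorized_over_array_parameters(self):
        s = Strategy("t", TerminalNode("c", "u"), upfront_cost=0.0)
        params = {"c": np.array([1.0, 2.0]), "u": np.array([0.1, 0.2])}
        res = rollback(s, params)
        assert np.allclose(res.expected_cost, [1.0, 2.0])
        assert np.allclose(res.expected_effect, [0.1, 0.2])


class TestOutcomeProbability:
    def test_depression_mass_no_intervention(self):
        assert outcome_probability(two_level_strategy(0.76), {}) == pytest.approx(
            P_DEP_NOINT, rel=1e-12
        )

    def test_depression_mass_supplementation(self):
        assert outcome_probability(two_level_strategy(0.172), {}) == pytest.approx(
            P_DEP_SUPP, rel=1e-12
        )

    def test_zero_mass_when_branch_closed(self):
        s = two_level_strategy(0.0)
        # deficiency branch closed: only the 0.16 sufficient-arm prevalence remains
        assert outcome_probability(s, {}) == pytest.approx(0.16, rel=1e-12)

    def test_missing_tag_raises(self):
        s = Strategy("t", TerminalNode(0.0, 0.5))
        with pytest.raises(EvaluationError, match="no leaf tagged"):
            outcome_probability(s, {})


# --- random-tree oracle -----------------------------------------------------

@st.composite
def random_trees(draw, max_depth=4):
    """Chance trees up to 4 levels with exact-normalized probabilities."""

    def node(depth):
        if depth >= max_depth or draw(st.booleans()):
            cost = draw(st.floats(0, 1000, allow_nan=False))
            utility = draw(st.floats(0, 1, allow_nan=False))
            return TerminalNode(cost, utility)
        k = draw(st.integers(2, 3))
        raw = [draw(st.floats(0.01, 1.0)) for _ in range(k)]
        total = sum(raw)
        probs = [r / total for r in raw]
        probs[-1] = 1.0 - sum(probs[:-1])  # exact normalization
        return ChanceNode(tuple(Branch(p, node(depth + 1)) for p in probs))

    root = node(1)
    if isinstance(root, TerminalNode):
        root = ChanceNode((Branch(0.5, root), Branch(0.5, TerminalNode(1.0, 0.5))))
    return Strategy("random", root, draw(st.floats(0, 10)))


def enumerate_expectation(strategy):
    """Independent oracle: recursive expectation, no path bookkeeping."""

    def expect(node):
        if isinstance(node, TerminalNode):
            return float(node.cost), float(node.utility)
        cost = effect = 0.0
        for b in node.branches:
            c, e = expect(b.child)
            cost += float(b.probability) * c
            effect += float(b.probability) * e
        return cost, effect

    c, e = expect(strategy.root)
    return float(strategy.upfront_cost) + c, e


@given(random_trees())
@settings(max_examples=100, deadline=None, derandomize=True)
def test_rollback_matches_recursive_expectation(strategy):
    res = rollback(strategy, {})
    cost, effect = enumerate_expectation(strategy)
    assert res.expected_cost == pytest.approx(cost, rel=1e-9, abs=1e-12)
    assert res.expected_effect == pytest.approx(effect, rel=1e-9, abs=1e-12)


@given(random_trees())
@settings(max_examples=100, deadline=None, derandomize=True)
def test_path_probabilities_conserve_mass(strategy):
    total = sum(p for p, _ in iter_paths(strategy.root, {}))
    assert total == pytest.approx(1.0, abs=1e-9)


def test_effect_monotone_in_leaf_utility():
    """Raising any leaf utility weakly raises the expected effect."""
    base = rollback(two_level_strategy(0.76), {})
    bumped_tree = two_level_strategy(0.76)
    # bump the depressed utility on the deficient branch
    status = bumped_tree.root.branches[0].child
    bumped_status = ChanceNode(
        (
            Branch(status.branches[0].probability, TerminalNode(335.4, 0.60, frozenset({"depressed"}))),
            status.branches[1],
        ),
        label=status.label,
    )
    bumped = Strategy(
        "arm",
        ChanceNode(
            (Branch(0.76, bumped_status, label="deficient"), bumped_tree.root.branches[1]),
            label=bumped_tree.root.label,
        ),
    )
    assert rollback(bumped, {}).expected_effect > base.expected_effect


def test_cost_and_effect_monotone_in_depression_risk():
    """More deficiency means more depression: higher cost, lower effect."""
    low = rollback(two_level_strategy(0.172), {})
    high = rollback(two_level_strategy(0.76), {})
    assert high.expected_cost > low.expected_cost
    assert high.expected_effect < low.expected_effect
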