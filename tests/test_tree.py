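"""Decision-tree construction, validation and expected-value rollback."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitd_cea import (
    NO_INTERVENTION,
    SUPPLEMENTATION,
    Payoff,
    TreeNode,
    build_vitd_tree,
    rollback,
    validate_tree,
)
from vitd_cea.tree import TreeModel, path_probabilities, tree_to_dict


def expected_values_closed_form(params, arm):
    """Independent hand formula: two-branch mixture, no tree involved.

    P(dm) = p_def*p_dm_def + p_suf*p_dm_suf per arm;
    effect = u_healthy - P(dm)*(u_healthy - u_dm);
    cost = base + P(dm)*c_dm.
    """
    if arm == NO_INTERVENTION:
        p_def, base = params.p_def_pre, 0.0
    else:
        p_def, base = params.p_def_post, params.c_vitd
    p_dm = p_def * params.p_dm_def + (1 - p_def) * params.p_dm_suf
    cost = base + p_dm * params.c_dm
    effect = params.u_healthy - p_dm * (params.u_healthy - params.u_dm)
    return cost, effect


class TestBuildTree:
    def test_structure_and_terminal_payoffs(self, params):
        tree = build_vitd_tree(params)
        assert [label for label, _ in tree.root.children] == [
            NO_INTERVENTION,
            SUPPLEMENTATION,
        ]
        supp = tree.root.children[1][1]
        p_def, deficient_node = supp.children[0]
        assert p_def == pytest.approx(0.172)
        p_dm, diabetic_terminal = deficient_node.children[0]
        assert p_dm == pytest.approx(0.128)
        assert diabetic_terminal.payoff.cost == pytest.approx(710.61)
        assert diabetic_terminal.payoff.effect == pytest.approx(0.59)

    def test_zero_supplement_cost_arms_share_payoff_sets(self, params):
        tree = build_vitd_tree(params.with_values(c_vitd=0.0))
        costs = {
            arm: sorted({p.cost for _, p in path_probabilities(tree, arm)})
            for arm in (NO_INTERVENTION, SUPPLEMENTATION)
        }
        assert costs[NO_INTERVENTION] == costs[SUPPLEMENTATION] == [0.0, 710.0]

    def test_built_tree_validates(self, params):
        assert validate_tree(build_vitd_tree(params)) == []

    def test_normalize_mode_accepts_published_raw_pair(self, params):
        # Ingesting the raw published 0.172/0.872 pair with normalization
        # recovers the 0.172/0.828 split (renormalized by the 1.044 sum).
        tree = build_vitd_tree(params, normalize=True)
        assert validate_tree(tree) == []


class TestValidateTree:
    def test_inconsistent_branch_pair_diagnosed(self):
        bad = TreeModel(
            TreeNode(
                "decision",
                "strategy",
                children=[
                    (
                        "arm",
                        TreeNode(
                            "chance",
                            "status",
                            children=[
                                (0.172, TreeNode("terminal", "a", payoff=Payoff(0, 0.5))),
                                (0.872, TreeNode("terminal", "b", payoff=Payoff(0, 0.5))),
                            ],
                        ),
                    )
                ],
            )
        )
        diags = validate_tree(bad)
        assert len(diags) == 1
        assert "sum to 1.044" in diags[0]

    def test_terminal_with_child_diagnosed(self):
        t = TreeNode("terminal", "leaf", payoff=Payoff(0, 0.5))
        t.children = [(1.0, TreeNode("terminal", "orphan", payoff=Payoff(0, 0.5)))]
        diags = validate_tree(TreeModel(TreeNode("decision", "root", children=[("s", t)])))
        assert any("leaf" in d and "children" in d for d in diags)

    def test_rollback_refuses_invalid_tree(self):
        bad = TreeModel(
            TreeNode(
                "decision",
                "root",
                children=[
                    (
                        "s",
                        TreeNode(
                            "chance",
                            "c",
                            children=[(0.3, TreeNode("terminal", "t", payoff=Payoff(0, 0.5)))],
                        ),
                    )
                ],
            )
        )
        with pytest.raises(ValueError, match="validation"):
            rollback(bad, "s")


class TestRollback:
    def test_base_case_no_intervention(self, params):
        cost, effect = rollback(build_vitd_tree(params), NO_INTERVENTION)
        assert cost == pytest.approx(80.9968, abs=1e-10)
        assert effect == pytest.approx(0.7406064, abs=1e-12)

    def test_base_case_supplementation(self, params):
        cost, effect = rollback(build_vitd_tree(params), SUPPLEMENTATION)
        assert cost == pytest.approx(57.39296, abs=1e-10)
        assert effect == pytest.approx(0.74640408, abs=1e-12)

    def test_unknown_strategy(self, params):
        with pytest.raises(KeyError, match="unknown strategy"):
            rollback(build_vitd_tree(params), "placebo")

    def test_zero_costs_conserve(self, params):
        p = params.with_values(c_vitd=0.0, c_dm=0.0)
        for arm in (NO_INTERVENTION, SUPPLEMENTATION):
            cost, _ = rollback(build_vitd_tree(p), arm)
            assert cost == 0.0

    @given(k=st.floats(min_value=0.0, max_value=10.0, allow_nan=False))
    @settings(derandomize=True, max_examples=25)
    def test_cost_linearity(self, params, k):
        """Scaling all terminal costs by k scales expected cost by k."""
        base_costs = {
            arm: rollback(build_vitd_tree(params), arm)[0]
            for arm in (NO_INTERVENTION, SUPPLEMENTATION)
        }
        scaled = params.with_values(c_vitd=params.c_vitd * k, c_dm=params.c_dm * k)
        for arm in (NO_INTERVENTION, SUPPLEMENTATION):
            cost, _ = rollback(build_vitd_tree(scaled), arm)
            assert cost == pytest.approx(k * base_costs[arm], rel=1e-12, abs=1e-12)

    @given(
        p_def=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        p_dm_def=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        p_dm_suf=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=50)
    def test_probability_conservation(self, params, p_def, p_dm_def, p_dm_suf):
        """Path probabilities per strategy partition unit mass."""
        p = params.with_values(
            p_def_pre=p_def,
            p_suf_pre=1 - p_def,
            p_dm_def=p_dm_def,
            p_dm_suf=p_dm_suf,
        )
        tree = build_vitd_tree(p)
        for arm in (NO_INTERVENTION, SUPPLEMENTATION):
            total = sum(prob for prob, _ in path_probabilities(tree, arm))
            assert total == pytest.approx(1.0, abs=1e-9)

    @given(
        p_def_post=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        c_dm=st.floats(min_value=0.0, max_value=5000.0, allow_nan=False),
        u_dm=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=50)
    def test_rollback_matches_closed_form_mixture(self, params, p_def_post, c_dm, u_dm):
        """Tree fold agrees with the independent mixture-formula oracle."""
        p = params.with_values(
            p_def_post=p_def_post, p_suf_post=1 - p_def_post, c_dm=c_dm, u_dm=u_dm
        )
        tree = build_vitd_tree(p)
        for arm in (NO_INTERVENTION, SUPPLEMENTATION):
            got = rollback(tree, arm)
            want = expected_values_closed_form(p, arm)
            assert np.allclose(got, want, rtol=1e-12, atol=1e-12)


class TestSerialization:
    def test_round_trip_structure(self, params):
        doc = tree_to_dict(build_vitd_tree(params).root)
        assert doc["kind"] == "decision"
        assert [s["strategy"] for s in doc["strategies"]] == [
            NO_INTERVENTION,
            SUPPLEMENTATION,
        ]
        leaf = doc["strategies"][1]["branches"][0]["branches"][0]
        assert leaf["payoff"] == {"cost": 710.61, "effect": 0.59}
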