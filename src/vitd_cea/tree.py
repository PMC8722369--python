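"""Two-strategy decision tree and expected-value rollback.

The model compares "no intervention" against a nine-month vitamin D
supplementation course in adolescents. Each strategy arm branches on
vitamin D status (deficient/sufficient) and then on developing type 2
diabetes, ending in a terminal (cost, QALY) payoff. Rollback is exact:
with eight terminals, expected values are computed by enumerating every
root-to-leaf path and probability-weighting its payoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import ParameterSet

__all__ = [
    "Payoff",
    "TreeNode",
    "TreeModel",
    "NO_INTERVENTION",
    "SUPPLEMENTATION",
    "STRATEGIES",
    "build_vitd_tree",
    "validate_tree",
    "rollback",
    "path_probabilities",
    "tree_to_dict",
]

NO_INTERVENTION = "no_intervention"
SUPPLEMENTATION = "vitd_supplementation"
STRATEGIES = (NO_INTERVENTION, SUPPLEMENTATION)

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class Payoff:
    """Terminal payoff: per-person cost (USD) and effect (QALYs) over one year."""

    cost: float
    effect: float

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"payoff cost must be non-negative, got {self.cost}")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError(f"one-year payoff effect must lie in [0, 1], got {self.effect}")


@dataclass
class TreeNode:
    """A node of the decision tree.

    ``kind`` is one of ``decision`` (children keyed by strategy label),
    ``chance`` (children keyed by branch probability) or ``terminal``
    (carries a Payoff, no children).
    """

    kind: str
    label: str
    children: list[tuple[object, "TreeNode"]] = field(default_factory=list)
    payoff: Payoff | None = None


@dataclass
class TreeModel:
    """A decision tree whose root offers exactly the two model strategies."""

    root: TreeNode


def _terminal(label: str, cost: float, effect: float) -> TreeNode:
    return TreeNode("terminal", label, payoff=Payoff(cost, effect))


def _status_subtree(
    label: str,
    p_def: float,
    p_suf: float,
    p_dm_def: float,
    p_dm_suf: float,
    base_cost: float,
    params: ParameterSet,
    normalize: bool = False,
) -> TreeNode:
    """Status chance node -> diabetes chance nodes -> four terminals.

    ``base_cost`` is the strategy-wide cost incurred regardless of outcome
    (the supplementation program cost, or zero).
    """
    if normalize:
        s = p_def + p_suf
        p_def, p_suf = p_def / s, p_suf / s

    def dm_node(status: str, p_dm: float) -> TreeNode:
        return TreeNode(
            "chance",
            f"{label}/{status}",
            children=[
                (p_dm, _terminal(f"{label}/{status}/t2dm", base_cost + params.c_dm, params.u_dm)),
                (1.0 - p_dm, _terminal(f"{label}/{status}/healthy", base_cost, params.u_healthy)),
            ],
        )

    return TreeNode(
        "chance",
        label,
        children=[
            (p_def, dm_node("deficient", p_dm_def)),
            (p_suf, dm_node("sufficient", p_dm_suf)),
        ],
    )


def build_vitd_tree(params: ParameterSet, normalize: bool = False) -> TreeModel:
    """Build the two-strategy tree from a parameter set.

    With ``normalize=True`` each status pair is rescaled to sum to one
    before the tree is built, which permits ingesting the published raw
    0.172/0.872 pair; the default is strict and expects valid pairs.
    """
    no_int = _status_subtree(
        NO_INTERVENTION,
        params.p_def_pre,
        params.p_suf_pre,
        params.p_dm_def,
        params.p_dm_suf,
        base_cost=0.0,
        params=params,
        normalize=normalize,
    )
    supp = _status_subtree(
        SUPPLEMENTATION,
        params.p_def_post,
        params.p_suf_post,
        params.p_dm_def,
        params.p_dm_suf,
        base_cost=params.c_vitd,
        params=params,
        normalize=normalize,
    )
    root = TreeNode(
        "decision",
        "strategy",
        children=[(NO_INTERVENTION, no_int), (SUPPLEMENTATION, supp)],
    )
    return TreeModel(root)


def validate_tree(tree: TreeModel) -> list[str]:
    """Return one diagnostic string per invariant violation (empty if valid)."""
    diagnostics: list[str] = []
    seen: set[int] = set()

    def visit(node: TreeNode) -> None:
        if id(node) in seen:
            diagnostics.append(f"node {node.label!r}: cycle or shared subtree detected")
            return
        seen.add(id(node))
        if node.kind == "terminal":
            if node.children:
                diagnostics.append(f"terminal node {node.label!r} has children")
            if node.payoff is None:
                diagnostics.append(f"terminal node {node.label!r} lacks a payoff")
            return
        if node.kind not in ("decision", "chance"):
            diagnostics.append(f"node {node.label!r}: unknown kind {node.kind!r}")
            return
        if not node.children:
            diagnostics.append(f"{node.kind} node {node.label!r} has no children")
        if node.payoff is not None:
            diagnostics.append(f"{node.kind} node {node.label!r} carries a payoff")
        if node.kind == "chance":
            probs = [p for p, _ in node.children]
            bad = [p for p in probs if not isinstance(p, (int, float)) or not 0 <= p <= 1]
            if bad:
                diagnostics.append(
                    f"chance node {node.label!r}: branch probabilities outside [0, 1]: {bad}"
                )
            elif abs(sum(probs) - 1.0) > _PROB_TOL:
                diagnostics.append(
                    f"chance node {node.label!r}: branch probabilities sum to {sum(probs):g}"
                )
        for _, child in node.children:
            visit(child)

    root = tree.root
    if root.kind != "decision":
        diagnostics.append(f"root node {root.label!r} must be a decision node")
    visit(root)
    return diagnostics


def _strategy_subtree(tree: TreeModel, strategy: str) -> TreeNode:
    for label, child in tree.root.children:
        if label == strategy:
            return child
    known = [label for label, _ in tree.root.children]
    raise KeyError(f"unknown strategy {strategy!r}; tree offers {known}")


def path_probabilities(tree: TreeModel, strategy: str) -> list[tuple[float, Payoff]]:
    """Enumerate (path probability, terminal payoff) pairs for one strategy."""
    paths: list[tuple[float, Payoff]] = []

    def walk(node: TreeNode, prob: float) -> None:
        if node.kind == "terminal":
            assert node.payoff is not None
            paths.append((prob, node.payoff))
            return
        for weight, child in node.children:
            walk(child, prob * float(weight))

    walk(_strategy_subtree(tree, strategy), 1.0)
    return paths


def rollback(tree: TreeModel, strategy: str) -> tuple[float, float]:
    """Expected (cost, effect) of a strategy by exact path enumeration."""
    diags = validate_tree(tree)
    if diags:
        raise ValueError("tree fails validation: " + "; ".join(diags))
    cost = 0.0
    effect = 0.0
    for prob, payoff in path_probabilities(tree, strategy):
        cost += prob * payoff.cost
        effect += prob * payoff.effect
    return cost, effect


def tree_to_dict(node: TreeNode) -> dict:
    """Serialize a node (and subtree) to a nested plain-dict document."""
    doc: dict = {"kind": node.kind, "label": node.label}
    if node.kind == "terminal":
        assert node.payoff is not None
        doc["payoff"] = {"cost": node.payoff.cost, "effect": node.payoff.effect}
    elif node.kind == "chance":
        doc["branches"] = [
            {"probability": float(p), **tree_to_dict(child)} for p, child in node.children
        ]
    else:
        doc["strategies"] = [
            {"strategy": label, **tree_to_dict(child)} for label, child in node.children
        ]
    return doc
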