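"""High-level convenience pipeline: parameters → tree → rollback → metrics."""

from __future__ import annotations

from .metrics import CEAResult, incremental_analysis
from .params import ParameterSet
from .tree import NO_INTERVENTION, SUPPLEMENTATION, build_vitd_tree, rollback

__all__ = ["base_case_analysis", "strategy_values"]


def strategy_values(params: ParameterSet) -> dict[str, tuple[float, float]]:
    """Expected (cost, effect) per strategy from an exact tree rollback."""
    tree = build_vitd_tree(params)
    return {s: rollback(tree, s) for s in (NO_INTERVENTION, SUPPLEMENTATION)}


def base_case_analysis(params: ParameterSet) -> CEAResult:
    """Full incremental analysis of supplementation vs. no intervention."""
    values = strategy_values(params)
    return incremental_analysis(values[SUPPLEMENTATION], values[NO_INTERVENTION])
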