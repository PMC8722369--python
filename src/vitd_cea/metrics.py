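"""Incremental cost-effectiveness metrics and decision rules.

Two ICER conventions are exposed. The standard convention is
(C_int − C_comp)/(E_int − E_comp), replaced by a dominance verdict when
one strategy is both cheaper and more effective. The published headline
table instead prints the savings-per-QALY ratio
(C_comp − C_int)/(E_int − E_comp) as a positive number even though the
intervention strictly dominates; ``icer_as_printed`` reproduces that
figure verbatim without adopting it as the headline classification.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd

from .tree import NO_INTERVENTION, SUPPLEMENTATION

__all__ = [
    "CEAResult",
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
    "EQUIVALENT",
    "incremental_analysis",
    "net_monetary_benefit",
    "decide",
    "result_table",
    "render_table",
]

# Markers replacing the standard ICER when a ratio would mislead.
DOMINANT = "dominant"  # intervention cheaper AND more effective
DOMINATED = "dominated"  # intervention costlier AND less effective
UNDEFINED = "undefined"  # zero effect difference, nonzero cost difference
EQUIVALENT = "equivalent"  # both differences zero


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of an intervention against a comparator.

    ``delta_cost`` follows the published orientation, comparator minus
    intervention, so a positive value denotes savings; ``delta_effect``
    is intervention minus comparator. ``quadrant`` locates the standard
    incremental pair (E_int − E_comp, C_int − C_comp) on the
    cost-effectiveness plane (NE = costlier & more effective, SE =
    cheaper & more effective, ...).
    """

    intervention: str
    comparator: str
    cost_intervention: float
    cost_comparator: float
    effect_intervention: float
    effect_comparator: float
    delta_cost: float
    delta_effect: float
    icer_standard: float | str
    icer_as_printed: float | None
    quadrant: str
    dominant: bool

    @property
    def cost_per_strategy(self) -> dict[str, float]:
        return {self.comparator: self.cost_comparator, self.intervention: self.cost_intervention}

    @property
    def effect_per_strategy(self) -> dict[str, float]:
        return {
            self.comparator: self.effect_comparator,
            self.intervention: self.effect_intervention,
        }


def _quadrant(d_effect: float, d_cost_standard: float) -> str:
    ew = "E" if d_effect >= 0 else "W"
    ns = "N" if d_cost_standard >= 0 else "S"
    return ns + ew


def incremental_analysis(
    intervention: tuple[float, float],
    comparator: tuple[float, float],
    intervention_label: str = SUPPLEMENTATION,
    comparator_label: str = NO_INTERVENTION,
) -> CEAResult:
    """Full incremental analysis of two (cost, effect) pairs."""
    c_int, e_int = intervention
    c_comp, e_comp = comparator
    delta_cost = c_comp - c_int  # printed orientation: positive = savings
    delta_effect = e_int - e_comp
    d_cost_std = c_int - c_comp

    dominant = c_int < c_comp and e_int > e_comp
    dominated = c_int > c_comp and e_int < e_comp

    icer_standard: float | str
    if delta_effect == 0 and d_cost_std == 0:
        icer_standard = EQUIVALENT
    elif delta_effect == 0:
        icer_standard = UNDEFINED
    elif dominant:
        icer_standard = DOMINANT
    elif dominated:
        icer_standard = DOMINATED
    else:
        icer_standard = d_cost_std / delta_effect

    icer_as_printed = delta_cost / delta_effect if delta_effect != 0 else None

    return CEAResult(
        intervention=intervention_label,
        comparator=comparator_label,
        cost_intervention=c_int,
        cost_comparator=c_comp,
        effect_intervention=e_int,
        effect_comparator=e_comp,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer_standard=icer_standard,
        icer_as_printed=icer_as_printed,
        quadrant=_quadrant(delta_effect, d_cost_std),
        dominant=dominant,
    )


def net_monetary_benefit(cost: float, effect: float, wtp: float) -> float:
    """Net monetary benefit λ·effect − cost at willingness-to-pay λ (USD/QALY)."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be non-negative, got {wtp}")
    return wtp * effect - cost


def decide(result: CEAResult, wtp: float) -> str:
    """Preferred strategy at willingness-to-pay ``wtp`` by net monetary benefit.

    Ties go to the comparator (conservative: the intervention must
    strictly improve NMB to be adopted).
    """
    nmb_int = net_monetary_benefit(result.cost_intervention, result.effect_intervention, wtp)
    nmb_comp = net_monetary_benefit(result.cost_comparator, result.effect_comparator, wtp)
    return result.intervention if nmb_int > nmb_comp else result.comparator


def result_table(result: CEAResult) -> pd.DataFrame:
    """Headline table: one row per strategy, incremental columns on the comparator row.

    Layout mirrors the published base-case table (Strategy, Cost($),
    Incr Cost($), Eff, Incr Eff, ICER); values are rounded the way the
    publication prints them (costs 4 dp, effects 5 dp, ICER 2 dp). Full
    precision stays on the CEAResult.
    """
    printed_icer = result.icer_as_printed
    rows = [
        {
            "Strategy": "No Intervention",
            "Cost($)": round(result.cost_comparator, 4),
            "Incr Cost($)": round(result.delta_cost, 5),
            "Eff": round(result.effect_comparator, 5),
            "Incr Eff": round(result.delta_effect, 4),
            "ICER (USD / QALY)": None if printed_icer is None else round(printed_icer, 2),
        },
        {
            "Strategy": "Vitamin D Supplementation",
            "Cost($)": round(result.cost_intervention, 5),
            "Incr Cost($)": 0,
            "Eff": round(result.effect_intervention, 5),
            "Incr Eff": None,
            "ICER (USD / QALY)": None,
        },
    ]
    return pd.DataFrame(rows)


def render_table(result: CEAResult) -> str:
    """Aligned-text rendering of the headline table plus the dominance verdict."""
    df = result_table(result)
    buf = io.StringIO()
    buf.write(df.to_string(index=False, na_rep=""))
    buf.write("\n\n")
    if result.dominant:
        verdict = (
            f"{result.intervention} strictly dominates {result.comparator} "
            "(cheaper and more effective)"
        )
    elif result.icer_standard == DOMINATED:
        verdict = f"{result.intervention} is dominated by {result.comparator}"
    else:
        verdict = f"standard ICER: {result.icer_standard}"
    buf.write(f"Classification: {verdict}\n")
    buf.write(
        f"Quadrant: {result.quadrant}; savings-per-QALY ratio as printed: "
        f"{result.icer_as_printed:.2f} USD/QALY\n"
        if result.icer_as_printed is not None
        else f"Quadrant: {result.quadrant}\n"
    )
    return buf.getvalue()
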