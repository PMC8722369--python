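"""Probabilistic sensitivity analysis over the decision tree.

Each iteration draws the uncertain parameters (supplementation cost and
diabetes cost from moment-matched Gamma distributions, diabetic utility
from a moment-matched Beta; healthy utility and all tree probabilities
held fixed, matching the published uncertainty table), rebuilds the
tree, rolls back both strategies, and records the incremental pair and
the net-monetary-benefit-preferred strategy on a willingness-to-pay
grid. The whole run is a pure function of (base parameters, config):
one integer seed drives a single numpy Generator, and draws are consumed
in the fixed order c_vitd, c_dm, u_dm (then any extra varied parameter
in sorted order) so results reproduce bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import incremental_analysis, net_monetary_benefit
from .params import DistributionSpec, ParameterSet, beta_from_moments, gamma_from_moments
from .tree import NO_INTERVENTION, SUPPLEMENTATION, build_vitd_tree, rollback

__all__ = ["PSAConfig", "PSAResult", "sample_parameter_set", "run_psa", "ceac", "export_scatter", "plot_scatter"]

#: Canonical draw order for the parameters the publication varies.
_DRAW_ORDER = ("c_vitd", "c_dm", "u_dm")


@dataclass(frozen=True)
class PSAConfig:
    """Configuration of a probabilistic sensitivity analysis run.

    Defaults follow the published analysis: 1000 Monte Carlo iterations
    varying the two costs and the diabetic utility, evaluated at the
    willingness-to-pay band endpoints 1032 and 2666 USD/QALY.
    """

    n_iterations: int = 1000
    seed: int = 0
    varied_parameters: tuple[str, ...] = ("c_vitd", "c_dm", "u_dm")
    lambda_grid: tuple[float, ...] = (1032.0, 2666.0)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size == 0 or np.any(grid < 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("lambda_grid must be non-empty, non-negative, strictly increasing")


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration records and summary of one seeded PSA run.

    ``records`` has one row per iteration with the sampled parameter
    values, per-strategy costs and effects, the incremental pair in the
    printed orientation (delta_cost = comparator − intervention), a
    strict-dominance flag, and the preferred strategy at each grid λ
    (columns ``prefer_at_<λ>``). ``summary`` holds the acceptability
    fraction per λ and the fraction of strictly dominant iterations.
    """

    records: pd.DataFrame
    seed: int
    config: PSAConfig
    summary: dict[str, float] = field(default_factory=dict)


def _draw(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "fixed":
        return spec.mean
    if spec.family == "gamma":
        shape, scale = gamma_from_moments(spec.mean, spec.sd)
        return float(rng.gamma(shape, scale))
    alpha, beta = beta_from_moments(spec.mean, spec.sd)
    return float(rng.beta(alpha, beta))


def _ordered_varied(varied: tuple[str, ...]) -> list[str]:
    canonical = [p for p in _DRAW_ORDER if p in varied]
    extra = sorted(set(varied) - set(_DRAW_ORDER))
    return canonical + extra


def sample_parameter_set(
    base: ParameterSet,
    rng: np.random.Generator,
    varied_parameters: tuple[str, ...] = ("c_vitd", "c_dm", "u_dm"),
) -> ParameterSet:
    """One joint draw of the varied parameters; all others untouched.

    Draws consume ``rng`` in the documented fixed order. A parameter
    whose spec is ``fixed`` is returned at its base value without
    consuming randomness.
    """
    overrides: dict[str, float] = {}
    for name in _ordered_varied(tuple(varied_parameters)):
        spec = base.psa_specs.get(name)
        if spec is None:
            raise KeyError(f"no distribution spec for varied parameter {name!r}")
        if spec.family != "fixed":
            overrides[name] = _draw(spec, rng)
    return base.with_values(**overrides) if overrides else base


def run_psa(base: ParameterSet, config: PSAConfig) -> PSAResult:
    """Run the full Monte Carlo PSA; deterministic given (base, config)."""
    rng = np.random.default_rng(config.seed)
    varied = _ordered_varied(config.varied_parameters)
    rows: list[dict[str, float | int | str | bool]] = []
    for i in range(config.n_iterations):
        sampled = sample_parameter_set(base, rng, config.varied_parameters)
        tree = build_vitd_tree(sampled)
        c0, e0 = rollback(tree, NO_INTERVENTION)
        c1, e1 = rollback(tree, SUPPLEMENTATION)
        res = incremental_analysis((c1, e1), (c0, e0))
        row: dict[str, float | int | str | bool] = {"iteration": i}
        for name in varied:
            row[name] = getattr(sampled, name)
        row.update(
            cost_no_intervention=c0,
            effect_no_intervention=e0,
            cost_supplementation=c1,
            effect_supplementation=e1,
            delta_cost=res.delta_cost,
            delta_effect=res.delta_effect,
            dominant=res.dominant,
        )
        for lam in config.lambda_grid:
            nmb_diff = net_monetary_benefit(c1, e1, lam) - net_monetary_benefit(c0, e0, lam)
            row[f"prefer_at_{lam:g}"] = SUPPLEMENTATION if nmb_diff > 0 else NO_INTERVENTION
        rows.append(row)
    records = pd.DataFrame(rows)
    summary = {
        f"acceptability_at_{lam:g}": float(
            (records[f"prefer_at_{lam:g}"] == SUPPLEMENTATION).mean()
        )
        for lam in config.lambda_grid
    }
    summary["dominance_fraction"] = float(records["dominant"].mean())
    return PSAResult(records=records, seed=config.seed, config=config, summary=summary)


def ceac(result: PSAResult) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over the config's λ grid.

    For each λ, the fraction of iterations in which supplementation has
    the higher net monetary benefit.
    """
    lam = np.asarray(result.config.lambda_grid, dtype=float)
    d_cost = result.records["delta_cost"].to_numpy()  # printed orientation
    d_eff = result.records["delta_effect"].to_numpy()
    # NMB difference (intervention − comparator) = λ·Δeffect + Δcost(printed)
    frac = [(lam_i * d_eff + d_cost > 0).mean() for lam_i in lam]
    return pd.DataFrame({"lambda": lam, "acceptability": frac})


def export_scatter(result: PSAResult, path: str | Path) -> Path:
    """Write the per-iteration scatter table to CSV; byte-stable per result."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(path, index=False)
    return path


def plot_scatter(result: PSAResult, path: str | Path) -> Path:
    """Incremental cost-effectiveness plane with the WTP band's rays.

    x: ΔQALYs (intervention − comparator); y: incremental cost in the
    standard orientation (intervention − comparator), so dominant draws
    fall in the south-east quadrant.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d_eff = result.records["delta_effect"].to_numpy()
    d_cost_std = -result.records["delta_cost"].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(d_eff, d_cost_std, s=8, alpha=0.5, label="PSA iterations")
    xs = np.array([0.0, max(1e-6, float(np.max(np.abs(d_eff))) * 1.1)])
    for lam, style in zip(result.config.lambda_grid[:1] + result.config.lambda_grid[-1:], ("--", ":")):
        ax.plot(xs, lam * xs, style, color="grey", label=f"WTP {lam:g} USD/QALY")
    ax.axhline(0, color="black", lw=0.6)
    ax.axvline(0, color="black", lw=0.6)
    ax.set_xlabel("Incremental effect (QALYs)")
    ax.set_ylabel("Incremental cost (USD)")
    ax.set_title("Incremental cost-effectiveness plane")
    ax.legend(loc="best", fontsize=8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
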