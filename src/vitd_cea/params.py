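"""Model inputs for the vitamin D / T2DM cost-effectiveness model.

Houses the base-case parameter set (branch probabilities, per-person
costs in 2018 USD, one-year health-state utilities, willingness-to-pay
bounds), distribution specifications for the probabilistic sensitivity
analysis, and the Rial-denominated program-cost ledger. Moment matching
for Gamma and Beta sampling distributions lives here because the
published analysis states only a mean and standard deviation per
parameter, never a parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "DistributionSpec",
    "ParameterSet",
    "ProgramCostLedger",
    "ParameterError",
    "load_parameters",
    "base_case",
    "normalize_complement",
    "gamma_from_moments",
    "beta_from_moments",
    "total_program_cost_rial",
    "U_DM_ALTERNATIVE",
]

#: Alternative diabetic-utility scenario (EQ-5D-3L point estimate quoted in
#: the source literature); the base case uses 0.59, which is the value the
#: headline table was computed with.
U_DM_ALTERNATIVE = 0.51

_COMPLEMENT_TOL = 1e-9


class ParameterError(ValueError):
    """Raised when a configuration value violates a model invariant.

    The message always names the offending field.
    """


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one uncertain parameter.

    ``family`` is one of ``"gamma"`` (costs), ``"beta"`` (utilities and
    probabilities) or ``"fixed"`` (degenerate: the parameter is not
    varied). ``mean`` and ``sd`` are on the parameter's own scale.
    """

    family: str
    mean: float
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "beta", "fixed"):
            raise ParameterError(
                f"DistributionSpec.family must be gamma|beta|fixed, got {self.family!r}"
            )
        if self.family == "fixed":
            return
        if self.sd is None:
            raise ParameterError(f"{self.family} spec requires an sd")
        if self.family == "gamma":
            if self.mean <= 0 or self.sd <= 0:
                raise ParameterError(
                    f"gamma spec requires mean > 0 and sd > 0, got mean={self.mean}, sd={self.sd}"
                )
        else:  # beta
            if not 0 < self.mean < 1:
                raise ParameterError(f"beta spec requires 0 < mean < 1, got {self.mean}")
            if self.sd**2 >= self.mean * (1 - self.mean):
                raise ParameterError(
                    f"beta spec infeasible: sd^2 = {self.sd**2:.6g} must be < "
                    f"mean*(1-mean) = {self.mean * (1 - self.mean):.6g}"
                )


def _default_psa_specs() -> dict[str, DistributionSpec]:
    # Published uncertainty table: Gamma on both costs, Beta on diabetic
    # utility; healthy utility listed without an SD, hence held fixed.
    return {
        "c_vitd": DistributionSpec("gamma", 0.61, 0.12),
        "c_dm": DistributionSpec("gamma", 710.0, 70.0),
        "u_dm": DistributionSpec("beta", 0.59, 0.15),
        "u_healthy": DistributionSpec("fixed", 0.76),
    }


@dataclass(frozen=True)
class ParameterSet:
    """Complete input set for the decision model (one-year horizon, 2018 USD).

    Probabilities come in complementary pairs that must each sum to 1:
    vitamin D status without supplementation (``p_def_pre``/``p_suf_pre``),
    status after a nine-month 50,000 IU/month supplementation course
    (``p_def_post``/``p_suf_post``), and the implicit diabetes/no-diabetes
    split at each chance node. The post-supplementation sufficiency default
    is the normalized complement 1 − 0.172 = 0.828.
    """

    p_def_pre: float = 0.76
    p_suf_pre: float = 0.24
    p_def_post: float = 0.172
    p_suf_post: float = 0.828
    p_dm_def: float = 0.128
    p_dm_suf: float = 0.07
    c_vitd: float = 0.61
    c_dm: float = 710.0
    u_dm: float = 0.59
    u_healthy: float = 0.76
    wtp_low: float = 1032.0
    wtp_high: float = 2666.0
    psa_specs: Mapping[str, DistributionSpec] = field(default_factory=_default_psa_specs)

    _PROBS = ("p_def_pre", "p_suf_pre", "p_def_post", "p_suf_post", "p_dm_def", "p_dm_suf")
    _UTILS = ("u_dm", "u_healthy")
    _COSTS = ("c_vitd", "c_dm")

    def __post_init__(self) -> None:
        for name in self._PROBS + self._UTILS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        for name in self._COSTS:
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{name} must be non-negative, got {v}")
        for a, b in (("p_def_pre", "p_suf_pre"), ("p_def_post", "p_suf_post")):
            s = getattr(self, a) + getattr(self, b)
            if abs(s - 1.0) > _COMPLEMENT_TOL:
                raise ParameterError(f"{a} + {b} must sum to 1, got {s}")
        if self.wtp_low > self.wtp_high:
            raise ParameterError(
                f"wtp_low must be <= wtp_high, got {self.wtp_low} > {self.wtp_high}"
            )

    def with_values(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given scalar fields replaced (revalidated)."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class ProgramCostLedger:
    """Rial-denominated program cost accounting, stored as constants.

    Per-student costs of the national supplementation program: nine
    vitamin D pearls (a low/high purchase-price range) plus a fixed
    administration cost for training and supervision, all in 2018
    Iranian Rials with their published USD equivalents. The diabetes
    management cost is inflated from its 2014 figure at the 2018
    inflation rate of 9.6%. No currency arithmetic is performed here;
    the published conversions are carried as stored values.
    """

    pearl_cost_low_rial: float = 9_908.0
    pearl_cost_high_rial: float = 19_816.0
    admin_cost_rial: float = 11_049.0
    pearl_cost_low_usd: float = 0.236
    pearl_cost_high_usd: float = 0.472
    admin_cost_usd: float = 0.25
    inflation_rate_2018: float = 9.6  # percent
    dm_cost_2014_rial: float = 18_317_140.0
    dm_cost_2018_rial: float = 19_111_120.0
    dm_cost_2018_usd: float = 709.0


def normalize_complement(p: float) -> float:
    """Return 1 − p, the normalized complement of a probability.

    Used to derive the post-supplementation sufficiency probability from
    the deficiency probability when a published pair does not sum to one.
    """
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"probability must lie in [0, 1], got {p}")
    return 1.0 - p


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Match a Gamma(shape, scale) distribution to a target mean and sd.

    shape = (mean/sd)^2, scale = sd^2/mean; the resulting distribution has
    exactly the requested first two moments.
    """
    if mean <= 0 or sd <= 0:
        raise ParameterError(f"gamma moments require mean > 0 and sd > 0, got ({mean}, {sd})")
    return (mean / sd) ** 2, sd**2 / mean


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Match a Beta(alpha, beta) distribution to a target mean and sd.

    With nu = mean(1-mean)/sd^2 - 1: alpha = mean*nu, beta = (1-mean)*nu.
    Feasible only when sd^2 < mean(1-mean).
    """
    if not 0 < mean < 1:
        raise ParameterError(f"beta moments require 0 < mean < 1, got {mean}")
    var = sd**2
    if var >= mean * (1 - mean):
        raise ParameterError(
            f"beta moments infeasible: sd^2 = {var:.6g} >= mean*(1-mean) = "
            f"{mean * (1 - mean):.6g}"
        )
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def total_program_cost_rial(ledger: ProgramCostLedger) -> tuple[float, float]:
    """Total per-student program cost range in Rials: pearls + administration."""
    return (
        ledger.pearl_cost_low_rial + ledger.admin_cost_rial,
        ledger.pearl_cost_high_rial + ledger.admin_cost_rial,
    )


def base_case() -> ParameterSet:
    """The bundled base-case parameter set (the headline analysis)."""
    return ParameterSet()


_SCALAR_FIELDS = {
    f.name for f in fields(ParameterSet) if f.name != "psa_specs"
}


def _parse_spec(name: str, raw: object) -> DistributionSpec:
    if not isinstance(raw, Mapping):
        raise ParameterError(f"psa.{name} must be a mapping with family/mean/sd")
    unknown = set(raw) - {"family", "mean", "sd"}
    if unknown:
        raise ParameterError(f"psa.{name} has unknown keys: {sorted(unknown)}")
    try:
        family = str(raw["family"])
        mean = float(raw["mean"])
    except KeyError as exc:
        raise ParameterError(f"psa.{name} missing required key {exc.args[0]!r}") from None
    sd = raw.get("sd")
    return DistributionSpec(family, mean, None if sd is None else float(sd))


def load_parameters(config_path: str | Path | None = None) -> ParameterSet:
    """Load a ParameterSet from a YAML config, falling back to the base case.

    The config is a flat mapping of ParameterSet field names to values,
    with an optional ``psa`` block mapping parameter names to
    ``{family, mean, sd}``. Unspecified fields take their base-case
    defaults; an empty or missing-key config therefore yields the full
    bundled base case. Invariant violations are reported with the
    offending field name.
    """
    if config_path is None:
        with resources.files("vitd_cea.data").joinpath("vitd_t2dm_base.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        path = Path(config_path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ParameterError("config must be a mapping of parameter names to values")

    overrides: dict[str, object] = {}
    for key, value in raw.items():
        if key == "psa":
            specs = dict(_default_psa_specs())
            if value is not None:
                if not isinstance(value, Mapping):
                    raise ParameterError("psa block must be a mapping")
                for pname, spec_raw in value.items():
                    specs[str(pname)] = _parse_spec(str(pname), spec_raw)
            overrides["psa_specs"] = specs
        elif key in _SCALAR_FIELDS:
            try:
                overrides[key] = float(value)
            except (TypeError, ValueError):
                raise ParameterError(f"{key} must be numeric, got {value!r}") from None
        else:
            raise ParameterError(f"unknown config key: {key!r}")
    if math.nan in overrides.values():
        raise ParameterError("NaN is not a valid parameter value")
    return ParameterSet(**overrides)  # type: ignore[arg-type]
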