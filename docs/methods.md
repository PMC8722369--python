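# Methods

## Model structure and assumptions

The model is a single-period (one-year) decision tree with two
strategies: no intervention, and a nine-month vitamin D
supplementation course for adolescents. Each arm passes through two
chance nodes — vitamin D status (deficient vs. sufficient, dichotomized
at serum 25(OH)D 30 ng/mL) and type 2 diabetes onset conditional on
status — ending in eight terminal (cost, QALY) payoffs. Rollback is
exact: all root-to-leaf paths are enumerated and probability-weighted,
so there is no sampling error in the base case. With a one-year horizon
a person's QALYs equal their health-state utility weight, and no
discounting is applied (nothing accrues beyond year one).

Key structural assumptions, inherited from the source analysis:

- Diabetes risk depends on vitamin D status only, identically in both
  arms (supplementation acts purely by shifting the status mixture).
- The supplementation arm is fully covered: every member incurs the
  program cost and the post-supplementation status probabilities.
- Costs and utilities are deterministic given the terminal state; all
  heterogeneity is carried by the two Bernoulli splits.

## Parameters

| Parameter | Meaning | Base | PSA distribution |
|---|---|---|---|
| `p_def_pre` / `p_suf_pre` | status without supplementation | 0.76 / 0.24 | fixed |
| `p_def_post` / `p_suf_post` | status after supplementation | 0.172 / 0.828 | fixed |
| `p_dm_def`, `p_dm_suf` | T2DM risk given status | 0.128, 0.07 | fixed |
| `c_vitd` | program cost (USD/person/yr) | 0.61 | Gamma, sd 0.12 |
| `c_dm` | T2DM management cost (USD/person/yr, 2018) | 710 | Gamma, sd 70 |
| `u_dm` | diabetic utility (QALY weight) | 0.59 | Beta, sd 0.15 |
| `u_healthy` | healthy utility | 0.76 | fixed (no sd published) |
| `wtp_low`–`wtp_high` | WTP band (USD/QALY) | 1032–2666 | — |

The source tables are internally inconsistent in four places; the
bundled base case resolves each in the direction that exactly
reproduces the published headline table, and the package treats that
resolution as its canonical input:

- The post-supplementation status pair is printed as 17.2% / 87.2%
  (sum 104.4%). We use the normalized complement 0.828; the tree
  builder also offers a `normalize=True` mode that rescales a raw
  inconsistent pair.
- The diabetic utility appears as both 0.51 ± 0.24 and 0.59 ± 0.15; the
  base case uses 0.59 (sd 0.15), with 0.51 retained as the named
  alternative scenario `U_DM_ALTERNATIVE`.
- The T2DM cost appears as both 709 and 710 USD; the base case uses 710.
- The program cost appears as a 0.499–0.72 USD range and as 0.61 ±
  0.12; the base case uses 0.61, and the range endpoints are natural
  one-way scenario overrides (`c_vitd: 0.72` in a config).

Rial-denominated program accounting (pearl purchase 9,908–19,816 Rials,
administration 11,049 Rials, the 2014→2018 inflation adjustment of the
diabetes cost at 9.6%) is stored as constants in `ProgramCostLedger`;
the only arithmetic performed on it is the per-student total
(20,957–30,865 Rials). No currency conversion is computed, because the
published Rial→USD conversions are not mutually consistent and the USD
model inputs are taken directly from the published tables.

## Incremental analysis and decision rules

`incremental_analysis` reports both ICER conventions. The standard
ratio (C_int − C_comp)/(E_int − E_comp) is replaced by a dominance
verdict when the intervention is strictly cheaper and more effective —
which the base case is — because a ratio of a negative cost difference
to a positive effect difference invites misreading. The
savings-per-QALY ratio (C_comp − C_int)/(E_int − E_comp) = 4071.26
USD/QALY is exposed as `icer_as_printed` since that is the convention
the source analysis reports (4071.25 after its intermediate rounding).
Decisions against the WTP band use net monetary benefit, NMB = λ·E − C,
evaluated at the band endpoints; ties go to the comparator, a
deliberate conservative bias against adopting the intervention. The
threshold comparison "ICER vs. band" is ill-defined for a dominant
strategy, which is why the NMB rule is the package's decision surface.

## Probabilistic sensitivity analysis

Only the parameters with published uncertainty are varied: `c_vitd`
and `c_dm` (Gamma) and `u_dm` (Beta), with distributions matched to the
published mean and sd by the method of moments (Gamma: shape =
(m/s)², scale = s²/m; Beta: ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν).
The healthy utility is listed without an sd and is held fixed; tree
probabilities are not varied (a Beta spec can be attached through the
config's `psa` block as an extension, off by default). Draws are not
truncated: Gamma is non-negative and Beta lives on [0, 1] by
construction. One `numpy.random.default_rng(seed)` generator drives the
run, consumed in the fixed order `c_vitd, c_dm, u_dm` per iteration, so
a `PSAResult` is a pure function of (parameters, config) and re-runs
are bit-identical.

The default run uses 1000 iterations, matching the published analysis;
at 1000 iterations, 100% acceptability at both band endpoints is the
expected outcome, since flipping the NMB sign at λ = 1032 requires a
joint draw roughly 4–5 sd from the means. The summary exposes both the
NMB acceptability per λ and the strict-dominance fraction, because a
"100% preferred" figure can mean either; they differ (dominance is
typically ~86% here) exactly in the iterations where the sampled
diabetic utility exceeds 0.76, making the effect difference negative
while the cost saving still decides in favour of supplementation. For
the same reason the acceptability curve is only guaranteed monotone in
λ while every iteration has a positive effect difference; far above the
band (λ ≳ 5000) acceptability can dip below 1.

## Cohort microsimulation (synthetic data and oracle)

`simulate_cohort` draws individuals through the exact stochastic
structure the tree assumes: status ~ Bernoulli(arm's deficiency
probability), diabetes ~ Bernoulli(risk given status), then the
deterministic payoff. It emulates the branch structure of the modelled
population only — no adherence, dropout, seasonality, dose–response,
or demographic covariates, none of which have published parameters — so
passing oracle tests validates the engine's arithmetic, not the model's
external realism. Per-arm empirical means converge to the rollback
values at rate 1/√n; the test suite checks agreement within 4 standard
errors at n = 10⁶ per arm.

The published 500-per-arm illustration reports diabetic counts of 57
(no intervention) and 39 (supplemented) as if deterministic. These are
rounded expectations: 500 × 0.11408 = 57.04 → 57, but
500 × 0.079976 = 39.99 → 40 under every reconstruction of the inputs.
`expected_counts` (round-half-up of n·P) therefore returns 57 and 40;
the 39 is flagged as irreproducible rather than forced.

## Numerical choices

- Chance-node probabilities must sum to 1 within 1e-9 (strict mode);
  `normalize=True` rescales instead. Complement pairs in `ParameterSet`
  are validated at the same tolerance.
- Costs and effects are carried at full double precision; rounding
  happens only in report rendering, mirroring the source table's
  printing (4 dp for the comparator cost, 5 dp for the intervention
  cost and effects, 4 dp for the incremental effect, 2 dp for the
  ratio).
- Beta moment matching requires s² < m(1−m); infeasible specs raise
  with the offending values rather than clipping.
- Degenerate PSA (all specs `fixed`) consumes no randomness and
  reproduces the base case exactly in every iteration, which the tests
  use as an oracle identity.

## Problem sizes

The base case is closed-form (8 paths). Default analysis sizes are 1000
PSA iterations and 500 people per arm, the published study conditions;
the convergence oracle uses 10⁵–10⁶ per arm, chosen so that 4-standard-
error bands are tight enough (≲ 0.9 USD on cost at 10⁶) to catch any
real rollback defect while the whole suite stays fast.

## Known limitations

- One-year horizon with no extrapolation; lifetime consequences of
  T2DM are outside the model.
- Parameter uncertainty is treated as independent across the three
  varied parameters (no correlation structure is published).
- Coverage/logistics of the national program are not modelled; the
  supplementation arm is fully covered by assumption.
- The stochastic count check uses a 99% binomial band with a
  multiplicity allowance (at most one excursion in 20 seeds), the
  coverage-consistent reading of a per-seed band check.
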