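# Methods

## Model and assumptions

The package evaluates counterfactual treatment-uptake scenarios for a
diseased population of `N` eligible patients observed over a fixed risk
window (e.g. one year after diagnosis). Receipt of the `k` treatments is a
random binary vector **T** = (T₁, …, T_k) following a multivariate Bernoulli
distribution; the uptake of treatment *i* is its marginal mean
uᵢ = P(Tᵢ = 1). Death within the window is Bernoulli with a conditional risk
given by the multiplicative no-interaction (Mant–Hicks) model

    R(t) = cf · ∏ᵢ RRᵢ^tᵢ,

where `cf` is the case fatality rate under no treatment and RRᵢ the
per-treatment relative risk (RRRᵢ = 1 − RRᵢ). Everything downstream follows
from one identity: the population-average ("marginal") risk equals
`cf · PGF_T(RR₁, …, RR_k)`, with `PGF_T(x) = E[∏ xᵢ^Tᵢ]` the probability
generating function of **T**. A counterfactual scenario changes only the law
of **T** (baseline → target); `N`, `cf` and the RRᵢ are held fixed.

Two estimators of the change in deaths prevented or postponed (ΔDPP) are
implemented:

* **classic**: `ΔDPP = cf · N · [PGF_b(RR) − PGF_t(RR)]`, which requires
  `cf`;
* **PIF-based**: `PIF = [PGF_b(RR) − PGF_t(RR)] / PGF_b(RR)` and
  `ΔDPP = PIF · d`, which requires only the observed baseline death count
  `d` — `cf` cancels from the ratio.

Since `E[d] = N · cf · PGF_b(RR)`, the two coincide exactly when the true
`cf` is used; when the observed treated-population rate
`cf̃ = cf · PGF_b(RR)` is substituted (the common practice this package
quantifies), the classic single-treatment answer is scaled by
`1 − u_b·RRR`, i.e. underestimated by the factor `u_b·RRR`. Stratified
populations aggregate as `ΔDPP = Σⱼ PIFⱼ · dⱼ`, and the percent mortality
reduction is `100 · ΔDPP / Σⱼ dⱼ`.

Key assumptions, inherited from the model: no interaction between treatment
effects (multiplicative risks), no confounding between uptake and risk, and
an eligible population and relative risks unchanged between baseline and
target. None of these are testable inside the package; they are scenario
premises.

## Uptake distributions

Three interchangeable parameterisations are accepted, all normalised to a
dense 2ᵏ outcome table internally:

* **independent** — marginal uptakes only; the table is the product law and
  the PGF has the closed form `∏ᵢ(1 − uᵢ(1 − xᵢ))`;
* **joint_table** — explicit outcome probabilities (validated: non-negative,
  summing to 1 within 1e-9);
* **moments** — ordinary joint moments `m_S = E[∏_{i∈S} Tᵢ]` (singletons are
  the marginal uptakes). The unique implied table follows by
  inclusion–exclusion, `p(T_A=1, T_{A^c}=0) = Σ_{B⊆A^c} (−1)^|B| m_{A∪B}`;
  an implied negative cell means the moment set is infeasible and is
  reported by cell. Higher-order moments omitted by the user default to the
  independence product of their singletons, with a logged notice.

Outcomes are indexed with treatment 1 as the least-significant bit;
bit-string keys in scenario files read left-to-right as treatments 1…k.
`k` is capped at 16 for tabular forms (table size 2ᵏ); beyond the cap only
the independent factorised form is representable.

## Numerical choices

* Probability normalisation, round-trip and reference-level checks use an
  absolute tolerance of 1e-9; scenario parameters are treated as exact, so
  the tolerance only absorbs float noise.
* ΔDPP and PIF values are full-precision floats everywhere in the library;
  rounding happens only in the text report (2 decimals for DPP and percents,
  5 for PIF) using decimal half-up rounding after pre-quantising at 1e-12,
  so a value like 28.965 prints as 28.97 rather than falling foul of binary
  representation noise.
* Signed results are returned, not clamped: a falling uptake yields a
  negative ΔDPP/PIF.
* Degenerate guards raise informative `ValueError`s: PIF with a zero
  baseline survival factor, zero baseline PGF, zero classic ΔDPP in the
  percent-difference convention, zero baseline deaths in the empirical PIF.
* `rr = 0` (risk-eliminating treatment) is allowed; `rr > 1` (harmful) is
  allowed but emits `HarmfulTreatmentWarning`, since the multiplicative
  relative-benefit of a combination then leaves [0, 1].

## Design choices where the design was open

* **cf interpretation.** A supplied case fatality rate is ambiguous in
  practice, so scenarios must declare it: `"biased"` (default) means it is
  the observed rate under baseline uptake and the classic path uses it
  as-is — reproducing the biased practice being studied; `"true"` means it
  is the no-treatment rate. When no `cf` is given the classic path estimates
  it as deaths/N under the same flag (deconvolved by `PGF_b(RR)` when
  declared true). When both `cf` and deaths are given and disagree by more
  than 1% relative, a warning is logged; deaths drive the PIF path and `cf`
  the classic path.
* **Missing deaths** are imputed as `round(N·cf·PGF_b(RR))` (true flag) or
  `round(N·cf)` (biased flag), with a logged notice.
* **Per-treatment attribution rows** change one treatment's marginal uptake
  at a time, holding the others at baseline, via the single-treatment
  formulas; this is exact under independent uptakes and a marginal
  approximation for dependent joint tables. Attribution rows are reported
  for inspection but never summed into totals — summing per-treatment
  effects overstates the joint effect — so totals aggregate joint rows only.
* **Percent difference between methods** is
  `100·(ΔDPP_PIF − ΔDPP_classic)/ΔDPP_classic`.
* Scenario files are fail-closed: versioned schema, unknown keys rejected,
  validation errors carry field paths.

## Cohort simulator

`simulate_cohort` draws each individual's treatment pattern from the joint
uptake law and then death from a Bernoulli with the multiplicative cell
risk — one draw per person over the risk window, with no time-to-event
structure, matching the risk-within-period framing of the analytic
formulas. Seeds are mandatory; identical seeds reproduce cohorts exactly.
The simulator emulates exactly the generating model the estimators assume
(multiplicative effects, uptake independent of risk); it does not emulate
interaction, confounding, covariate-dependent uptake or censoring, so
passing Monte-Carlo checks validate the arithmetic and the distributional
machinery, not the model's fit to any real registry. Validation checks use
10⁵–10⁶ individuals per arm with 3-standard-error acceptance bands
(delta-method standard error for the empirical PIF ratio), sizes at which
the checks complete in seconds while keeping the false-failure rate well
under 1%. The random scenario generator draws k ≤ 4 treatments with
relative risks in (0.05, 1], uptake laws either independent or
Dirichlet-random joint tables (allowing dependence), and true case fatality
rates in (0.02, 0.5) — ranges chosen to span realistic cardiovascular-style
scenarios while exercising the dependent-uptake code paths.

## Known limitations

* No sampling uncertainty: all inputs are treated as true parameters; no
  confidence intervals are produced.
* Binary treatments and categorical exposures only; no continuous-exposure
  PIF.
* No interaction or "chain-reaction" risk models; the multiplicative
  assumption is hard-coded.
* Estimating joint uptake laws from individual-level registry data is out of
  scope (the simulator generates cohorts; it does not fit them).
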