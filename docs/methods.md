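# Methods

## The model

The flexible parametric proportional-hazards model places a restricted
(natural) cubic spline on the log cumulative hazard in log time:

    ln H(t | arm) = s(ln t; γ) + β·arm,      S(t | arm) = exp(−H(t | arm)),

with `s(x; γ) = γ₀ + γ₁x + Σⱼ γ_{j+1} v_j(x)` and
`v_j(x) = (x−k_j)₊³ − λ_j (x−k_min)₊³ − (1−λ_j)(x−k_max)₊³`,
`λ_j = (k_max−k_j)/(k_max−k_min)`. The basis is linear beyond the boundary
knots, so extrapolation is a straight line in log time. With no internal
knots the family is exactly Weibull (`γ₁ = 1` exponential); with the
default two internal knots it is flexible enough to track most smooth
baseline hazards while the arm effect `β` stays a single log hazard ratio.

Knots: boundary knots at the minimum and maximum log *uncensored* time,
internal knots at equally spaced quantiles of the log uncensored times
(33%/67% for two knots), using the linear order-statistic interpolation
convention for quantiles.

The log likelihood with right censoring is

    ℓ(γ, β) = Σ_events [ ln s′(ln tᵢ; γ) − ln tᵢ + ηᵢ ] − Σ_all exp(ηᵢ),
    ηᵢ = s(ln tᵢ; γ) + β·armᵢ,

valid only while `s′(ln tᵢ) > 0` at every event time (a cumulative hazard
must be non-decreasing). During optimisation that constraint is enforced
by a smooth quadratic barrier rather than a hard bound, keeping the
objective differentiable; the public `log_likelihood` returns −∞ outside
the feasible region.

Fitting starts from the exponential solution
(`γ = (ln(events / total follow-up), 1, 0, …)`, `β = 0`) and uses a
trust-region Newton method with the analytic gradient and Hessian of ℓ,
with up to three deterministically jittered restarts before a
`ConvergenceError` is raised (the fitter fails loudly; the study harness
treats a failure as a repetition to discard and replace). The parameter
covariance is the inverse of the analytic observed information at the
optimum — exact second derivatives rather than finite differences, which
removes one layer of numerical noise from every delta-method standard
error downstream.

## Summary measures and tests

* HR: `exp(β)`, standard error on the log scale directly from the
  covariance; Wald interval `exp(β ∓ z·se)`.
* DRMST(τ): `∫₀^τ [S(t|1) − S(t|0)] dt`, evaluated by 64-point
  Gauss–Legendre quadrature after the substitution `t = τu²`. The
  substitution matters: near `t = 0` the survival difference behaves like
  `t^γ₁`, and for fitted slopes below 1 plain Gauss–Legendre on `[0, τ]`
  only reaches ~1e-7 accuracy, while the substituted rule is below 3e-9
  against an adaptive-quadrature oracle across random parameter draws.
  The order is fixed for bit-reproducibility.
* DS(τ): `S(τ|1) − S(τ|0)` from the fitted curves.
* Delta method: gradients of DRMST and DS with respect to `(γ, β)` by
  central finite differences with per-parameter step
  `max(1e-5, 1e-4·|θⱼ|)`; variance `g'ᵀ V g'`. Wald tests are performed on
  the log scale for HR and the identity scale for DRMST/DS. The identity
  scale is the conventional choice for these differences and is what makes
  the small-sample type-I inflation of the model-based DS test at very low
  survival reproducible; a bootstrap SE utility (`bootstrap_drmst_se`) is
  provided for cross-checking but is not on the main path.

The one-sided non-inferiority test at level α rejects when

* HR: `(ln m − ln ĤR)/se > z_{1−α}` (margin `m ≥ 1`),
* DRMST/DS: `(estimate + m)/se > z_{1−α}` (margin `m ≥ 0`, stored as a
  positive tolerable loss),

equivalently when the margin-side bound of the one-sided `1−α` interval is
strictly inside the non-inferiority region. `m = 1` (HR) or `m = 0`
(differences) gives a superiority test. Confidence intervals are reported
two-sided at `1−2α` so their relevant bound coincides with the test.

## Non-parametric estimators

Kaplan–Meier with the Greenwood variance; ties between censorings and
events at the same time are resolved events-first. The RMST is the area
under the step function on `[0, τ]` with the standard product-limit
variance `Σ_{tᵢ≤τ} A(tᵢ)² dᵢ/(nᵢ(nᵢ−dᵢ))`, `A(tᵢ) = ∫_{tᵢ}^τ Ŝ(u)du`
(squared forward areas times Greenwood increments); RMST to τ is refused
as unidentifiable if follow-up ends before τ while the curve is still
positive. DS uses simple binomial proportions whenever every subject's
τ-status is known — always true in the simulated designs, where minimum
potential follow-up equals τ — and falls back to Kaplan–Meier survival at
τ with Greenwood variances otherwise (logging a notice). A subject with an
event exactly at τ counts as a failure; one censored exactly at τ counts
as a survivor. None of these estimators uses information beyond τ, so
censoring the data at τ first changes nothing (a property the tests
assert exactly).

## Margin matching

Under an exponential control arm with `S_C(τ) = s` and a
proportional-hazards boundary (research hazard = `m_HR` × control):

    λ_C = −ln(s)/τ,   λ_A = m_HR·λ_C,
    DS margin    = s − s^{m_HR},
    DRMST margin = (1 − e^{−λ_C τ})/λ_C − (1 − e^{−λ_A τ})/λ_A,

computed with `expm1` so the restricted means stay accurate down to
vanishing hazards. Both losses are strictly increasing in `m_HR`, so the
inverse mapping (back-calculating an HR margin from a DS or DRMST margin)
is monotone root-finding on the log-HR scale, with round-trip accuracy
~1e-10. `match_margins_curve` accepts an arbitrary control survival
function and evaluates the same two integrals numerically. Exact closed
forms for the published margin tables mostly agree to one unit in the last
printed digit; the PATCH cohort margins as printed are mutually
inconsistent at that precision (the printed HR margins are themselves
rounded back-calculations), and this package always reports the
closed-form value at full precision.

## The simulator

What it emulates: two-arm trials with uniform accrual over
`accrual_years`, exponential event times (control rate fixed by the
design's survival at τ, research rate scaled by the true HR), and
administrative censoring at `total_years` from the start of recruitment —
so censoring time is uniform on `(total−accrual, total)` and, in the
default 3/6-year design, no subject is censored before the 3-year horizon.
Allocation ratios other than 1:1 round the research arm to the nearest
integer. The PATCH cohorts are preset designs: 83% / 66% control 3-year
survival, total sizes 1345 / 1500 split 1.08:1 (698/647 and 779/721).

What it does not emulate: dropout, non-adherence, delayed entry, covariate
effects, and — deliberately — non-proportional hazards or non-exponential
baselines in the preset scenarios. Passing tests therefore demonstrate
correct operating characteristics *under proportional hazards with an
exponential baseline*; they say nothing about robustness to
non-proportionality, where the model-based DRMST/DS estimators should not
be used uncritically (the generic design hook accepts other baselines, but
none of the packaged scenarios exercise them).

Randomness: every repetition draws its generator from
`SeedSequence((master_seed, scenario_key, rep_index))`, so repetitions are
individually reproducible and replaceable; replacement repetitions use a
reserved index stream (offset 10⁹) so that a convergence failure in one
repetition never shifts the seeds of the others.

## The study harness

Each repetition simulates one trial and analyses it three ways: the
non-parametric estimators on data censored at τ; the flexible parametric
model on data censored at τ; and the same model on all data to the
analysis date (under proportional hazards, events after τ still sharpen
estimates at τ — the source of the "all data" power gain). Power rows
generate under equal arms (true HR = 1); type-I rows generate at the
margin (true HR = margin), the boundary of the null — the convention
validated by the Schoenfeld events approximation
`Φ(√(E/4)·|ln m_HR| − z_{1−α})`, which lands within ~1 point of the
simulated HR-test cells and also confirms that the grid's sample sizes are
per arm. Rejection proportions carry Monte-Carlo standard errors
`√(p(1−p)/n_reps)`. Non-convergent repetitions are discarded and replaced
(counted, and warned about above a 1% rate); cells with rejection rate
above 3% are flagged in the output table as an annotation only.

Problem sizes: the packaged acceptance runs and tests use 2,000
repetitions per scenario, giving MCSEs around 0.8 points for power near
85% and 0.35 points for a 2.5% type-I rate; comparisons are made within
three MCSEs. The full 12-scenario grid at any replication count is
available through `run_table` / `nisurv run-study`.

## Known limitations

* Proportional hazards is assumed by the model-based estimators; no
  time-dependent effects or average-HR weighting.
* Delta-method standard errors for DRMST and DS are first-order and can be
  slightly anti-conservative in small samples with very low survival (the
  harness reproduces this as type-I inflation of the model-based DS test
  around 20% survival).
* The margin-matching reference is a point match at the design's control
  rate, not a full non-inferiority frontier across control rates.
* No support for left truncation, interval censoring, competing risks, or
  covariates beyond the randomised arm.
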