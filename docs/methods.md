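# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical choices and the known limitations of `mwtprisk`.

## Latent-WTP model and likelihood

Each household record carries two binary purchase intentions: the parent's
decision to buy a risk-reducing vaccine for herself and one for her child,
both at the same randomly assigned annual price Q. Stated willingness to
pay is latent,

    W̃_i = α_i + γ_i X_i + σ_i ε_i,     i ∈ {p, k},

where X_i is either the proportionate risk reduction Δ_i (decimal fraction
of baseline risk eliminated) or the absolute reduction Δ_i·R_i in chances
in 100, α_i absorbs systematic misstatement of intentions, and (ε_p, ε_k)
are standard bivariate normal with correlation ρ. Only 1{W̃_i ≥ Q} is
observed. Subtracting Q, mean-centering every regressor on the estimation
sample and dividing by σ_i yields a two-equation probit whose price
coefficient is −1/σ_i; the model is estimated by full maximum likelihood
over (β_p, β_k, ρ) with log-likelihood

    ℓ = Σ_h log Φ₂(s_p x_p′β_p, s_k x_k′β_k, s_p s_k ρ),   s_i = 2·buy_i − 1.

Mean-centering makes the constant the mean of the standardized net latent
WTP and, importantly, makes all estimates invariant to location shifts of
the price (verified by test). Centering always uses the estimation
sample's own means, so subsample fits re-center automatically.

Dollar scale is recovered by dividing any risk coefficient by the negative
price coefficient. For the proportionate specification this gives γ ($ per
unit Δ); γ/100 is the MWTP per percentage point, and MWTP for a
1-chance-in-100 reduction at baseline risk R is γ/R, a rectangular
hyperbola. The absolute specification's ω coefficient divided by
−coef(q) is directly the (constant) MWTP per chance in 100.

### Numerical implementation

- **Bivariate normal CDF.** Φ₂ is computed from the Owen's-T decomposition
  (two `scipy.special.owens_t` calls plus univariate CDFs), vectorised and
  accurate to ~1e-14; arguments exactly zero are nudged by 1e-15 so the
  T-function arguments stay defined, and the half-correction term is keyed
  on the signs of the arguments rather than their product (which can
  underflow). `scipy.stats.multivariate_normal.cdf` serves as an
  independent oracle in the tests only — it is far too slow for the MLE
  inner loop.
- **Optimization.** Starting values are per-equation univariate probit
  fits by Newton scoring with ρ started at 0; ρ is transformed by the
  inverse hyperbolic tangent so the search is unconstrained. BFGS with the
  analytic score is followed by a Newton polish on a finite-difference
  Hessian; convergence requires a gradient sup-norm below 1e-6. Divergence,
  separation, or ρ at the boundary are reported via the `converged` flag
  and `message`, never silently.
- **Covariance.** Inverse of the central-finite-difference Hessian of the
  negative log-likelihood in the reported (coefficients, ρ)
  parameterization, step 1e-5·(1+|θ|), symmetrized. Plain inverse-Hessian
  standard errors; no robust or clustered variants.
- **Inference.** The LR test is 2·(ℓ_full − ℓ_restricted) against χ²; a
  negative statistic beyond 1e-6 raises (optimization failure). The Wald
  test of equal parent/child dollar slopes uses the delta method on
  g = γ_p/(−q_p) − γ_k/(−q_k) and refuses to run when either price
  coefficient has |t| < 2 (unidentified ratio).
- **Pruning.** "Disregard insignificant coefficients" is implemented as a
  post-fit rule (two-sided p ≥ 0.05 by default) applied only when building
  MWTP curves, never inside the likelihood. A hyperbola is refused when a
  risk-bin interaction survives pruning, since a surviving interaction
  contradicts risk-independence of the proportionate-reduction MWTP.

## Synthetic data generator

The generator emulates the study conditions the estimator assumes:

- **Design.** Δ_p uniform on {0.1, 0.7}; price uniform on
  {10, 20, 40, 80, 160} and common to both vaccines in a household; Δ_k
  uniform on the child levels *exceeding* the household's Δ_p (the child's
  reduction always exceeds the parent's by design), so
  P(Δ_k = 0.8) = 3/4 and E[Δ_k] = 0.65.
- **Baseline risks.** Revised perceived risks on [0, 100] are scaled Beta
  distributions moment-matched to (mean 33.59, SD 20.14) for parents and
  (24.30, 15.40) for children. The pooled SDs are not published; these
  values are the closest published gender-specific revised-risk SDs. An
  infeasible (mean, SD) pair raises; SD = 0 degenerates to a point mass.
  The parent–child joint distribution is unpublished; a Gaussian copula
  with correlation 0.5 (a moderate familial association) is the default
  and is configurable.
- **Latent WTP truth.** Dollar-scale defaults are derived from the
  published proportionate-specification estimates by inverting the
  normalization: σ_i = −1/coef(q), γ_i = coef(δ_i)·σ_i, and α_i chosen so
  the implied centered constant matches the published constant at the
  design means (Δ̄_p = 0.4, Δ̄_k = 0.65, Q̄ = 62); ρ = 0.8912.
- **Misreport layer.** The "uncertain purchaser" recoding is modeled as an
  optional layer flipping each positive intention to 0 independently with
  a configurable probability (default 0: the estimator sees final
  indicators). Ties W̃ = Q count as purchases (measure zero).
- **Seeding.** One master seed spawns independent child streams (design,
  risks, errors, covariates, misreport) via `numpy` SeedSequence; identical
  seeds give byte-identical CSVs.

What the generator does *not* emulate: the risk-grid elicitation and
belief-updating process behind the perceived risks, panel recruitment and
nonresponse, any dependence of purchase errors on covariates, or
misreporting correlated across the two vaccines. Passing tests therefore
validate the estimator and arithmetic under the model's own assumptions,
not robustness to their violation in field data.

A note on independence: with ρ = 0 the two purchase indicators are
independent *conditional on the design*, but not marginally — the
household-common price is a shared shock that induces positive association
by itself. Tests of the ρ = 0 case therefore hold the price fixed.

## Risk bins and curve forms

Published bin definitions are integer ranges (parents 0–20 / 21–30 /
31–46 / 47–100; children 0–14 / 15–20 / 21–30 / 31–100); continuous
generated risks are cut at the midpoints 20.5/30.5/46.5 (parents) and
14.5/20.5/30.5 (children), with the highest bin as the omitted reference
and bins closed on the right at each cut. Step curves come from the
absolute specification with ω and q interacted with bin indicators;
piecewise-linear curves come from ω interacted with hinge functions of
baseline risk at the bin edges, which makes MWTP continuous and piecewise
linear in R. The published step and piecewise-linear MWTP values are also
available as reference curves (`reference_step_curve`,
`reference_piecewise_curve`) for examples and tests, because the underlying
interaction coefficients of those specifications are not published.

Welfare integrals use exact closed forms per curve form (level × width;
scale × log ratio; piecewise-constant and trapezoid sums) and are
cross-checked against adaptive quadrature to 1e-6 relative.

## Expected-utility theory module

Utility is CRRA with state-specific level shifts and slope multipliers,
U_ij(C) = a_ij + m_ij·u(C), u(C) = C^(1−η)/(1−η) (ln C at η = 1) — the
smallest family exhibiting both orderings of state-dependent marginal
utility. η is this package's curvature symbol. The risk technology is
exponential, R(X, G) = R₀·exp(−β_X X − β_G G − β_XG X G), which can
produce either sign of the cross partial R^XG; a perfect-substitute
variant R₀·exp(−β_X(X + φG)) is included. The two first-order conditions
are solved by alternating Brent root finds (Gauss–Seidel, tolerance 1e-12
on X, FOC residuals checked to 1e-8); corners are flagged, not hidden.
MWTP* = −1/R^X at the optimum, and an independent evaluation of the
exogenous-risk MWTP formula at the optimal (R, consumption) reproduces it
to 1e-5 — the marginal-value-equals-marginal-cost identity.

One limiting-behavior caveat: making risk reduction very cheap (large β_X)
drives optimal risk toward zero but does *not* drive MWTP* toward zero —
at an interior optimum MWTP* equals the marginal *value* of risk
reduction, which converges to the bounded willingness (utility gap over
marginal expected utility) at near-zero risk. Similarly, the exact
full-offset result dX/dG = −φ for perfect substitutes holds only when
income effects are absent (linear consumption utility with
state-independent slopes); with curvature the offset is partial.

## Simulation study sizes

The Monte-Carlo studies use the study's own design throughout: n = 2211
households per replicate. Parameter recovery uses 200 replicates and
checks that mean estimates of (γ/σ, −1/σ, ρ) fall within 2 Monte-Carlo
SEs of the generating values. Size calibration of the 12-df LR test and
the Wald equality test uses 500 replicates each under their simulated
nulls, with an acceptance band of 5% ± 2% (≈ ±2 binomial SEs). The
end-to-end dollar-slope (γ) recovery check allows an additional 2% on top
of 2 MC SEs because γ̂ is a ratio of estimates and carries a finite-sample
Jensen bias of order (SE_q/q)² ≈ 1.5–2% at n = 2211 that no replicate
count removes. Consistency is checked by comparing relative RMSE at
n = 500 versus n = 8000.

## Known limitations

- No sampling weights, no random effects beyond the α_i constant, no
  robust/clustered standard errors, no semiparametric estimators.
- Coefficients on ω (absolute reduction) and on the perceived-risk bin
  indicators may be inconsistent in field data because perceived risk can
  correlate with the disturbance; the package estimates them as specified
  and leaves the interpretation to the analyst.
- Curves are defined on baseline risk in (0, 100] and are not
  extrapolated below R = 1 in reporting grids.
- Welfare totals are point estimates; no uncertainty propagation or
  population aggregation.
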