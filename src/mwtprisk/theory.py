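"""Two-person, two-state expected-utility model of morbidity-risk valuation.

A parent values reductions in her own and her child's probability of illness.
With exogenous risks (R_p, R_k) her expected utility is

    EU = (1-R_p) EU_H. + R_p EU_S.,     EU_H. = (1-R_k) U_HH + R_k U_HS,
                                        EU_S. = (1-R_k) U_SH + R_k U_SS,

and MWTP for a marginal reduction in her own risk is the expected utility gap
between healthy and sick divided by the marginal expected utility of income.
Whether that MWTP rises or falls with baseline risk depends on the
state-dependence of the marginal utility of income ("sick anyway" effect).

With endogenous risk, R_i = R_i(X_i, G) is produced by private expenditure X_i
(unit price) and exogenous public expenditure G.  At an interior optimum
first-order conditions eliminate utility terms and MWTP* equals the marginal
cost of risk reduction, -1/R_i^X, which ties the ratio of parent and child
MWTPs to the ratio of marginal products (and, under equal-proportionate-
reduction technologies, to the inverse ratio of baseline risks).

The utility family here is CRRA with state-specific level and slope
multipliers, U_ij(C) = a_ij + m_ij * u(C) with u(C) = C^(1-eta)/(1-eta)
(ln C at eta = 1); the risk technology is exponential,
R(X, G) = R0 exp(-bx X - bg G - bxg X G), or the perfect-substitute variant
R(X, G) = R0 exp(-bx (X + phi G)).  These are the smallest parametric
families exhibiting both orderings of state-dependent marginal utility and
both signs of the cross partial R^XG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

STATES = ("HH", "SH", "HS", "SS")  # parent state first, child state second


# ---------------------------------------------------------------------------
# Utility specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UtilitySpec:
    """CRRA utility with state-dependent level shifts and slope multipliers.

    U_ij(C) = levels[ij] + slopes[ij] * u(C), u CRRA with curvature ``eta``.
    ``income`` is the endowment I in dollars; consumption is I minus private
    risk expenditure.  Slope multipliers must be positive so U' > 0; CRRA
    guarantees U'' <= 0 for eta >= 0.
    """

    income: float
    eta: float = 1.0
    levels: dict = field(default_factory=lambda: {s: 0.0 for s in STATES})
    slopes: dict = field(default_factory=lambda: {s: 1.0 for s in STATES})

    def __post_init__(self) -> None:
        if self.income <= 0:
            raise ValueError("income must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative for concavity")
        for s in STATES:
            if self.slopes[s] <= 0:
                raise ValueError(f"slope multiplier for state {s} must be > 0")

    def _u(self, c: float) -> float:
        if c <= 0:
            raise ValueError("consumption must be positive")
        if self.eta == 1.0:
            return float(np.log(c))
        return float(c ** (1.0 - self.eta) / (1.0 - self.eta))

    def _du(self, c: float) -> float:
        return float(c ** (-self.eta))

    def utility(self, state: str, c: float) -> float:
        return self.levels[state] + self.slopes[state] * self._u(c)

    def mutility(self, state: str, c: float) -> float:
        """Marginal utility of consumption in one health state."""
        return self.slopes[state] * self._du(c)

    # conditional expected utilities of the parent given the child's risk
    def eu_parent(self, parent_state: str, r_k: float, c: float) -> float:
        h, s = f"{parent_state}H", f"{parent_state}S"
        return (1.0 - r_k) * self.utility(h, c) + r_k * self.utility(s, c)

    def deu_parent(self, parent_state: str, r_k: float, c: float) -> float:
        h, s = f"{parent_state}H", f"{parent_state}S"
        return (1.0 - r_k) * self.mutility(h, c) + r_k * self.mutility(s, c)

    # conditional expected utilities over the child's state given parent risk
    def eu_child(self, child_state: str, r_p: float, c: float) -> float:
        h, s = f"H{child_state}", f"S{child_state}"
        return (1.0 - r_p) * self.utility(h, c) + r_p * self.utility(s, c)

    def deu_child(self, child_state: str, r_p: float, c: float) -> float:
        h, s = f"H{child_state}", f"S{child_state}"
        return (1.0 - r_p) * self.mutility(h, c) + r_p * self.mutility(s, c)

    def expected_utility(self, r_p: float, r_k: float, c: float) -> float:
        return (1.0 - r_p) * self.eu_parent("H", r_k, c) + r_p * self.eu_parent(
            "S", r_k, c
        )


# ---------------------------------------------------------------------------
# Exogenous risk
# ---------------------------------------------------------------------------

def mwtp_exogenous(
    spec: UtilitySpec, R_p: float, R_k: float, person: str = "parent"
) -> float:
    """MWTP ($ per unit probability) for a marginal own/child risk reduction.

    Evaluated at consumption equal to the full income endowment.  Raises if
    utility is not strictly increasing on the evaluation range or if the
    healthy-state expected utility does not exceed the sick-state one.
    """
    for r in (R_p, R_k):
        if not 0.0 < r < 1.0:
            raise ValueError("probabilities must lie in (0, 1)")
    c = spec.income
    for cc in (0.5 * c, c):  # monotonicity spot-check on the range used
        for s in STATES:
            if spec.mutility(s, cc) <= 0:
                raise ValueError(f"utility non-monotone in state {s}")
    if person.startswith("p"):
        eu_h, eu_s = spec.eu_parent("H", R_k, c), spec.eu_parent("S", R_k, c)
        deu_h, deu_s = spec.deu_parent("H", R_k, c), spec.deu_parent("S", R_k, c)
        r = R_p
    else:
        eu_h, eu_s = spec.eu_child("H", R_p, c), spec.eu_child("S", R_p, c)
        deu_h, deu_s = spec.deu_child("H", R_p, c), spec.deu_child("S", R_p, c)
        r = R_k
    if eu_h < eu_s:
        raise ValueError("healthy-state expected utility must exceed sick-state")
    denom = (1.0 - r) * deu_h + r * deu_s
    return (eu_h - eu_s) / denom


# ---------------------------------------------------------------------------
# Risk technology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskTechnology:
    """Exponential risk-production function.

    Default mode: R(X, G) = r0 * exp(-beta_x X - beta_g G - beta_xg X G);
    substitute=True gives the perfect-substitute variant
    R(X, G) = r0 * exp(-beta_x (X + phi G)).  Both satisfy R in (0, r0],
    R^X < 0 and R^XX > 0 for beta_x + beta_xg G > 0 on X, G >= 0.
    """

    r0: float
    beta_x: float
    beta_g: float = 0.0
    beta_xg: float = 0.0
    substitute: bool = False
    phi: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.r0 < 1.0:
            raise ValueError("r0 must lie in (0, 1)")
        if self.beta_x <= 0:
            raise ValueError("beta_x must be positive")

    def _exponent(self, x: float, g: float) -> float:
        if self.substitute:
            return -self.beta_x * (x + self.phi * g)
        return -self.beta_x * x - self.beta_g * g - self.beta_xg * x * g

    def risk(self, x: float, g: float) -> float:
        return self.r0 * np.exp(self._exponent(x, g))

    def d_dx(self, x: float, g: float) -> float:
        bx = self.beta_x if self.substitute else self.beta_x + self.beta_xg * g
        return -bx * self.risk(x, g)

    def d2_dx2(self, x: float, g: float) -> float:
        bx = self.beta_x if self.substitute else self.beta_x + self.beta_xg * g
        return bx * bx * self.risk(x, g)

    def d_dg(self, x: float, g: float) -> float:
        if self.substitute:
            return -self.beta_x * self.phi * self.risk(x, g)
        return -(self.beta_g + self.beta_xg * x) * self.risk(x, g)

    def d2_dxdg(self, x: float, g: float) -> float:
        if self.substitute:
            return self.beta_x**2 * self.phi * self.risk(x, g)
        bx = self.beta_x + self.beta_xg * g
        bg = self.beta_g + self.beta_xg * x
        return (-self.beta_xg + bx * bg) * self.risk(x, g)


# ---------------------------------------------------------------------------
# Endogenous risk: optimal private expenditure
# ---------------------------------------------------------------------------

@dataclass
class EndogenousSolution:
    """Interior (or corner) optimum of the endogenous-risk model."""

    x_p: float
    x_k: float
    r_p: float
    r_k: float
    mwtp_p: float
    mwtp_k: float
    foc_p: float
    foc_k: float
    corner_p: bool
    corner_k: bool
    expected_utility: float
    g: float


def _foc_parent(spec, tech_p, tech_k, x_p, x_k, g) -> float:
    """First-order condition for the parent's own expenditure X_p."""
    c = spec.income - x_p - x_k
    r_p, r_k = tech_p.risk(x_p, g), tech_k.risk(x_k, g)
    eu_h, eu_s = spec.eu_parent("H", r_k, c), spec.eu_parent("S", r_k, c)
    deu_h, deu_s = spec.deu_parent("H", r_k, c), spec.deu_parent("S", r_k, c)
    return (
        tech_p.d_dx(x_p, g) * (eu_s - eu_h)
        - (1.0 - r_p) * deu_h
        - r_p * deu_s
    )


def _foc_child(spec, tech_p, tech_k, x_p, x_k, g) -> float:
    """First-order condition for the child-directed expenditure X_k."""
    c = spec.income - x_p - x_k
    r_p, r_k = tech_p.risk(x_p, g), tech_k.risk(x_k, g)
    eu_h, eu_s = spec.eu_child("H", r_p, c), spec.eu_child("S", r_p, c)
    deu_h, deu_s = spec.deu_child("H", r_p, c), spec.deu_child("S", r_p, c)
    return (
        tech_k.d_dx(x_k, g) * (eu_s - eu_h)
        - (1.0 - r_k) * deu_h
        - r_k * deu_s
    )


def solve_endogenous(
    spec: UtilitySpec,
    tech_p: RiskTechnology,
    tech_k: RiskTechnology,
    G: float = 0.0,
    budget: float | None = None,
    tol: float = 1e-12,
    max_rounds: int = 400,
) -> EndogenousSolution:
    """Solve both first-order conditions by alternating bracketed root finds.

    Each round solves the parent FOC in X_p with X_k held fixed (Brent's
    method on a sign-changing bracket) and then the child FOC in X_k; under
    concave EU the Gauss-Seidel iteration contracts to the joint optimum.
    A FOC that is already non-positive at X = 0 gives a corner (X* = 0,
    flagged, with MWTP* <= marginal cost).  Residuals of both FOCs at the
    solution are reported and checked to 1e-8.
    """
    if budget is None:
        budget = 0.9 * spec.income
    if budget <= 0 or budget >= spec.income:
        raise ValueError("budget must lie in (0, income)")

    x_p, x_k = 0.0, 0.0
    corner_p = corner_k = False
    for _ in range(max_rounds):
        x_p_old, x_k_old = x_p, x_k

        hi = min(budget, spec.income - x_k - 1e-9 * spec.income)
        f0 = _foc_parent(spec, tech_p, tech_k, 0.0, x_k, G)
        if f0 <= 0.0:
            x_p, corner_p = 0.0, True
        else:
            fhi = _foc_parent(spec, tech_p, tech_k, hi, x_k, G)
            if fhi > 0.0:
                raise ValueError("no interior solution for X_p within budget")
            x_p = optimize.brentq(
                lambda x: _foc_parent(spec, tech_p, tech_k, x, x_k, G),
                0.0, hi, xtol=1e-15, rtol=8.9e-16,
            )
            corner_p = False

        hi = min(budget, spec.income - x_p - 1e-9 * spec.income)
        f0 = _foc_child(spec, tech_p, tech_k, x_p, 0.0, G)
        if f0 <= 0.0:
            x_k, corner_k = 0.0, True
        else:
            fhi = _foc_child(spec, tech_p, tech_k, x_p, hi, G)
            if fhi > 0.0:
                raise ValueError("no interior solution for X_k within budget")
            x_k = optimize.brentq(
                lambda x: _foc_child(spec, tech_p, tech_k, x_p, x, G),
                0.0, hi, xtol=1e-15, rtol=8.9e-16,
            )
            corner_k = False

        if abs(x_p - x_p_old) < tol and abs(x_k - x_k_old) < tol:
            break

    r_p, r_k = tech_p.risk(x_p, G), tech_k.risk(x_k, G)
    foc_p = _foc_parent(spec, tech_p, tech_k, x_p, x_k, G)
    foc_k = _foc_child(spec, tech_p, tech_k, x_p, x_k, G)
    for who, corner, foc in (("X_p", corner_p, foc_p), ("X_k", corner_k, foc_k)):
        if not corner and abs(foc) > 1e-8:
            raise RuntimeError(f"FOC residual for {who} did not converge: {foc:.3e}")
    mwtp_p = -1.0 / tech_p.d_dx(x_p, G)
    mwtp_k = -1.0 / tech_k.d_dx(x_k, G)
    return EndogenousSolution(
        x_p=x_p, x_k=x_k, r_p=r_p, r_k=r_k,
        mwtp_p=mwtp_p, mwtp_k=mwtp_k,
        foc_p=foc_p, foc_k=foc_k,
        corner_p=corner_p, corner_k=corner_k,
        expected_utility=spec.expected_utility(
            r_p, r_k, spec.income - x_p - x_k
        ),
        g=G,
    )


def comparative_statics_dG(
    spec: UtilitySpec,
    tech_p: RiskTechnology,
    tech_k: RiskTechnology,
    G: float,
    h: float = 1e-3,
    person: str = "parent",
    budget: float | None = None,
) -> dict:
    """Central-difference derivative of optimal MWTP* with respect to G.

    Returns the finite-difference derivative, its sign, and the analytic
    decomposition (R^XX dX/dG + R^XG) / (R^X)^2 evaluated at the middle
    solution (dX/dG itself by central difference).  Raises if any of the
    three evaluation points is a corner.
    """
    sols = {
        dg: solve_endogenous(spec, tech_p, tech_k, G + dg, budget)
        for dg in (-h, 0.0, h)
    }
    attr_x = "x_p" if person.startswith("p") else "x_k"
    attr_m = "mwtp_p" if person.startswith("p") else "mwtp_k"
    corner = "corner_p" if person.startswith("p") else "corner_k"
    for s in sols.values():
        if getattr(s, corner):
            raise ValueError("corner solution encountered; derivative undefined")
    tech = tech_p if person.startswith("p") else tech_k
    dm_dg = (getattr(sols[h], attr_m) - getattr(sols[-h], attr_m)) / (2.0 * h)
    dx_dg = (getattr(sols[h], attr_x) - getattr(sols[-h], attr_x)) / (2.0 * h)
    x_mid = getattr(sols[0.0], attr_x)
    rx = tech.d_dx(x_mid, G)
    analytic = (tech.d2_dx2(x_mid, G) * dx_dg + tech.d2_dxdg(x_mid, G)) / rx**2
    return {
        "dmwtp_dG": dm_dg,
        "sign": float(np.sign(dm_dg)),
        "analytic_decomposition": analytic,
        "dx_dG": dx_dg,
        "solution": sols[0.0],
    }


def ratio_conditions(
    sol: EndogenousSolution,
    tech_p: RiskTechnology,
    tech_k: RiskTechnology,
) -> dict:
    """Optimality-ratio report at an interior endogenous solution.

    Verifies MWTP*_p / MWTP*_k = R_k^X / R_p^X (marginal-product form) and
    reports the baseline-risk ratio R_k / R_p, which the MWTP ratio equals
    when one-unit changes in X produce equal *proportionate* reductions.
    """
    if sol.corner_p or sol.corner_k:
        raise ValueError("ratio conditions require an interior solution")
    rx_p = tech_p.d_dx(sol.x_p, sol.g)
    rx_k = tech_k.d_dx(sol.x_k, sol.g)
    mwtp_ratio = sol.mwtp_p / sol.mwtp_k
    mp_ratio = rx_k / rx_p
    return {
        "mwtp_ratio": mwtp_ratio,
        "marginal_product_ratio": mp_ratio,
        "risk_ratio": sol.r_k / sol.r_p,
        "marginal_product_identity_gap": abs(mwtp_ratio - mp_ratio),
    }
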