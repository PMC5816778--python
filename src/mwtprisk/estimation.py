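"""Maximum-likelihood bivariate probit for the mean-centered latent-WTP model.

The estimating equation per person i in {parent, child} is the re-parameterized
latent-WTP model

    (W~_i - Q)/sigma_i = c_i/sigma_i + (gamma_i/sigma_i) * delta_i
                         - (1/sigma_i) * q + eps_i,

with delta_i the mean-centered proportionate risk reduction (or omega_i, the
mean-centered absolute reduction Delta_i*R_i) and q the mean-centered price;
only the sign of the left side is observed (purchase iff >= 0).  The parent and
child errors are standard bivariate normal with correlation rho, so the
log-likelihood is a sum of bivariate-normal orthant probabilities

    ll = sum log Phi2(s_p x_p'b_p, s_k x_k'b_k, s_p s_k rho),   s_i = 2 buy_i - 1.

Because the price coefficient equals -1/sigma_i, dollar-scale MWTP is recovered
downstream by dividing risk coefficients by the negative price coefficient.

Everything here is hand-rolled on numpy/scipy primitives: the bivariate normal
CDF via Owen's T, analytic score, BFGS with a Newton polish, and covariance
from a central-finite-difference Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

_SQRT2PI = np.sqrt(2.0 * np.pi)

# Baseline-risk bin edges implied by the published integer bin ranges
# (parents 0-20 / 21-30 / 31-46 / 47-100; children 0-14 / 15-20 / 21-30 /
# 31-100), cut at the integer midpoints for continuous risks.  The highest
# bin is the omitted reference category.
PARENT_RISK_BIN_EDGES: tuple[float, ...] = (20.5, 30.5, 46.5)
CHILD_RISK_BIN_EDGES: tuple[float, ...] = (14.5, 20.5, 30.5)
RISK_BIN_LABELS = ("lowest", "low", "high")  # "highest" omitted

DESIGN_SPECS = (
    "base", "absolute", "risk_bins", "risk_bins_main", "absolute_risk_bins",
    "piecewise", "income", "children",
)


# ---------------------------------------------------------------------------
# Bivariate normal CDF (Owen's T decomposition)
# ---------------------------------------------------------------------------

def phi2(a, b, rho):
    """Standard bivariate normal CDF P(Z1 <= a, Z2 <= b; rho).

    Computed from Owen's T function:

        Phi2(h,k,rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - beta,

    with a_h = (k - rho h)/(h sqrt(1-rho^2)) (symmetrically for a_k) and
    beta = 1/2 iff hk < 0 or (hk = 0 and h + k < 0).  Accurate to ~1e-14,
    vectorised over a and b.  |rho| must be < 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError("|rho| must be < 1")
    # nudge exact zeros so the Owen's T arguments are well-defined; the
    # introduced error is O(1e-15)
    h = np.where(a == 0.0, 1e-15, a)
    k = np.where(b == 0.0, 1e-15, b)
    s = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * s)
    ak = (h - rho * k) / (k * s)
    p = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, ah)
        - special.owens_t(k, ak)
    )
    # correction term: 1/2 when h and k have opposite signs (the product
    # h*k can underflow to -0.0, so compare signs directly)
    beta = np.where(((h > 0) & (k < 0)) | ((h < 0) & (k > 0)), 0.5, 0.0)
    return np.clip(p - beta, 0.0, 1.0)


def phi2_density(a, b, rho):
    """Standard bivariate normal density at (a, b) with correlation rho."""
    s2 = 1.0 - rho * rho
    z = (a * a - 2.0 * rho * a * b + b * b) / s2
    return np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(s2))


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def risk_bin_indicators(risk: np.ndarray, edges: Sequence[float]) -> dict[str, np.ndarray]:
    """Uncentered indicator columns for the three non-reference risk bins."""
    e = list(edges)
    bins = {
        "lowest": risk <= e[0],
        "low": (risk > e[0]) & (risk <= e[1]),
        "high": (risk > e[1]) & (risk <= e[2]),
    }
    return {name: ind.astype(float) for name, ind in bins.items()}


def _person_design(
    df: pd.DataFrame, person: str, spec: str,
    parent_edges, child_edges,
) -> pd.DataFrame:
    """Mean-centered design matrix for one equation (parent or child)."""
    p = "p" if person.startswith("p") else "k"
    delta = df[f"delta_{p}"].to_numpy(dtype=float)
    risk = df[f"r_{p}"].to_numpy(dtype=float)
    q = df["price"].to_numpy(dtype=float)
    omega = delta * risk

    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    edges = parent_edges if p == "p" else child_edges

    if spec == "base":
        cols["delta"] = _center(delta)
        cols["q"] = _center(q)
    elif spec == "absolute":
        cols["omega"] = _center(omega)
        cols["q"] = _center(q)
    elif spec in ("risk_bins", "risk_bins_main", "absolute_risk_bins"):
        risk_name = "omega" if spec == "absolute_risk_bins" else "delta"
        risk_var = omega if spec == "absolute_risk_bins" else delta
        inds = risk_bin_indicators(risk, edges)
        for name, ind in inds.items():
            if ind.sum() == 0:
                raise ValueError(f"empty risk bin '{name}' for {person}")
            cols[f"bin_{name}"] = _center(ind)
        cv, cq = _center(risk_var), _center(q)
        cols[risk_name] = cv
        cols["q"] = cq
        if spec != "risk_bins_main":
            for name, ind in inds.items():
                cols[f"{risk_name}_x_{name}"] = cv * _center(ind)
                cols[f"q_x_{name}"] = cq * _center(ind)
    elif spec == "piecewise":
        # omega interacted with hinge functions of baseline risk at the bin
        # edges yields MWTP continuous and piecewise linear in R
        cols["omega"] = _center(omega)
        cols["q"] = _center(q)
        for knot in edges:
            hinge = omega * np.maximum(risk - knot, 0.0)
            cols[f"omega_hinge_{knot:g}"] = _center(hinge)
    elif spec in ("income", "children"):
        var = "income_bracket" if spec == "income" else "n_children"
        if var not in df.columns:
            raise ValueError(f"records lack '{var}' needed for spec '{spec}'")
        cd, cq = _center(delta), _center(q)
        cols["delta"] = cd
        cols["q"] = cq
        levels = np.sort(np.unique(df[var].to_numpy()))
        for lev in levels[:-1]:  # highest level omitted as reference
            ind = (df[var].to_numpy() == lev).astype(float)
            if ind.sum() == 0:
                raise ValueError(f"empty {var} level {lev}")
            ci = _center(ind)
            cols[f"{var}_{lev}"] = ci
            cols[f"delta_x_{var}_{lev}"] = cd * ci
            cols[f"q_x_{var}_{lev}"] = cq * ci
    else:
        raise ValueError(f"unknown spec '{spec}'; choose from {DESIGN_SPECS}")

    out = pd.DataFrame(cols)
    # interaction columns are products of centered parents and so are not
    # exactly mean zero themselves; re-centering them preserves the model
    # space while keeping the centering invariant exact for every column
    for c in out.columns:
        if c != "const":
            out[c] = _center(out[c].to_numpy())
    return out


def build_design(
    records: pd.DataFrame,
    spec: str = "base",
    parent_edges: Sequence[float] = PARENT_RISK_BIN_EDGES,
    child_edges: Sequence[float] = CHILD_RISK_BIN_EDGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the (parent, child) mean-centered design matrices for a spec.

    All non-constant columns are centered on the estimation sample's own
    means, so subsample fits re-center automatically.
    """
    xp = _person_design(records, "parent", spec, parent_edges, child_edges)
    xk = _person_design(records, "child", spec, parent_edges, child_edges)
    return xp, xk


# ---------------------------------------------------------------------------
# Univariate probit (Newton scoring) -- starting values
# ---------------------------------------------------------------------------

def fit_probit(x: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-10):
    """Univariate probit MLE by Newton-Raphson; returns (beta, llf, converged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(x.shape[1])
    beta[0] = stats.norm.ppf(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    converged = False
    for _ in range(max_iter):
        eta = x @ beta
        s = 2.0 * y - 1.0
        z = s * eta
        # score uses the inverse Mills ratio lambda(z) = phi(z)/Phi(z)
        lam = s * np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
        grad = x.T @ lam
        w = lam * (lam + eta)  # observed-information weights
        hess = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    llf = float(stats.norm.logcdf((2.0 * y - 1.0) * (x @ beta)).sum())
    return beta, llf, converged


# ---------------------------------------------------------------------------
# Bivariate probit MLE
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """One estimated bivariate probit specification.

    Coefficients are on the normalized scale of the latent model
    (c/sigma, gamma/sigma on the risk term, -1/sigma on price).  ``vcov`` is
    the inverse of the finite-difference Hessian over the stacked parameter
    vector [parent coefs, child coefs, rho].
    """

    spec: str
    params_p: pd.Series
    params_k: pd.Series
    rho: float
    vcov: pd.DataFrame
    llf: float
    n: int
    converged: bool
    n_iter: int
    grad_norm: float
    message: str = ""

    @property
    def names(self) -> list[str]:
        return list(self.vcov.columns)

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate(
            [self.params_p.to_numpy(), self.params_k.to_numpy(), [self.rho]]
        )

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())), index=self.names)

    def coef(self, person: str, term: str) -> float:
        s = self.params_p if person.startswith("p") else self.params_k
        return float(s[term])

    def coef_se(self, person: str, term: str) -> float:
        tag = ("p:" if person.startswith("p") else "k:") + term
        return float(np.sqrt(self.vcov.loc[tag, tag]))

    def to_dict(self) -> dict:
        return {
            "spec": self.spec,
            "params_parent": self.params_p.to_dict(),
            "params_child": self.params_k.to_dict(),
            "rho": self.rho,
            "se": self.se().to_dict(),
            "vcov": {"names": self.names, "values": self.vcov.to_numpy().tolist()},
            "llf": self.llf,
            "n": self.n,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
        }


def _loglike_and_score(theta, xp, xk, sp, sk, spk, kp):
    """Negative log-likelihood and gradient; theta = [bp, bk, atanh(rho)]."""
    bp = theta[:kp]
    bk = theta[kp:-1]
    z = theta[-1]
    # tanh saturates in floats; keep rho strictly inside (-1, 1)
    rho = float(np.clip(np.tanh(z), -1 + 1e-10, 1 - 1e-10))

    a = sp * (xp @ bp)
    b = sk * (xk @ bk)
    r = spk * rho
    p = phi2(a, b, r)
    p = np.maximum(p, 1e-300)
    ll = np.log(p).sum()

    s = np.sqrt(1.0 - rho * rho)
    # d log Phi2 / da = phi(a) Phi((b - r a)/s) / Phi2
    da = np.exp(stats.norm.logpdf(a) + stats.norm.logcdf((b - r * a) / s)) / p
    db = np.exp(stats.norm.logpdf(b) + stats.norm.logcdf((a - r * b) / s)) / p
    dr = phi2_density(a, b, r) / p

    g_bp = xp.T @ (sp * da)
    g_bk = xk.T @ (sk * db)
    g_z = float(np.sum(spk * dr)) * (1.0 - rho * rho)  # chain rule through tanh
    grad = np.concatenate([g_bp, g_bk, [g_z]])
    return -ll, -grad


def _loglike_rho_grad(theta, xp, xk, sp, sk, spk, kp):
    """Gradient of the log-likelihood in the reported (b_p, b_k, rho) scale."""
    t = theta.copy()
    rho = np.clip(t[-1], -1 + 1e-12, 1 - 1e-12)
    t[-1] = np.arctanh(rho)
    nll, ngrad = _loglike_and_score(t, xp, xk, sp, sk, spk, kp)
    g = -ngrad
    g[-1] = g[-1] / (1.0 - rho * rho)  # undo tanh chain rule
    return -nll, g


def loglike_bivariate_probit(
    xp: pd.DataFrame | np.ndarray,
    xk: pd.DataFrame | np.ndarray,
    buy_p: np.ndarray,
    buy_k: np.ndarray,
    beta_p: np.ndarray,
    beta_k: np.ndarray,
    rho: float,
) -> float:
    """Log-likelihood at an arbitrary parameter point (for diagnostics/tests)."""
    xp = np.asarray(xp, dtype=float)
    xk = np.asarray(xk, dtype=float)
    sp = 2.0 * np.asarray(buy_p, dtype=float) - 1.0
    sk = 2.0 * np.asarray(buy_k, dtype=float) - 1.0
    p = phi2(sp * (xp @ beta_p), sk * (xk @ beta_k), sp * sk * rho)
    return float(np.log(np.maximum(p, 1e-300)).sum())


def fit_bivariate_probit(
    design: tuple[pd.DataFrame, pd.DataFrame],
    outcomes: tuple[np.ndarray, np.ndarray] | pd.DataFrame,
    spec: str = "",
    gtol: float = 1e-6,
    max_iter: int = 500,
    hessian_step: float = 1e-5,
) -> FitResult:
    """Fit the two-equation probit with correlated errors by full MLE.

    Starting values come from univariate probit fits per equation with rho
    started at 0; rho is optimized through an inverse-hyperbolic-tangent
    transform so the search is unconstrained.  BFGS with the analytic score
    is followed by a Newton polish on the finite-difference Hessian until the
    gradient sup-norm is below ``gtol``.  Standard errors are taken from the
    inverse central-finite-difference Hessian (step ``hessian_step*(1+|t|)``)
    in the reported (coefficients, rho) parameterization.

    Divergence or separation yields ``converged=False`` with diagnostics in
    ``message`` -- never a silent failure.
    """
    xp_df, xk_df = design
    if isinstance(outcomes, pd.DataFrame):
        yp = outcomes["buy_p"].to_numpy(dtype=float)
        yk = outcomes["buy_k"].to_numpy(dtype=float)
    else:
        yp = np.asarray(outcomes[0], dtype=float)
        yk = np.asarray(outcomes[1], dtype=float)
    xp = xp_df.to_numpy(dtype=float)
    xk = xk_df.to_numpy(dtype=float)
    n = xp.shape[0]
    for y, who in ((yp, "parent"), (yk, "child")):
        if y.min() == y.max():
            raise ValueError(f"{who} outcome does not vary")
    for x, who in ((xp, "parent"), (xk, "child")):
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(f"{who} design matrix is rank deficient")

    sp = 2.0 * yp - 1.0
    sk = 2.0 * yk - 1.0
    spk = sp * sk
    kp = xp.shape[1]

    b0p, _, _ = fit_probit(xp, yp)
    b0k, _, _ = fit_probit(xk, yk)
    theta0 = np.concatenate([b0p, b0k, [0.0]])  # atanh(0) = 0

    args = (xp, xk, sp, sk, spk, kp)
    res = optimize.minimize(
        _loglike_and_score, theta0, args=args, jac=True, method="BFGS",
        options={"gtol": gtol * 1e-3, "maxiter": max_iter},
    )
    theta = res.x
    n_iter = int(res.nit)

    # Newton polish in the unconstrained scale if BFGS stopped short
    grad_norm = float(np.max(np.abs(res.jac)))
    message = str(res.message)
    for _ in range(20):
        if grad_norm <= gtol * 0.1:
            break
        h = _fd_hessian(lambda t: _loglike_and_score(t, *args)[1], theta, hessian_step)
        try:
            step = np.linalg.solve(h, _loglike_and_score(theta, *args)[1])
        except np.linalg.LinAlgError:
            break
        cand = theta - step
        if not np.isfinite(cand).all():
            break
        if _loglike_and_score(cand, *args)[0] > _loglike_and_score(theta, *args)[0] + 1e-9:
            break
        theta = cand
        grad_norm = float(np.max(np.abs(_loglike_and_score(theta, *args)[1])))
        n_iter += 1

    rho = float(np.clip(np.tanh(theta[-1]), -1 + 1e-10, 1 - 1e-10))
    nll = _loglike_and_score(theta, *args)[0]
    converged = bool(np.isfinite(nll)) and grad_norm < gtol and abs(rho) < 1 - 1e-8
    if abs(rho) >= 1 - 1e-8:
        message += " | rho at boundary (possible degenerate correlation)"
    if not np.isfinite(nll):
        message += " | non-finite log-likelihood (possible separation)"

    # covariance in the reported parameterization [b_p, b_k, rho]
    theta_rep = np.concatenate([theta[:-1], [rho]])

    def grad_rep(t):
        return -_loglike_rho_grad(t, *args)[1]  # gradient of the NEGATIVE llf

    h_rep = _fd_hessian(grad_rep, theta_rep, hessian_step)
    h_rep = 0.5 * (h_rep + h_rep.T)
    try:
        vcov = np.linalg.inv(h_rep)
    except np.linalg.LinAlgError:
        vcov = np.full_like(h_rep, np.nan)
        converged = False
        message += " | singular Hessian"

    names_p = [f"p:{c}" for c in xp_df.columns]
    names_k = [f"k:{c}" for c in xk_df.columns]
    names = names_p + names_k + ["rho"]
    return FitResult(
        spec=spec,
        params_p=pd.Series(theta[:kp], index=list(xp_df.columns)),
        params_k=pd.Series(theta[kp:-1], index=list(xk_df.columns)),
        rho=rho,
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        llf=float(-nll),
        n=n,
        converged=converged,
        n_iter=n_iter,
        grad_norm=grad_norm,
        message=message.strip(" |"),
    )


def _fd_hessian(grad_fn, theta: np.ndarray, rel_step: float) -> np.ndarray:
    """Central-finite-difference Jacobian of a gradient function."""
    k = len(theta)
    h = np.empty((k, k))
    for j in range(k):
        step = rel_step * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += step
        tm[j] -= step
        h[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * step)
    return 0.5 * (h + h.T)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def lr_test(restricted: FitResult, full: FitResult, tol: float = 1e-6):
    """Likelihood-ratio test of nested specifications fit on the same data.

    Returns (statistic, df, p).  A full-model log-likelihood below the
    restricted one beyond ``tol`` indicates an optimization failure and
    raises.
    """
    if restricted.n != full.n:
        raise ValueError("fits are not on the same data (different n)")
    df = (len(full.params_p) + len(full.params_k)) - (
        len(restricted.params_p) + len(restricted.params_k)
    )
    if df < 0:
        raise ValueError("'full' has fewer parameters than 'restricted'")
    stat = 2.0 * (full.llf - restricted.llf)
    if stat < -tol:
        raise RuntimeError(
            f"full-model log-likelihood below restricted ({full.llf:.6f} < "
            f"{restricted.llf:.6f}): optimization failure"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def wald_ratio_equality(
    fit: FitResult,
    risk_term_p: str = "delta",
    risk_term_k: str = "delta",
    price_term: str = "q",
):
    """Wald test of equal dollar-scale MWTP slopes for parent and child.

    H0: gamma_p = gamma_k where gamma_i = coef(risk_i) / (-coef(price_i)),
    with the delta-method variance from the joint covariance of the four
    coefficients.  Raises when either price coefficient is statistically
    indistinguishable from zero (|t| < 2), since the ratio is then
    unidentified.
    """
    names = [f"p:{risk_term_p}", f"p:{price_term}",
             f"k:{risk_term_k}", f"k:{price_term}"]
    gp, qp = fit.coef("parent", risk_term_p), fit.coef("parent", price_term)
    gk, qk = fit.coef("child", risk_term_k), fit.coef("child", price_term)
    for who, q, tag in (("parent", qp, names[1]), ("child", qk, names[3])):
        t = abs(q) / np.sqrt(fit.vcov.loc[tag, tag])
        if t < 2.0:
            raise ValueError(
                f"{who} price coefficient indistinguishable from 0 "
                f"(|t| = {t:.2f}); MWTP ratio unidentified"
            )
    g = gp / (-qp) - gk / (-qk)
    # gradient of g wrt (gp, qp, gk, qk)
    jac = np.array([-1.0 / qp, gp / qp**2, 1.0 / qk, -gk / qk**2])
    sub = fit.vcov.loc[names, names].to_numpy()
    var = float(jac @ sub @ jac)
    stat = g * g / var
    p = float(stats.chi2.sf(stat, 1))
    return stat, p
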