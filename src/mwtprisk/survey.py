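"""Synthetic stated-preference survey data for heart-disease risk valuation.

Generates household-level records with the experimental design and latent-WTP
error structure that the bivariate-probit estimator assumes: a parent states
purchase intentions for two hypothetical vaccines (one for herself, one for her
child) at a randomly assigned common price, with randomly assigned proportionate
risk reductions and individually perceived baseline risks of heart-disease
diagnosis before age 75 (in "chances in 100").

Latent stated WTP for person i in {parent, child} is

    W~_i = alpha_i + gamma_i * X_i + sigma_i * eps_i

where X_i is the proportionate risk reduction Delta_i (proportionate mode) or
the absolute reduction Delta_i * R_i in chances in 100 (absolute mode), and
(eps_p, eps_k) are standard bivariate normal with correlation rho.  The parent
buys vaccine i iff W~_i >= Q (ties count as purchase; measure zero under
continuous errors).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# Experimental design constants (the study's randomized vaccine attributes)
# ---------------------------------------------------------------------------

DELTA_P_LEVELS: tuple[float, ...] = (0.1, 0.7)
DELTA_K_LEVELS: tuple[float, ...] = (0.2, 0.8)
PRICE_LEVELS: tuple[float, ...] = (10.0, 20.0, 40.0, 80.0, 160.0)

#: Expected design-point means under the randomized assignment.  delta_k is
#: drawn conditionally on delta_k > delta_p, so P(delta_k = 0.8) = 3/4.
DELTA_P_MEAN = float(np.mean(DELTA_P_LEVELS))
DELTA_K_MEAN = 0.25 * DELTA_K_LEVELS[0] + 0.75 * DELTA_K_LEVELS[1]
PRICE_MEAN = float(np.mean(PRICE_LEVELS))

#: Published normalized bivariate-probit estimates (proportionate-reduction
#: specification, n = 2211) used as the default data-generating truth.
PUBLISHED_PROPORTIONATE_FIT: dict[str, float] = {
    "const_k": -0.3729,
    "const_p": -0.4195,
    "risk_k": 0.7404,   # gamma_k / sigma_k on delta_k
    "risk_p": 0.9624,   # gamma_p / sigma_p on delta_p
    "price_k": -0.0037,  # -1 / sigma_k
    "price_p": -0.0042,  # -1 / sigma_p
    "rho": 0.8912,
}

#: Default baseline-risk moment targets (mean, SD) in chances in 100:
#: pooled revised own-risk mean 33.59 and revised child-risk mean 24.30.
PARENT_RISK_MOMENTS: tuple[float, float] = (33.59, 20.14)
CHILD_RISK_MOMENTS: tuple[float, float] = (24.30, 15.40)

#: Default rank correlation between parent and child perceived risks,
#: induced through a Gaussian copula.  Not identified by published moments;
#: a moderate positive familial correlation is assumed.
DEFAULT_RISK_COPULA_CORR = 0.5

#: Share of respondents that are mothers (1461 / 2211 in the study sample).
FEMALE_SHARE = 0.661

CSV_COLUMNS = [
    "id", "delta_p", "delta_k", "price", "r_p", "r_k",
    "buy_p", "buy_k", "income_bracket", "n_children", "parent_female",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignPoint:
    """One household's randomly assigned vaccine attributes.

    The price Q is shared by the parent and child vaccines within a
    household; the child's proportionate reduction always exceeds the
    parent's by design.
    """

    delta_p: float
    delta_k: float
    price: float

    def __post_init__(self) -> None:
        if self.delta_p not in DELTA_P_LEVELS:
            raise ValueError(f"delta_p must be one of {DELTA_P_LEVELS}")
        if self.delta_k not in DELTA_K_LEVELS:
            raise ValueError(f"delta_k must be one of {DELTA_K_LEVELS}")
        if self.price not in PRICE_LEVELS:
            raise ValueError(f"price must be one of {PRICE_LEVELS}")


@dataclass(frozen=True)
class BaselineRisks:
    """Revised perceived risks (chances in 100) for parent and child."""

    r_p: float
    r_k: float

    def __post_init__(self) -> None:
        for r in (self.r_p, self.r_k):
            if not 0.0 <= r <= 100.0:
                raise ValueError("risks must lie in [0, 100]")


@dataclass(frozen=True)
class LatentWTPParams:
    """Dollar-scale parameters of the latent stated-WTP equations.

    alpha_*  systematic misstatement constants ($)
    gamma_*  true WTP per unit of proportionate (or absolute) reduction ($)
    sigma_*  error scale ($)
    rho      correlation of the standardized parent/child errors
    """

    alpha_p: float
    alpha_k: float
    gamma_p: float
    gamma_k: float
    sigma_p: float
    sigma_k: float
    rho: float

    def __post_init__(self) -> None:
        if self.sigma_p <= 0 or self.sigma_k <= 0:
            raise ValueError("sigma_p and sigma_k must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly in (-1, 1)")

    def replace(self, **kwargs) -> "LatentWTPParams":
        return dataclasses.replace(self, **kwargs)


def params_from_normalized(
    normalized: dict[str, float] | None = None,
    *,
    delta_p_mean: float = DELTA_P_MEAN,
    delta_k_mean: float = DELTA_K_MEAN,
    price_mean: float = PRICE_MEAN,
) -> LatentWTPParams:
    """Convert normalized probit coefficients into dollar-scale parameters.

    The mean-centered probit reports (c/sigma, gamma/sigma, -1/sigma, rho).
    Inverting: sigma = -1/coef(price); gamma = coef(risk)*sigma; and alpha is
    chosen so that the implied constant c/sigma = (alpha + gamma*Dbar - Qbar)/sigma
    matches the reported constant under the design means supplied.

    Defaults reproduce the published proportionate-specification fit, making
    the returned object the standard data-generating truth for simulation
    studies at the study's design (Dbar_p = 0.4, Dbar_k = 0.5, Qbar = 62).
    """
    z = dict(PUBLISHED_PROPORTIONATE_FIT if normalized is None else normalized)
    sigma_p = -1.0 / z["price_p"]
    sigma_k = -1.0 / z["price_k"]
    if sigma_p <= 0 or sigma_k <= 0:
        raise ValueError("price coefficients must be negative")
    gamma_p = z["risk_p"] * sigma_p
    gamma_k = z["risk_k"] * sigma_k
    alpha_p = z["const_p"] * sigma_p - gamma_p * delta_p_mean + price_mean
    alpha_k = z["const_k"] * sigma_k - gamma_k * delta_k_mean + price_mean
    return LatentWTPParams(
        alpha_p=alpha_p, alpha_k=alpha_k,
        gamma_p=gamma_p, gamma_k=gamma_k,
        sigma_p=sigma_p, sigma_k=sigma_k,
        rho=z["rho"],
    )


def default_params() -> LatentWTPParams:
    """Dollar-scale truth matching the published proportionate fit."""
    return params_from_normalized(None)


# ---------------------------------------------------------------------------
# Seeding: one master seed, independent child streams per stage
# ---------------------------------------------------------------------------

_STREAMS = ("design", "risks", "errors", "covariates", "misreport")


def child_rngs(seed: int | np.random.SeedSequence) -> dict[str, np.random.Generator]:
    """Spawn one independent generator per simulation stage from a master seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def draw_design(n: int, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw ``n`` design points randomly from the legal attribute sets.

    delta_p and the price are uniform over their levels and independent; the
    price is drawn once per household (shared by both vaccines).  delta_k is
    uniform over the child levels that exceed the household's delta_p, since
    the child's proportionate reduction always exceeds the parent's by
    design (so delta_p = 0.7 forces delta_k = 0.8).
    Returns a DataFrame with columns delta_p, delta_k, price.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    delta_p = rng.choice(DELTA_P_LEVELS, size=n)
    delta_k = rng.choice(DELTA_K_LEVELS, size=n)
    # resample the illegal (0.7, 0.2) combination up to the only legal level
    delta_k = np.where(delta_k <= delta_p, max(DELTA_K_LEVELS), delta_k)
    return pd.DataFrame({
        "delta_p": delta_p,
        "delta_k": delta_k,
        "price": rng.choice(PRICE_LEVELS, size=n),
    })


def beta_params_from_moments(mean: float, sd: float, scale: float = 100.0) -> tuple[float, float]:
    """Moment-matched Beta(a, b) shape parameters on [0, scale].

    Raises ValueError when no Beta distribution on [0, scale] has the
    requested mean and SD (variance must be below mu*(1-mu) on the unit scale).
    """
    if not 0.0 < mean < scale:
        raise ValueError(f"mean must lie in (0, {scale})")
    if sd <= 0:
        raise ValueError("sd must be positive")
    mu = mean / scale
    var = (sd / scale) ** 2
    if var >= mu * (1.0 - mu):
        raise ValueError(
            f"(mean={mean}, sd={sd}) is infeasible for a Beta on [0, {scale}]: "
            f"variance must be < {mu * (1 - mu) * scale**2:.4g}"
        )
    nu = mu * (1.0 - mu) / var - 1.0
    return mu * nu, (1.0 - mu) * nu


def draw_baseline_risks(
    n: int,
    parent_moments: tuple[float, float] = PARENT_RISK_MOMENTS,
    child_moments: tuple[float, float] = CHILD_RISK_MOMENTS,
    copula_corr: float = DEFAULT_RISK_COPULA_CORR,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw correlated perceived baseline risks on [0, 100].

    Marginals are moment-matched scaled Beta distributions; the joint is a
    Gaussian copula with correlation ``copula_corr``.  An SD of exactly zero
    degenerates to a point mass at the mean.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not -1.0 < copula_corr < 1.0:
        raise ValueError("copula_corr must lie in (-1, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    z = rng.standard_normal((n, 2))
    z[:, 1] = copula_corr * z[:, 0] + np.sqrt(1.0 - copula_corr**2) * z[:, 1]
    u = stats.norm.cdf(z)

    out = {}
    for col, (mean, sd), ui in (("r_p", parent_moments, u[:, 0]),
                                ("r_k", child_moments, u[:, 1])):
        if sd == 0.0:
            out[col] = np.full(n, float(mean))
        else:
            a, b = beta_params_from_moments(mean, sd)
            out[col] = 100.0 * stats.beta.ppf(ui, a, b)
    return pd.DataFrame(out)


def draw_covariates(n: int, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Household covariates: income bracket, number of children, parent gender.

    Distributions are simple stand-ins for a national parent panel: income
    brackets 1..5 roughly symmetric, 74% of households with two or more
    children, and a 66% share of mothers.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    income = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.15, 0.25, 0.30, 0.20, 0.10])
    n_children = rng.choice([1, 2, 3, 4], size=n, p=[0.26, 0.40, 0.23, 0.11])
    female = (rng.random(n) < FEMALE_SHARE).astype(int)
    return pd.DataFrame({
        "income_bracket": income, "n_children": n_children, "parent_female": female,
    })


def simulate_purchases(
    designs: pd.DataFrame,
    risks: pd.DataFrame,
    params: LatentWTPParams,
    mode: str = "proportionate",
    seed: int | np.random.Generator = 0,
    misreport_rate: float = 0.0,
    misreport_rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw latent WTPs and the implied purchase indicators.

    mode="proportionate" uses X_i = Delta_i; mode="absolute" uses
    X_i = Delta_i * R_i (absolute reduction in chances in 100).  The optional
    misreport layer flips each positive intention to 0 independently with
    probability ``misreport_rate`` (the "uncertain purchaser" recoding the
    estimator assumes has already been applied; default off).
    """
    if mode not in ("proportionate", "absolute"):
        raise ValueError("mode must be 'proportionate' or 'absolute'")
    if not 0.0 <= misreport_rate < 1.0:
        raise ValueError("misreport_rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(designs)
    if len(risks) != n:
        raise ValueError("designs and risks must have equal length")

    eps = rng.standard_normal((n, 2))
    eps[:, 1] = params.rho * eps[:, 0] + np.sqrt(1.0 - params.rho**2) * eps[:, 1]

    if mode == "proportionate":
        x_p = designs["delta_p"].to_numpy()
        x_k = designs["delta_k"].to_numpy()
    else:
        x_p = designs["delta_p"].to_numpy() * risks["r_p"].to_numpy()
        x_k = designs["delta_k"].to_numpy() * risks["r_k"].to_numpy()

    w_p = params.alpha_p + params.gamma_p * x_p + params.sigma_p * eps[:, 0]
    w_k = params.alpha_k + params.gamma_k * x_k + params.sigma_k * eps[:, 1]
    price = designs["price"].to_numpy()
    buy_p = (w_p >= price).astype(int)
    buy_k = (w_k >= price).astype(int)

    if misreport_rate > 0.0:
        mrng = misreport_rng if misreport_rng is not None else rng
        buy_p = np.where(mrng.random(n) < misreport_rate, 0, buy_p)
        buy_k = np.where(mrng.random(n) < misreport_rate, 0, buy_k)

    rec = pd.concat(
        [designs.reset_index(drop=True), risks.reset_index(drop=True)], axis=1
    )
    rec.insert(0, "id", np.arange(n))
    rec["buy_p"] = buy_p
    rec["buy_k"] = buy_k
    return rec


def simulate_survey(
    n: int = 2211,
    params: LatentWTPParams | None = None,
    mode: str = "proportionate",
    parent_moments: tuple[float, float] = PARENT_RISK_MOMENTS,
    child_moments: tuple[float, float] = CHILD_RISK_MOMENTS,
    copula_corr: float = DEFAULT_RISK_COPULA_CORR,
    misreport_rate: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Generate a complete synthetic survey dataset.

    One master seed spawns independent child streams for the design, the
    baseline risks, the latent-WTP errors, the covariates and the optional
    misreport layer, so identical seeds reproduce byte-identical datasets.
    The default sample size matches the study (n = 2211 parent-child
    households) and the default parameters are the published-fit truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params is None:
        params = default_params()
    rngs = child_rngs(seed)
    designs = draw_design(n, rngs["design"])
    risks = draw_baseline_risks(
        n, parent_moments, child_moments, copula_corr, rngs["risks"]
    )
    covs = draw_covariates(n, rngs["covariates"])
    rec = simulate_purchases(
        designs, risks, params, mode, rngs["errors"],
        misreport_rate=misreport_rate, misreport_rng=rngs["misreport"],
    )
    rec = pd.concat([rec, covs], axis=1)
    return rec[CSV_COLUMNS]


def write_records(records: pd.DataFrame, path) -> None:
    """Write household records to CSV with the documented header."""
    records.to_csv(path, index=False, float_format="%.10g")


def read_records(path) -> pd.DataFrame:
    """Read a household-record CSV produced by :func:`write_records`."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise ValueError(f"record file missing required columns: {missing}")
    return df
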