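"""Shared fixtures: simulated datasets and published-estimate fit objects."""

import numpy as np
import pandas as pd
import pytest

import mwtprisk as m

# Published interaction-specification estimates (coefficient, SE) used to
# exercise curve construction and pruning exactly as the reporting
# convention prescribes.  Interactions of delta/q with the risk-bin
# indicators are individually insignificant; main terms are strongly
# significant.
INTERACTION_FIT_PARENT = {
    "const": (-0.4289, 0.0285),
    "bin_lowest": (-0.4136, 0.0639),
    "bin_low": (-0.3075, 0.0584),
    "bin_high": (-0.1059, 0.0635),
    "delta": (0.9565, 0.0894),
    "q": (-0.0041, 0.0006),
    "delta_x_lowest": (0.2108, 0.2414),
    "delta_x_low": (0.2787, 0.2093),
    "delta_x_high": (0.2255, 0.2397),
    "q_x_lowest": (0.0003, 0.0013),
    "q_x_low": (0.0008, 0.0011),
    "q_x_high": (-0.00006, 0.0012),
}
INTERACTION_FIT_CHILD = {
    "const": (-0.3794, 0.0281),
    "bin_lowest": (-0.5244, 0.0696),
    "bin_low": (-0.4311, 0.0615),
    "bin_high": (-0.3622, 0.0635),
    "delta": (0.7500, 0.0763),
    "q": (-0.0037, 0.0005),
    "delta_x_lowest": (-0.1214, 0.2202),
    "delta_x_low": (-0.0846, 0.1955),
    "delta_x_high": (-0.1081, 0.1951),
    "q_x_lowest": (0.0017, 0.0013),
    "q_x_low": (-0.000001, 0.0011),
    "q_x_high": (-0.0009, 0.0012),
}


def make_fit(coefs_p: dict, coefs_k: dict, rho: float = 0.8983,
             spec: str = "risk_bins", n: int = 2211) -> m.FitResult:
    """Assemble a FitResult from (coefficient, SE) pairs with diagonal vcov."""
    params_p = pd.Series({k: v[0] for k, v in coefs_p.items()})
    params_k = pd.Series({k: v[0] for k, v in coefs_k.items()})
    names = [f"p:{k}" for k in coefs_p] + [f"k:{k}" for k in coefs_k] + ["rho"]
    ses = [v[1] for v in coefs_p.values()] + [v[1] for v in coefs_k.values()] + [0.0116]
    vcov = pd.DataFrame(np.diag(np.square(ses)), index=names, columns=names)
    return m.FitResult(
        spec=spec, params_p=params_p, params_k=params_k, rho=rho,
        vcov=vcov, llf=-2199.88, n=n, converged=True, n_iter=1,
        grad_norm=0.0,
    )


@pytest.fixture(scope="session")
def interaction_fit() -> m.FitResult:
    return make_fit(INTERACTION_FIT_PARENT, INTERACTION_FIT_CHILD)


@pytest.fixture(scope="session")
def records_2211() -> pd.DataFrame:
    """Default-truth synthetic survey at the study sample size."""
    return m.simulate_survey(n=2211, seed=20_211)


@pytest.fixture(scope="session")
def records_20k() -> pd.DataFrame:
    """A large sample for low-noise frequency and monotonicity checks."""
    return m.simulate_survey(n=20_000, seed=777)


@pytest.fixture(scope="session")
def base_fit_20k(records_20k) -> m.FitResult:
    design = m.build_design(records_20k, "base")
    return m.fit_bivariate_probit(design, records_20k, spec="base")
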