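"""Run orchestration, purchase-rate tabulations and report output.

Coordinates the full simulate -> fit -> MWTP-curve -> welfare pipeline from a
single config object, and produces the descriptive purchase-rate table
(proportion of parents intending to buy by price and proportionate risk
reduction, with one-tail two-proportion z-tests against the lowest price and
across risk-reduction levels).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import curves as curves_mod
from . import estimation, survey, welfare

log = logging.getLogger("mwtprisk")


# ---------------------------------------------------------------------------
# Two-proportion z-test and purchase-rate tabulation
# ---------------------------------------------------------------------------

def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int):
    """One-tail independent-samples difference-of-proportions test.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with the pooled proportion p;
    the one-tail p-value is P(Z >= z), testing H1: p1 > p2.
    """
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 observations per cell")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    denom = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if denom == 0.0:
        return 0.0, 0.5
    z = (p1 - p2) / denom
    return float(z), float(stats.norm.sf(z))


def tabulate_purchase_rates(records: pd.DataFrame) -> pd.DataFrame:
    """Purchase proportions by person, risk-reduction level and price.

    One row per (person, delta level) including an "all" margin; columns hold
    the proportion at each price, the pooled proportion, the one-tail z/p of
    each price cell against the lowest ($10) price column, and the one-tail
    z/p of high-vs-low proportionate reduction at each price.  Empty cells
    yield NaN with a warning.
    """
    prices = sorted(records["price"].unique())
    rows = []
    for person, dcol, bcol in (("parent", "delta_p", "buy_p"),
                               ("child", "delta_k", "buy_k")):
        levels = sorted(records[dcol].unique())
        for level in [*levels, "all"]:
            sub = records if level == "all" else records[records[dcol] == level]
            row: dict = {"person": person, "delta": level}
            base = sub[sub["price"] == prices[0]]
            for price in prices:
                cell = sub[sub["price"] == price]
                if len(cell) < 2:
                    log.warning("empty cell: %s delta=%s price=%s", person, level, price)
                    row[f"prop_{price:g}"] = np.nan
                    continue
                row[f"prop_{price:g}"] = cell[bcol].mean()
                if price != prices[0] and len(base) >= 2:
                    # one-tail test that purchase is MORE likely at the lowest price
                    z, p = two_proportion_ztest(
                        int(base[bcol].sum()), len(base),
                        int(cell[bcol].sum()), len(cell),
                    )
                    row[f"z_vs_low_price_{price:g}"] = z
                    row[f"p_vs_low_price_{price:g}"] = p
            row["prop_all"] = sub[bcol].mean() if len(sub) else np.nan
            rows.append(row)
        # high-vs-low proportionate reduction within each price
        hi = records[records[dcol] == levels[-1]]
        lo = records[records[dcol] == levels[0]]
        drow: dict = {"person": person, "delta": "high_vs_low"}
        for price in prices:
            h = hi[hi["price"] == price]
            l = lo[lo["price"] == price]
            if len(h) < 2 or len(l) < 2:
                log.warning("empty cell in high-vs-low: %s price=%s", person, price)
                drow[f"z_delta_{price:g}"] = np.nan
                continue
            z, p = two_proportion_ztest(
                int(h[bcol].sum()), len(h), int(l[bcol].sum()), len(l)
            )
            drow[f"z_delta_{price:g}"] = z
            drow[f"p_delta_{price:g}"] = p
        rows.append(drow)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed for a reproducible end-to-end run."""

    seed: int = 0
    n: int = 2211
    normalized_params: dict = field(
        default_factory=lambda: dict(survey.PUBLISHED_PROPORTIONATE_FIT)
    )
    parent_moments: tuple = survey.PARENT_RISK_MOMENTS
    child_moments: tuple = survey.CHILD_RISK_MOMENTS
    copula_corr: float = survey.DEFAULT_RISK_COPULA_CORR
    misreport_rate: float = 0.0
    mode: str = "proportionate"
    specs: tuple = ("base", "absolute")
    prune_alpha: float = 0.05
    welfare_from: float = 33.59
    welfare_to: float = 20.0
    outdir: str = "mwtprisk_run"

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("config.n must be >= 1")
        if not 0.0 < self.prune_alpha < 1.0:
            raise ValueError("prune_alpha must lie in (0, 1)")
        if not 0.0 < self.welfare_to < self.welfare_from <= 100.0:
            raise ValueError("need 0 < welfare_to < welfare_from <= 100")
        for s in self.specs:
            if s not in estimation.DESIGN_SPECS:
                raise ValueError(f"unknown spec '{s}'")
        survey.params_from_normalized(self.normalized_params)  # raises if invalid

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        cfg = cls(**data)
        cfg.specs = tuple(cfg.specs)
        cfg.parent_moments = tuple(cfg.parent_moments)
        cfg.child_moments = tuple(cfg.child_moments)
        return cfg

    def hash(self) -> str:
        """Stdlib-only provenance hash of the canonicalised config."""
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_CURVE_FOR_SPEC = {
    "base": "hyperbola",
    "risk_bins": "hyperbola",
    "absolute": "constant",
    "absolute_risk_bins": "step",
    "piecewise": "piecewise_linear",
}


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> fit -> MWTP grid -> welfare, writing every stage to disk.

    Outputs under ``config.outdir``: dataset.csv, purchase_rates.csv, one
    fit_<spec>.json per spec, mwtp_grid.csv, welfare.csv and run_log.json
    (master seed, config hash, stage record).  Any stage failure aborts with
    a stage-named error; identical configs reproduce identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    bundle: dict = {"config_hash": config.hash(), "seed": config.seed}

    def stage(name: str):
        stages.append(name)
        log.info("stage: %s", name)

    try:
        stage("simulate")
        params = survey.params_from_normalized(config.normalized_params)
        records = survey.simulate_survey(
            n=config.n, params=params, mode=config.mode,
            parent_moments=config.parent_moments,
            child_moments=config.child_moments,
            copula_corr=config.copula_corr,
            misreport_rate=config.misreport_rate,
            seed=config.seed,
        )
        survey.write_records(records, outdir / "dataset.csv")

        stage("tabulate")
        tabulate_purchase_rates(records).to_csv(
            outdir / "purchase_rates.csv", index=False
        )

        stage("fit")
        fits: dict[str, estimation.FitResult] = {}
        for spec_name in config.specs:
            design = estimation.build_design(records, spec_name)
            fit = fits[spec_name] = estimation.fit_bivariate_probit(
                design, records, spec=spec_name
            )
            (outdir / f"fit_{spec_name}.json").write_text(
                json.dumps(fit.to_dict(), indent=1)
            )

        stage("mwtp")
        curve_objs: dict[str, curves_mod.MWTPCurve] = {}
        grid_rows = []
        for spec_name, fit in fits.items():
            form = _CURVE_FOR_SPEC.get(spec_name)
            if form is None:
                continue
            for person in ("parent", "child"):
                curve = curves_mod.build_curve(
                    fit, form, person, config.prune_alpha
                )
                curve_objs[f"{person}_{form}"] = curve
                for r in curves_mod.REPORT_RISK_GRID:
                    grid_rows.append({
                        "person": person, "form": form, "risk": r,
                        "mwtp": curve(r),
                    })
        mwtp_grid = pd.DataFrame(grid_rows)
        mwtp_grid.to_csv(outdir / "mwtp_grid.csv", index=False)

        stage("welfare")
        wrows = []
        for name, curve in curve_objs.items():
            q = welfare.WelfareQuery(curve, config.welfare_from, config.welfare_to)
            wrows.append({
                "curve": name, "R_start": config.welfare_from,
                "R_end": config.welfare_to, "total_wtp": welfare.total_wtp(q),
            })
        pd.DataFrame(wrows).to_csv(outdir / "welfare.csv", index=False)

        stage("log")
        run_log = {
            "seed": config.seed,
            "config_hash": config.hash(),
            "config": asdict(config),
            "stages": stages,
            "n": int(len(records)),
            "fits": {s: {"llf": f.llf, "rho": f.rho, "converged": f.converged}
                     for s, f in fits.items()},
        }
        (outdir / "run_log.json").write_text(
            json.dumps(run_log, indent=1, default=list)
        )
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage '{stages[-1]}' "
            f"(completed: {stages[:-1]}); partial outputs in {outdir}"
        ) from err

    bundle.update(records=records, fits=fits, curves=curve_objs,
                  mwtp_grid=mwtp_grid, welfare=pd.DataFrame(wrows),
                  outdir=outdir)
    return bundle
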