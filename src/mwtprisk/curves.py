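"""MWTP-versus-baseline-risk curves from normalized probit coefficients.

A fitted latent-WTP probit reports normalized coefficients; because the price
coefficient equals -1/sigma, dividing any risk coefficient by the negative of
the price coefficient recovers its dollar scale.  For the proportionate
specification this yields gamma, the annual WTP for eliminating the whole
baseline risk, so gamma/100 is the MWTP per percentage point and the MWTP for
a 1-chance-in-100 (absolute) reduction at baseline risk R is gamma/R -- a
rectangular hyperbola in R.  The absolute specification instead yields a
constant MWTP per chance in 100; bin-interacted variants yield step or
continuous piecewise-linear curves.

All curve values are in dollars per 1-in-100 risk reduction per year, over
baseline risk expressed in chances in 100 on (0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .estimation import (
    CHILD_RISK_BIN_EDGES,
    PARENT_RISK_BIN_EDGES,
    RISK_BIN_LABELS,
    FitResult,
)

CURVE_FORMS = ("constant", "hyperbola", "step", "piecewise_linear")

#: Risk grid used in published-style MWTP tables: low risks, the child and
#: parent mean revised risks, and the upper range.
REPORT_RISK_GRID = (1.0, 10.0, 20.0, 24.30, 33.59, 50.0, 75.0, 100.0)


# ---------------------------------------------------------------------------
# Un-normalization arithmetic
# ---------------------------------------------------------------------------

def unnormalize(coef_risk: float, coef_price: float) -> tuple[float, float]:
    """Recover (gamma, per-point MWTP) from normalized coefficients.

    gamma = coef_risk / (-coef_price) is the dollar WTP per unit of
    proportionate reduction; gamma/100 is the annual MWTP for a one
    percentage-point reduction in baseline risk.
    """
    if coef_price >= 0:
        raise ValueError("price coefficient must be negative (-1/sigma)")
    gamma = coef_risk / (-coef_price)
    return gamma, gamma / 100.0


def mwtp_per_chance(per_point: float, R: float) -> float:
    """MWTP ($) for a 1-chance-in-100 reduction at baseline risk ``R``.

    Hyperbola evaluation: per_point * 100 / R.  At R = 100 this equals the
    per-point value itself.
    """
    if R <= 0:
        raise ValueError("baseline risk must be positive")
    return per_point * 100.0 / R


def absolute_mwtp(coef_omega: float, coef_price: float) -> float:
    """Constant MWTP ($ per 1-in-100) from the absolute-reduction spec."""
    if coef_price >= 0:
        raise ValueError("price coefficient must be negative (-1/sigma)")
    return coef_omega / (-coef_price)


# ---------------------------------------------------------------------------
# Curve object
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MWTPCurve:
    """A functional form mapping baseline risk to $ per 1-in-100 reduction.

    forms and parameters:
      constant          params["level"] = m
      hyperbola         params["scale"] = A, MWTP(R) = A/R
      step              params["edges"] (ascending interior cut points) and
                        params["levels"] (len(edges)+1 bin values, low->high)
      piecewise_linear  params["knots"], params["values"] (interpolated;
                        clamped to the outer knot values beyond the knots)
    """

    form: str
    params: dict = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        if self.form not in CURVE_FORMS:
            raise ValueError(f"form must be one of {CURVE_FORMS}")
        p = self.params
        if self.form == "constant" and "level" not in p:
            raise ValueError("constant curve needs params['level']")
        if self.form == "hyperbola" and "scale" not in p:
            raise ValueError("hyperbola curve needs params['scale']")
        if self.form == "step":
            if len(p.get("levels", ())) != len(p.get("edges", ())) + 1:
                raise ValueError("step curve needs len(levels) == len(edges)+1")
            if list(p["edges"]) != sorted(p["edges"]):
                raise ValueError("step edges must be ascending")
        if self.form == "piecewise_linear":
            if len(p.get("knots", ())) != len(p.get("values", ())):
                raise ValueError("piecewise curve needs matching knots/values")
            if list(p["knots"]) != sorted(p["knots"]):
                raise ValueError("piecewise knots must be ascending")

    def __call__(self, R):
        """Evaluate the curve at baseline risk R (chances in 100)."""
        r = np.asarray(R, dtype=float)
        if np.any(r <= 0) or np.any(r > 100):
            raise ValueError("baseline risk must lie in (0, 100]")
        if self.form == "constant":
            out = np.full_like(r, float(self.params["level"]))
        elif self.form == "hyperbola":
            out = float(self.params["scale"]) / r
        elif self.form == "step":
            idx = np.searchsorted(np.asarray(self.params["edges"], dtype=float),
                                  r, side="left")
            out = np.asarray(self.params["levels"], dtype=float)[idx]
        else:
            out = np.interp(r, np.asarray(self.params["knots"], dtype=float),
                            np.asarray(self.params["values"], dtype=float))
        return float(out) if np.isscalar(R) else out

    def to_dict(self) -> dict:
        return {"form": self.form, "params": {
            k: (list(v) if isinstance(v, (list, tuple, np.ndarray)) else v)
            for k, v in self.params.items()}, "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "MWTPCurve":
        return cls(form=d["form"], params=dict(d["params"]), label=d.get("label", ""))


def constant_curve(level: float, label: str = "") -> MWTPCurve:
    return MWTPCurve("constant", {"level": float(level)}, label)


def hyperbola_curve(scale: float, label: str = "") -> MWTPCurve:
    return MWTPCurve("hyperbola", {"scale": float(scale)}, label)


def step_curve(edges: Sequence[float], levels: Sequence[float], label: str = "") -> MWTPCurve:
    return MWTPCurve("step", {"edges": list(map(float, edges)),
                              "levels": list(map(float, levels))}, label)


def piecewise_curve(knots: Sequence[float], values: Sequence[float], label: str = "") -> MWTPCurve:
    return MWTPCurve("piecewise_linear", {"knots": list(map(float, knots)),
                                          "values": list(map(float, values))}, label)


# ---------------------------------------------------------------------------
# Reference curves (published point estimates, used in examples and tests)
# ---------------------------------------------------------------------------

def reference_step_curve(person: str) -> MWTPCurve:
    """Published step-function MWTP levels by perceived-risk bin.

    Parents: $14.20 (R <= 20), $9.59, $5.58, $2.64; children: $14.07
    (R <= 14), $10.82, $6.43, $3.95, at the standard bin cut points.
    """
    if person.startswith("p"):
        return step_curve(PARENT_RISK_BIN_EDGES, [14.20, 9.59, 5.58, 2.64],
                          "parent step (reference)")
    return step_curve(CHILD_RISK_BIN_EDGES, [14.07, 10.82, 6.43, 3.95],
                      "child step (reference)")


def reference_piecewise_curve(person: str) -> MWTPCurve:
    """Published continuous piecewise-linear MWTP values on the report grid."""
    if person.startswith("p"):
        vals = [27.85, 22.55, 16.65, 14.11, 8.51, 5.01, 3.26, 1.52]
        return piecewise_curve(REPORT_RISK_GRID, vals, "parent piecewise (reference)")
    vals = [15.02, 12.99, 9.62, 6.25, 5.04, 3.78, 1.86, -0.07]
    return piecewise_curve(REPORT_RISK_GRID, vals, "child piecewise (reference)")


# ---------------------------------------------------------------------------
# Curves from fitted models
# ---------------------------------------------------------------------------

def _pruned_coef(fit: FitResult, person: str, term: str, prune_alpha: float) -> float:
    """Coefficient, or 0 when two-sided insignificant at prune_alpha."""
    c = fit.coef(person, term)
    se = fit.coef_se(person, term)
    p = 2.0 * stats.norm.sf(abs(c) / se)
    return c if p < prune_alpha else 0.0


def build_curve(
    fit: FitResult,
    form: str,
    person: str = "parent",
    prune_alpha: float = 0.05,
) -> MWTPCurve:
    """Construct an MWTP curve for one person from a fitted specification.

    Insignificant *interaction* coefficients (two-sided p >= prune_alpha) are
    set to zero before the dollar conversion -- a reporting convention, never
    part of the likelihood.  The main risk and price terms must survive
    pruning, otherwise no curve is identified and an error is raised.
    """
    if not fit.converged:
        raise ValueError("cannot build a curve from a non-converged fit")
    if form not in CURVE_FORMS:
        raise ValueError(f"form must be one of {CURVE_FORMS}")
    who = "parent" if person.startswith("p") else "child"
    edges = PARENT_RISK_BIN_EDGES if who == "parent" else CHILD_RISK_BIN_EDGES

    def main(term: str) -> float:
        c = _pruned_coef(fit, who, term, prune_alpha)
        if c == 0.0:
            raise ValueError(
                f"main term '{term}' pruned at alpha={prune_alpha}: no curve"
            )
        return c

    if form == "hyperbola":
        # a hyperbola requires MWTP for a proportionate reduction to be
        # independent of baseline risk: any surviving delta/q interaction
        # with a risk bin contradicts that restriction
        coefs = fit.params_p if who == "parent" else fit.params_k
        survivors = [
            t for t in coefs.index
            if ("delta_x_" in t or "q_x_" in t)
            and _pruned_coef(fit, who, t, prune_alpha) != 0.0
        ]
        if survivors:
            raise ValueError(
                f"significant risk interaction terms {survivors} are "
                "inconsistent with a hyperbola in baseline risk"
            )
        gamma, _ = unnormalize(main("delta"), main("q"))
        return hyperbola_curve(gamma, f"{who} hyperbola")
    if form == "constant":
        return constant_curve(absolute_mwtp(main("omega"), main("q")),
                              f"{who} constant")
    if form == "step":
        c_omega, c_q = main("omega"), main("q")
        levels = []
        for lab in RISK_BIN_LABELS:
            dw = _pruned_coef(fit, who, f"omega_x_{lab}", prune_alpha)
            dq = _pruned_coef(fit, who, f"q_x_{lab}", prune_alpha)
            levels.append(absolute_mwtp(c_omega + dw, c_q + dq))
        levels.append(absolute_mwtp(c_omega, c_q))  # reference (highest) bin
        return step_curve(edges, levels, f"{who} step")
    # piecewise_linear: omega plus hinge interactions in R
    c_omega, c_q = main("omega"), main("q")
    hinge_coefs = [
        _pruned_coef(fit, who, f"omega_hinge_{k:g}", prune_alpha) for k in edges
    ]
    grid = [1.0, *edges, 100.0]
    values = [
        (c_omega + sum(h * max(r - k, 0.0) for h, k in zip(hinge_coefs, edges)))
        / (-c_q)
        for r in grid
    ]
    return piecewise_curve(grid, values, f"{who} piecewise")


def relative_increase(curve: MWTPCurve, R_from: float, R_to: float) -> float:
    """Percent change in MWTP moving baseline risk from R_from to R_to."""
    m_from = curve(R_from)
    if m_from == 0:
        raise ValueError("MWTP at R_from is zero; relative change undefined")
    return 100.0 * (curve(R_to) / m_from - 1.0)
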