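"""Metabolic-rate harmonization and relative resting expenditure.

Species-level basal/resting metabolic rates arrive in heterogeneous
units; they are converted to watts and regressed (ln W on ln mass, with
a measurement-type offset) under the classic two-thirds/three-quarters
scaling expectation — the slope prior is Normal(0.67, 0.1).  The sign of
a species' residual classifies it as relatively high (positive) or low
(negative) resting expenditure: the inverse proxy for surplus energy
available to fund a stress response.

The fit is a penalized point estimate: the maximum a-posteriori solution
of the Gaussian-prior linear model, computed in closed form.  Phylogeny
is intentionally absent here; relatedness enters the downstream
meta-regression instead, and including it twice would be redundant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MetabolicRecord",
    "RelativeExpenditure",
    "AllometricFit",
    "OXYJOULE_EQUIV_J_PER_ML_O2",
    "to_watts",
    "fit_allometry",
    "classify_relative_rmr",
    "read_metabolic_table",
]

#: Oxyjoule equivalent: joules liberated per mL O2 consumed (configurable).
OXYJOULE_EQUIV_J_PER_ML_O2 = 20.1

_SECONDS_PER_DAY = 86_400.0
_KJ_PER_KCAL = 4.184


@dataclass(frozen=True)
class MetabolicRecord:
    """One species-level metabolic measurement before harmonization."""

    species: str
    value: float
    units: Literal["W", "mL_O2_per_min", "mL_O2_per_h", "kJ_per_day", "kcal_per_day"]
    mtype: Literal["basal", "resting"]
    mass: float  # grams
    source: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"{self.species}: metabolic value must be positive")
        if self.mass <= 0:
            raise ValueError(f"{self.species}: mass must be positive")


@dataclass(frozen=True)
class RelativeExpenditure:
    """Sign-classified residual from the allometric fit (ln-W scale)."""

    species: str
    residual: float
    category: Literal["high", "low"]


def to_watts(
    rec: MetabolicRecord,
    rq_joule_equiv: float = OXYJOULE_EQUIV_J_PER_ML_O2,
) -> float:
    """Convert a metabolic measurement to watts."""
    if rec.units == "W":
        return rec.value
    if rec.units == "mL_O2_per_min":
        return rec.value * rq_joule_equiv / 60.0
    if rec.units == "mL_O2_per_h":
        return rec.value * rq_joule_equiv / 3600.0
    if rec.units == "kJ_per_day":
        return rec.value * 1000.0 / _SECONDS_PER_DAY
    if rec.units == "kcal_per_day":
        return rec.value * _KJ_PER_KCAL * 1000.0 / _SECONDS_PER_DAY
    raise ValueError(f"unknown metabolic unit: {rec.units!r}")


@dataclass
class AllometricFit:
    """MAP estimates of the ln-W ~ ln-mass scaling model."""

    intercept: float
    slope: float
    mtype_offset: float  # additive shift for 'resting' relative to 'basal'
    sigma: float
    species: list[str] = field(default_factory=list)
    residuals: dict[str, float] = field(default_factory=dict)

    def predict(self, ln_mass: float, mtype: str = "basal") -> float:
        shift = self.mtype_offset if mtype == "resting" else 0.0
        return self.intercept + self.slope * ln_mass + shift


def fit_allometry(
    recs: Sequence[MetabolicRecord],
    *,
    slope_prior: tuple[float, float] = (0.67, 0.1),
    intercept_prior_sd: float = math.inf,
    mtype_prior_sd: float = 1.0,
    rq_joule_equiv: float = OXYJOULE_EQUIV_J_PER_ML_O2,
) -> AllometricFit:
    """Fit ln(W) = a + b ln(mass) + d * 1[resting] by penalized least squares.

    ``slope_prior`` is the (mean, sd) of the Gaussian slope prior; the
    intercept and measurement-type offset get weak Gaussian priors.  The
    penalty is calibrated against the residual variance, so the point
    estimate is the MAP of the corresponding Bayesian linear model with
    sigma plugged in (two-pass: OLS residual scale, then the penalized
    solve).  Residuals are ordinary: observed minus fitted, per species.
    """
    if len({r.species for r in recs}) < 3:
        raise ValueError("allometric fit needs at least 3 distinct species")
    ln_w = np.array([math.log(to_watts(r, rq_joule_equiv)) for r in recs])
    ln_m = np.array([math.log(r.mass) for r in recs])
    is_resting = np.array([1.0 if r.mtype == "resting" else 0.0 for r in recs])
    if np.ptp(ln_m) == 0:
        raise ValueError("all records share one mass: no scaling information")
    X = np.column_stack([np.ones_like(ln_m), ln_m, is_resting])

    # pass 1: unpenalized scale estimate for calibrating the prior weight
    coef_ols, *_ = np.linalg.lstsq(X, ln_w, rcond=None)
    resid_ols = ln_w - X @ coef_ols
    dof = max(len(recs) - X.shape[1], 1)
    sigma2 = float(resid_ols @ resid_ols) / dof
    sigma2 = max(sigma2, 1e-12)  # noise-free data: vanishing penalty

    prior_mean = np.array([0.0, slope_prior[0], 0.0])
    # flat default intercept prior keeps the residuals summing exactly to zero
    icpt_prec = 0.0 if math.isinf(intercept_prior_sd) else 1.0 / intercept_prior_sd**2
    prior_prec = np.diag(
        [icpt_prec, 1.0 / slope_prior[1] ** 2, 1.0 / mtype_prior_sd**2]
    )
    A = X.T @ X / sigma2 + prior_prec
    rhs = X.T @ ln_w / sigma2 + prior_prec @ prior_mean
    coef = np.linalg.solve(A, rhs)
    fitted = X @ coef
    resid = ln_w - fitted
    sigma = math.sqrt(float(resid @ resid) / dof)

    residuals: dict[str, float] = {}
    for r, e in zip(recs, resid):
        residuals[r.species] = float(e)  # one value per species expected
    return AllometricFit(
        intercept=float(coef[0]),
        slope=float(coef[1]),
        mtype_offset=float(coef[2]),
        sigma=sigma,
        species=[r.species for r in recs],
        residuals=residuals,
    )


def classify_relative_rmr(
    fit: AllometricFit,
    recs: Optional[Iterable[MetabolicRecord]] = None,
    *,
    rq_joule_equiv: float = OXYJOULE_EQUIV_J_PER_ML_O2,
) -> tuple[dict[str, RelativeExpenditure], list[str]]:
    """Classify species by residual sign; returns (classification, warnings).

    With no ``recs``, the residuals stored on the fit are classified.  A
    residual of exactly zero goes to "low" — an arbitrary but
    deterministic tie-break, reported in the warning list.
    """
    warnings: list[str] = []
    residuals: dict[str, float]
    if recs is None:
        residuals = dict(fit.residuals)
    else:
        residuals = {}
        for r in recs:
            pred = fit.predict(math.log(r.mass), r.mtype)
            residuals[r.species] = math.log(to_watts(r, rq_joule_equiv)) - pred
    out: dict[str, RelativeExpenditure] = {}
    for sp, res in residuals.items():
        if res == 0.0:
            warnings.append(f"{sp}: residual exactly 0, classified 'low'")
        cat = "high" if res > 0 else "low"
        out[sp] = RelativeExpenditure(species=sp, residual=res, category=cat)
    return out, warnings


def read_metabolic_table(path) -> list[MetabolicRecord]:
    """Metabolic-rate CSV: species, value, units, mtype, mass[, source]."""
    df = pd.read_csv(path)
    required = {"species", "value", "units", "mtype", "mass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metabolic table missing columns: {sorted(missing)}")
    return [
        MetabolicRecord(
            species=row.species,
            value=float(row.value),
            units=row.units,
            mtype=row.mtype,
            mass=float(row.mass),
            source=getattr(row, "source", "") or "",
        )
        for row in df.itertuples()
    ]


def categories_to_binary(
    classification: Mapping[str, RelativeExpenditure]
) -> dict[str, int]:
    """Map species -> 1 (high expenditure) / 0 (low), for the design matrix."""
    return {
        sp: 1 if rel.category == "high" else 0
        for sp, rel in classification.items()
    }
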