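"""Log response ratios, pooled standard errors, and the deg-C conversion.

The meta-analytic effect size is the natural log of the ratio of
post-stress (or stressed-arm) to baseline (or control-arm) body
temperature, both in deg C:

    lRR = ln(T_b1 / T_b0)          (pre/post design)
    lRR = ln(T_b1S / T_b1C)        (stressed vs control design)

Its uncertainty is the pooled standard error, printed as a SUM of
SE-to-mean ratios:

    se = se_num / T_num + se_den / T_den

with a quadrature (delta-method) alternative available for sensitivity
analysis.  A reported pooled SE, when present, passes through unchanged.
Temperature changes convert to and from the log scale at a stated
baseline via dT = tb0 * (exp(lRR) - 1); the meta-analysis reports them
at the 38 deg C convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from stresstherm.io_schema import Dataset, ObservationRecord, ValidationFailure

__all__ = [
    "EffectSize",
    "response_ratio",
    "pooled_se",
    "corrected_lrr",
    "delta_t_from_lrr",
    "lrr_from_delta_t",
    "add_effect_sizes",
]


@dataclass(frozen=True)
class EffectSize:
    """A log response ratio with its pooled standard error."""

    lrr: float
    se: float | None
    design: Literal["pre_post", "stressed_vs_control"]
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.se is not None and self.se < 0:
            raise ValidationFailure("pooled se must be non-negative")


def response_ratio(rec: ObservationRecord) -> EffectSize:
    """The log response ratio of a record (no uncertainty attached)."""
    if rec.tb_response <= 0 or rec.tb_baseline <= 0:
        raise ValidationFailure(
            f"{rec.record_id}: non-positive temperature, log-ratio undefined"
        )
    lrr = math.log(rec.tb_response / rec.tb_baseline)
    return EffectSize(lrr=lrr, se=None, design=rec.design)


def _arm_ses(rec: ObservationRecord) -> tuple[float, float]:
    """Standard errors of the numerator and denominator means.

    Record dispersions are standard deviations; each arm's SE is
    sd / sqrt(n) with the record's single reported group size.
    """
    if rec.tb_response_sd is None or rec.tb_baseline_sd is None:
        missing = [
            name
            for name, v in (
                ("tb_response_sd", rec.tb_response_sd),
                ("tb_baseline_sd", rec.tb_baseline_sd),
            )
            if v is None
        ]
        raise ValidationFailure(f"{rec.record_id}: missing dispersion {missing}")
    root_n = math.sqrt(rec.n_individuals)
    return rec.tb_response_sd / root_n, rec.tb_baseline_sd / root_n


def pooled_se(
    rec: ObservationRecord, *, form: Literal["sum", "quadrature"] = "sum"
) -> float:
    """Pooled standard error of the record's log response ratio.

    A reported pooled SE takes precedence over the derived forms.
    """
    if rec.pooled_se_reported is not None:
        return rec.pooled_se_reported
    se_num, se_den = _arm_ses(rec)
    r_num = se_num / rec.tb_response
    r_den = se_den / rec.tb_baseline
    if form == "sum":
        return r_num + r_den
    if form == "quadrature":
        return math.sqrt(r_num**2 + r_den**2)
    raise ValueError(f"unknown pooled-SE form: {form!r}")


def corrected_lrr(
    rec: ObservationRecord, *, se_form: Literal["sum", "quadrature"] = "sum"
) -> EffectSize:
    """Small-sample bias-corrected log response ratio (RR-delta).

    Adds half the difference of the squared coefficients of variation
    scaled by group size:

        lrr_corr = lrr + (sd_num^2 / (n T_num^2) - sd_den^2 / (n T_den^2)) / 2
    """
    base = response_ratio(rec)
    if rec.tb_response_sd is None or rec.tb_baseline_sd is None:
        raise ValidationFailure(
            f"{rec.record_id}: RR-delta needs both arm dispersions"
        )
    n = rec.n_individuals
    term = 0.5 * (
        rec.tb_response_sd**2 / (n * rec.tb_response**2)
        - rec.tb_baseline_sd**2 / (n * rec.tb_baseline**2)
    )
    return EffectSize(
        lrr=base.lrr + term,
        se=pooled_se(rec, form=se_form),
        design=rec.design,
        corrected=True,
    )


def delta_t_from_lrr(lrr: float, tb0: float = 38.0) -> float:
    """Absolute body-temperature change (deg C) implied by a log response
    ratio at baseline ``tb0`` (the analysis convention is 38 deg C)."""
    if tb0 <= 0:
        raise ValidationFailure("baseline temperature must be positive")
    return tb0 * (math.exp(lrr) - 1.0)


def lrr_from_delta_t(delta_t: float, tb0: float = 38.0) -> float:
    """Inverse of :func:`delta_t_from_lrr`; round-trips to ~1e-12."""
    if tb0 <= 0:
        raise ValidationFailure("baseline temperature must be positive")
    if delta_t <= -tb0:
        raise ValidationFailure("temperature change exceeds the baseline scale")
    return math.log1p(delta_t / tb0)


def add_effect_sizes(
    ds: Dataset,
    *,
    se_form: Literal["sum", "quadrature"] = "sum",
    corrected: bool = False,
) -> pd.DataFrame:
    """Observation table augmented with lrr / lrr_se (/ lrr_corrected).

    The corrected column is only attached when requested, since it needs
    arm dispersions that a reported-pooled-SE record may lack.
    """
    df = ds.to_dataframe()
    lrrs, ses, corrs = [], [], []
    for rec in ds.records:
        lrrs.append(response_ratio(rec).lrr)
        ses.append(pooled_se(rec, form=se_form))
        if corrected:
            corrs.append(corrected_lrr(rec, se_form=se_form).lrr)
    df["lrr"] = lrrs
    df["lrr_se"] = ses
    if corrected:
        df["lrr_corrected"] = corrs
    return df
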