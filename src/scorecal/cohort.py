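"""Applying the calibrated risk function to survey microdata.

Pipeline: eligibility filtering (missing data first, then prior CVD, then
age), per-person 10-year risk at the exact recorded age via the direct
formula (never chart readings), and survey-weighted summaries — mean risk
and high-risk prevalence (risk >= 5% by guideline convention) with
Taylor-linearized confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import Method, ten_year_risk
from .domain import Coefficients, CholMeasure, MortalityTable, RiskFactorMeans, RiskProfile, SEXES
from .errors import ValidationError

log = logging.getLogger(__name__)

HIGH_RISK_THRESHOLD = 0.05

#: Variables required to compute a SCORE-style risk for a record.
SCORE_VARS = ("age", "sex", "sbp", "tc", "hdl", "smoker")
PRIOR_CVD_FLAGS = ("prior_chd", "prior_stroke", "prior_hf")


@dataclass
class CohortRecord:
    """One survey participant. ``None`` marks a missing value."""

    id: str
    age: float | None = None
    sex: str | None = None
    sbp: float | None = None
    tc: float | None = None
    hdl: float | None = None
    smoker: bool | None = None
    weight: float | None = None
    prior_chd: bool | None = None
    prior_stroke: bool | None = None
    prior_hf: bool | None = None

    def missing_fields(self) -> list[str]:
        out = [v for v in SCORE_VARS if getattr(self, v) is None]
        out += [v for v in PRIOR_CVD_FLAGS if getattr(self, v) is None]
        if self.weight is None or (self.weight is not None and self.weight <= 0):
            out.append("weight")
        if self.hdl is not None and self.hdl <= 0:
            out.append("hdl")
        if self.sex is not None and self.sex not in SEXES:
            out.append("sex")
        return out

    def has_prior_cvd(self) -> bool:
        return any(bool(getattr(self, f)) for f in PRIOR_CVD_FLAGS)


@dataclass
class EligibilityReport:
    """Sequential exclusion tally: missing data, then prior CVD, then age."""

    n_input: int
    n_excluded_missing: int
    n_excluded_prior_cvd: int
    n_excluded_age: int
    n_eligible: int
    dispositions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (self.n_excluded_missing + self.n_excluded_prior_cvd
                 + self.n_excluded_age + self.n_eligible)
        if total != self.n_input:
            raise ValidationError("eligibility tallies must sum to n_input")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_missing": self.n_excluded_missing,
            "n_excluded_prior_cvd": self.n_excluded_prior_cvd,
            "n_excluded_age": self.n_excluded_age,
            "n_eligible": self.n_eligible,
        }


def filter_cohort(
    records: Sequence[CohortRecord],
    age_min: float = 40.0,
    age_max: float = 65.0,
) -> tuple[list[CohortRecord], EligibilityReport]:
    """Apply the exclusion cascade in its fixed order.

    A record failing several rules is counted once, at the first rule it
    fails: missing data on any SCORE variable or prior-CVD flag, then any
    prior-CVD flag set, then age outside [age_min, age_max].
    """
    eligible: list[CohortRecord] = []
    disp: dict[str, str] = {}
    n_miss = n_cvd = n_age = 0
    for r in records:
        if r.missing_fields():
            n_miss += 1
            disp[r.id] = "excluded_missing"
        elif r.has_prior_cvd():
            n_cvd += 1
            disp[r.id] = "excluded_prior_cvd"
        elif not age_min <= r.age <= age_max:
            n_age += 1
            disp[r.id] = "excluded_age"
        else:
            eligible.append(r)
            disp[r.id] = "eligible"
    report = EligibilityReport(
        n_input=len(records),
        n_excluded_missing=n_miss,
        n_excluded_prior_cvd=n_cvd,
        n_excluded_age=n_age,
        n_eligible=len(eligible),
        dispositions=disp,
    )
    return eligible, report


def apply_risk(
    records: Sequence[CohortRecord],
    table: MortalityTable,
    means: RiskFactorMeans,
    coefs: Coefficients,
    chol_measure: CholMeasure = CholMeasure.TC,
    method: Method = "constant",
) -> np.ndarray:
    """Per-record 10-year risk at the exact recorded age.

    The ratio chart uses per-person tc/hdl. Errors from the risk engine
    carry the offending record's id.
    """
    out = np.empty(len(records))
    for i, r in enumerate(records):
        chol = r.tc if chol_measure is CholMeasure.TC else r.tc / r.hdl
        profile = RiskProfile(
            sex=r.sex, age=r.age, sbp=r.sbp, chol_value=chol,
            chol_measure=chol_measure, smoker=bool(r.smoker),
        )
        try:
            out[i] = ten_year_risk(profile, table, means, coefs, method)
        except ValidationError as e:
            raise ValidationError(f"record {r.id}: {e}") from e
    return out


@dataclass
class WeightedEstimate:
    """A survey-weighted point estimate with a normal-approximation CI."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_unweighted: int
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError("se must be non-negative")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValidationError("estimate must lie inside its CI")

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_unweighted": self.n_unweighted,
            "ci_level": self.ci_level,
        }


def _weighted_ratio_estimate(
    y: np.ndarray, w: np.ndarray, ci_level: float, clip_unit: bool
) -> WeightedEstimate:
    """Hajek estimator sum(w y)/sum(w) with Taylor-linearized SE.

    Each record is treated as its own sampling unit (no strata/clusters);
    the linearized influence of record i is w_i (y_i - estimate) / sum(w),
    and the variance estimate carries the usual n/(n-1) factor. Invariant
    under rescaling all weights by a positive constant.
    """
    n = y.size
    if n == 0:
        raise ValidationError("empty input")
    if np.any(w <= 0):
        raise ValidationError("weights must be strictly positive")
    wsum = w.sum()
    if wsum <= 0:
        raise ValidationError("total weight must be positive")
    est = float(np.dot(w, y) / wsum)
    if n == 1:
        se = 0.0
    else:
        infl = w * (y - est) / wsum
        se = float(math.sqrt(n / (n - 1) * np.sum(infl**2)))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    lo, hi = est - z * se, est + z * se
    if clip_unit:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return WeightedEstimate(
        estimate=est, se=se, ci_low=lo, ci_high=hi,
        n_unweighted=n, ci_level=ci_level,
    )


def weighted_mean_risk(
    risks: np.ndarray,
    weights: np.ndarray,
    ci_level: float = 0.95,
) -> WeightedEstimate:
    """Survey-weighted mean 10-year risk with linearized CI."""
    risks = np.asarray(risks, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if risks.shape != weights.shape:
        raise ValidationError("risks and weights must align")
    return _weighted_ratio_estimate(risks, weights, ci_level, clip_unit=True)


def weighted_high_risk_prevalence(
    risks: np.ndarray,
    weights: np.ndarray,
    threshold: float = HIGH_RISK_THRESHOLD,
    ci_level: float = 0.95,
) -> WeightedEstimate:
    """Survey-weighted proportion with risk >= threshold (inclusive)."""
    risks = np.asarray(risks, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if risks.shape != weights.shape:
        raise ValidationError("risks and weights must align")
    ind = (risks >= threshold).astype(float)
    return _weighted_ratio_estimate(ind, weights, ci_level, clip_unit=True)


def summarize_by_group(
    records: Sequence[CohortRecord],
    risks: np.ndarray,
    threshold: float = HIGH_RISK_THRESHOLD,
    ci_level: float = 0.95,
) -> dict:
    """Weighted mean risk and high-risk prevalence overall and by
    sex x 5-year age group."""
    w = np.array([r.weight for r in records], dtype=float)
    out = {
        "overall": {
            "mean_risk": weighted_mean_risk(risks, w, ci_level).to_dict(),
            "high_risk_prevalence": weighted_high_risk_prevalence(
                risks, w, threshold, ci_level
            ).to_dict(),
        },
        "by_group": {},
    }
    for sex in SEXES:
        for start in range(40, 66, 5):
            sel = np.array(
                [r.sex == sex and start <= r.age < start + 5 for r in records]
            )
            if not sel.any():
                continue
            key = f"{sex}_{start}-{start + 4}"
            out["by_group"][key] = {
                "mean_risk": weighted_mean_risk(risks[sel], w[sel], ci_level).to_dict(),
                "high_risk_prevalence": weighted_high_risk_prevalence(
                    risks[sel], w[sel], threshold, ci_level
                ).to_dict(),
            }
    return out
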