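"""Synthetic study data with the structure the calibration assumes.

Generators for (1) national-style mortality tables with Gompertz-increasing
cause-specific rates, (2) survey microdata with approximately normal SBP
and cholesterol, Bernoulli smoking, log-normal survey weights and planted
missingness / prior-CVD flags, (3) weighted band means estimated back from
microdata, and (4) a Monte-Carlo two-cause piecewise-exponential lifetime
simulator used as the independent correctness oracle for the analytic
cumulative-incidence engine.

Every stochastic operation takes its randomness from ``SimParams.seed``;
identical parameters give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .domain import (
    AgeBand,
    BandHazards,
    CoefficientSet,
    Coefficients,
    MeansEntry,
    MortalityEntry,
    MortalityTable,
    RiskFactorMeans,
    SEXES,
)
from .cohort import CohortRecord
from .errors import ValidationError


def default_coefficients() -> Coefficients:
    """Illustrative log hazard ratios for synthetic experiments.

    Magnitudes are epidemiologically plausible (~1.6%/mmHg SBP, ~28%/mmol/L
    TC, doubling for smoking); real chart production must supply externally
    derived coefficients via configuration.
    """
    return Coefficients(
        shared=CoefficientSet(beta_sbp=0.015, beta_tc=0.25, beta_ratio=0.15, beta_smoke=0.71),
        provenance="synthetic illustrative values",
    )


@dataclass
class SimParams:
    """Generator settings; defaults emulate a contemporary Western-European
    middle-aged population with declining-CVD-era mortality.

    Gompertz rates: annual rate at band midpoint age a is
    ``m0 * exp(gamma * (a - 40)) * sex_multiplier``.
    """

    # mortality (annual rates at age 40; log-slope per year of age)
    m0_cvd: float = 2e-4
    m0_noncvd: float = 1.2e-3
    gamma_cvd: float = 0.095
    gamma_noncvd: float = 0.075
    sex_mult_cvd: dict = field(default_factory=lambda: {"female": 0.55, "male": 1.0})
    sex_mult_noncvd: dict = field(default_factory=lambda: {"female": 0.65, "male": 1.0})
    population_per_cell: float = 100_000.0
    deterministic_mortality: bool = True  # expected counts instead of Poisson draws

    # risk factors (means at age 40; linear trend per year of age)
    sbp_mean: dict = field(default_factory=lambda: {"female": 124.0, "male": 130.0})
    sbp_trend: float = 0.5          # mmHg per year of age
    sbp_sd: float = 17.0
    tc_mean: dict = field(default_factory=lambda: {"female": 5.5, "male": 5.6})
    tc_trend: float = 0.02          # mmol/L per year of age
    tc_sd: float = 1.0
    hdl_mean: dict = field(default_factory=lambda: {"female": 1.6, "male": 1.3})
    hdl_sd: float = 0.35
    smoking_prev: dict = field(default_factory=lambda: {"female": 0.26, "male": 0.32})

    # survey structure
    weight_lognorm_mu: float = 0.0
    weight_lognorm_sigma: float = 0.5
    missing_rate: float = 0.0
    prior_cvd_rate: float = 0.0
    age_min: float = 40.0
    age_max: float = 75.0           # exclusive; covers the full horizon grid
    n: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if min(self.m0_cvd, self.m0_noncvd) < 0 or self.n < 1:
            raise ValidationError("rates must be non-negative and n >= 1")
        if min(self.sbp_sd, self.tc_sd, self.hdl_sd) <= 0:
            raise ValidationError("standard deviations must be positive")
        for p in (self.missing_rate, self.prior_cvd_rate, *self.smoking_prev.values()):
            if not 0 <= p <= 1:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.population_per_cell <= 0:
            raise ValidationError("population_per_cell must be positive")

    def to_json_dict(self) -> dict:
        return asdict(self)

    def expected_rate(self, cause: str, sex: str, age: float) -> float:
        """Expected annual rate at exact age for one cause."""
        if cause == "cvd":
            return self.m0_cvd * math.exp(self.gamma_cvd * (age - 40.0)) * self.sex_mult_cvd[sex]
        return (
            self.m0_noncvd
            * math.exp(self.gamma_noncvd * (age - 40.0))
            * self.sex_mult_noncvd[sex]
        )

    def expected_sbp(self, sex: str, age: float) -> float:
        return self.sbp_mean[sex] + self.sbp_trend * (age - 40.0)

    def expected_tc(self, sex: str, age: float) -> float:
        return self.tc_mean[sex] + self.tc_trend * (age - 40.0)


def synth_mortality(params: SimParams) -> MortalityTable:
    """Mortality table over bands 40-44 ... 70-74 for both sexes.

    The Gompertz rate is evaluated at each band's midpoint. Deterministic
    mode stores expected death counts; otherwise counts are Poisson draws
    seeded from ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    entries: dict[tuple[str, int], MortalityEntry] = {}
    for sex in SEXES:
        for start in range(40, 75, 5):
            mid = AgeBand(start).midpoint
            pop = params.population_per_cell
            mu_cvd = params.expected_rate("cvd", sex, mid) * pop
            mu_non = params.expected_rate("noncvd", sex, mid) * pop
            if params.deterministic_mortality:
                d_cvd, d_non = mu_cvd, mu_non
            else:
                d_cvd = float(rng.poisson(mu_cvd))
                d_non = float(rng.poisson(mu_non))
            entries[(sex, start)] = MortalityEntry(d_cvd, d_non, pop)
    return MortalityTable(entries=entries)


def synth_survey(params: SimParams) -> tuple[list[CohortRecord], dict]:
    """Survey microdata with ground truth for filter and recovery tests.

    Returns ``(records, truth)`` where ``truth`` holds the planted
    disposition per record id (``eligible`` / ``excluded_missing`` /
    ``excluded_prior_cvd`` / ``excluded_age`` evaluated in the standard
    cascade order with age limits 40-65) and the configured cell means.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n
    sex_arr = rng.choice(SEXES, size=n)
    age = rng.uniform(params.age_min, params.age_max, size=n)
    sbp = np.empty(n)
    tc = np.empty(n)
    hdl = np.empty(n)
    smoker = np.empty(n, dtype=bool)
    for sex in SEXES:
        m = sex_arr == sex
        k = int(m.sum())
        sbp[m] = rng.normal(params.sbp_mean[sex] + params.sbp_trend * (age[m] - 40.0),
                            params.sbp_sd, size=k)
        tc[m] = rng.normal(params.tc_mean[sex] + params.tc_trend * (age[m] - 40.0),
                           params.tc_sd, size=k)
        hdl[m] = rng.normal(params.hdl_mean[sex], params.hdl_sd, size=k)
        smoker[m] = rng.random(k) < params.smoking_prev[sex]
    sbp = np.clip(sbp, 61.0, 249.0)
    tc = np.clip(tc, 1.5, 14.0)
    hdl = np.maximum(hdl, 0.3)  # truncation keeps the ratio finite
    weight = rng.lognormal(params.weight_lognorm_mu, params.weight_lognorm_sigma, size=n)
    prior = rng.random((n, 3)) < params.prior_cvd_rate
    miss_record = rng.random(n) < params.missing_rate
    miss_field = rng.integers(0, 4, size=n)  # which SCORE variable to blank

    records: list[CohortRecord] = []
    dispositions: dict[str, str] = {}
    miss_names = ("sbp", "tc", "hdl", "smoker")
    for i in range(n):
        rid = f"P{i:06d}"
        rec = CohortRecord(
            id=rid,
            age=float(age[i]),
            sex=str(sex_arr[i]),
            sbp=float(sbp[i]),
            tc=float(tc[i]),
            hdl=float(hdl[i]),
            smoker=bool(smoker[i]),
            weight=float(weight[i]),
            prior_chd=bool(prior[i, 0]),
            prior_stroke=bool(prior[i, 1]),
            prior_hf=bool(prior[i, 2]),
        )
        if miss_record[i]:
            setattr(rec, miss_names[int(miss_field[i])], None)
            dispositions[rid] = "excluded_missing"
        elif prior[i].any():
            dispositions[rid] = "excluded_prior_cvd"
        elif not 40.0 <= age[i] <= 65.0:
            dispositions[rid] = "excluded_age"
        else:
            dispositions[rid] = "eligible"
        records.append(rec)
    truth = {"dispositions": dispositions, "params": params}
    return records, truth


def estimate_means(records: list[CohortRecord], bands: list[int] | None = None) -> RiskFactorMeans:
    """Weighted risk-factor means per sex x 5-year band.

    Weighted means within constant 5-year age groups are the saturated
    equivalent of a banded regression of each factor on age group. The
    ratio is averaged as the mean of per-person tc/hdl. Records with any
    missing required field are dropped; an empty required cell is an error.
    """
    if bands is None:
        bands = list(range(40, 75, 5))
    entries: dict[tuple[str, int], MeansEntry] = {}
    for sex in SEXES:
        for start in bands:
            sel = [
                r for r in records
                if r.sex == sex and r.age is not None and start <= r.age < start + 5
                and None not in (r.sbp, r.tc, r.hdl, r.smoker, r.weight)
            ]
            if not sel:
                raise ValidationError(f"no usable records in cell sex={sex!r}, band {AgeBand(start)}")
            w = np.array([r.weight for r in sel])
            wsum = w.sum()
            entries[(sex, start)] = MeansEntry(
                mean_sbp=float(np.dot(w, [r.sbp for r in sel]) / wsum),
                mean_tc=float(np.dot(w, [r.tc for r in sel]) / wsum),
                mean_ratio=float(np.dot(w, [r.tc / r.hdl for r in sel]) / wsum),
                smoking_prev=float(np.dot(w, [float(r.smoker) for r in sel]) / wsum),
            )
    return RiskFactorMeans(entries=entries)


def band_means_entry_counts(records: list[CohortRecord]) -> dict[tuple[str, int], int]:
    """Unweighted usable-record count per sex x band (for SE checks)."""
    counts: dict[tuple[str, int], int] = {}
    for r in records:
        if r.age is None or r.sex is None:
            continue
        if None in (r.sbp, r.tc, r.hdl, r.smoker, r.weight):
            continue
        start = int(r.age // 5) * 5
        counts[(r.sex, start)] = counts.get((r.sex, start), 0) + 1
    return counts


def simulate_deaths(
    profile_hazards: list[BandHazards],
    n: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo fraction dying of CVD over the horizon, with binomial SE.

    Each individual walks the piecewise-constant two-cause exponential
    model: within a band, times to CVD and non-CVD death are independent
    exponentials at the band's hazards; the earlier one, if it falls inside
    the band's exposure, fixes the cause; survivors advance to the next
    band. Fully vectorised over individuals.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    alive = np.ones(n, dtype=bool)
    died_cvd = np.zeros(n, dtype=bool)
    for bh in profile_hazards:
        k = int(alive.sum())
        if k == 0:
            break
        with np.errstate(divide="ignore"):
            t_cvd = (rng.exponential(1.0, size=k) / bh.h_cvd
                     if bh.h_cvd > 0 else np.full(k, np.inf))
            t_non = (rng.exponential(1.0, size=k) / bh.h_noncvd
                     if bh.h_noncvd > 0 else np.full(k, np.inf))
        t_min = np.minimum(t_cvd, t_non)
        event = t_min < bh.exposure
        cvd_event = event & (t_cvd <= t_non)
        idx = np.flatnonzero(alive)
        died_cvd[idx[cvd_event]] = True
        alive[idx[event]] = False
    frac = float(died_cvd.sum()) / n
    se = math.sqrt(max(frac * (1.0 - frac), 1.0 / n) / n)
    return frac, se
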