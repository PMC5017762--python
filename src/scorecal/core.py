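"""Competing-risks 10-year risk of fatal CVD.

The model: within each 5-year age band, death from CVD and death from any
other cause act as two competing exponential clocks with constant annual
cause-specific hazards. The band's CVD hazard for an individual is the
observed national rate for that band multiplied by the individual's hazard
ratio exp(beta'(x - xbar)) relative to the band's population means; the
competing (non-CVD) hazard is the observed rate unmodified. Chaining the
per-band cumulative incidence contributions over the 10-year horizon gives
the absolute risk of dying of CVD within 10 years in the presence of the
competing cause.

Two variants are provided:

* ``ten_year_risk_constant`` — rates held constant within each band (the
  band partition of the horizon is exact; no interpolation). This is the
  default method: piecewise-constant rates are the Markov-consistent
  reading of band-aggregated mortality data.
* ``ten_year_risk_interpolated`` — the legacy variant for sensitivity
  comparison: annual rates linearly interpolated in age between band
  midpoints, chained in 1-year steps, constant extrapolation beyond the
  outermost midpoints.
"""

from __future__ import annotations

import math
from typing import Literal

from .domain import (
    AgeBand,
    BandHazards,
    Coefficients,
    CholMeasure,
    MortalityTable,
    RiskFactorMeans,
    RiskProfile,
)
from .errors import ConfigurationError, ValidationError

HORIZON_YEARS = 10.0

Method = Literal["constant", "interpolated"]


def band_rates(table: MortalityTable, sex: str, band: AgeBand) -> tuple[float, float]:
    """Observed annual cause-specific mortality rates ``(m_cvd, m_noncvd)``.

    ``m = deaths / population``; rates are treated as annual hazards
    directly (see :func:`annualize` for the strict conversion option).
    """
    e = table.entry(sex, band)
    return e.deaths_cvd / e.population, e.deaths_noncvd / e.population


def annualize(m: float, strict: bool = False) -> float:
    """Map an observed annual death proportion to an annual hazard.

    With ``strict=False`` (default) the rate is used as the hazard, valid
    to first order for the small rates (< 0.05/y) this model targets.
    ``strict=True`` applies the exact conversion ``-log(1 - m)``.
    """
    if strict:
        return -math.log1p(-m)
    return m


def hazard_ratio(
    profile: RiskProfile,
    means: RiskFactorMeans,
    coefs: Coefficients,
    band: AgeBand,
) -> float:
    """Relative CVD-mortality risk exp(beta'(x - xbar)) against band means.

    The smoking indicator (1/0) is centred on the band's smoking
    prevalence, symmetrically with the continuous factors, so a profile
    exactly at the band means has hazard ratio 1.
    """
    xbar = means.entry(profile.sex, band)
    cs = coefs.for_sex(profile.sex)
    try:
        beta_chol = cs.beta_chol(profile.chol_measure)
    except AttributeError:  # pragma: no cover - defensive
        raise ConfigurationError(
            f"no cholesterol coefficient resolvable for measure {profile.chol_measure}"
        )
    lp = (
        cs.beta_sbp * (profile.sbp - xbar.mean_sbp)
        + beta_chol * (profile.chol_value - xbar.chol_mean(profile.chol_measure))
        + cs.beta_smoke * (float(profile.smoker) - xbar.smoking_prev)
    )
    return math.exp(lp)


def horizon_bands(age: float, table: MortalityTable, sex: str) -> list[tuple[AgeBand, float]]:
    """Partition the 10-year horizon [age, age+10) by the 5-year band grid.

    Returns ``(band, exposure)`` pairs whose exposures sum to exactly 10
    years: two full bands for chart-aligned entry ages (multiples of 5),
    three segments otherwise.
    """
    if not 40 <= age <= 65:
        raise ValidationError(f"entry age {age} outside [40, 65]")
    table.require_coverage(sex, age, age + HORIZON_YEARS)
    out: list[tuple[AgeBand, float]] = []
    t = float(age)
    end = age + HORIZON_YEARS
    while t < end - 1e-12:
        band = AgeBand.containing(t)
        seg_end = min(band.end, end)
        out.append((band, seg_end - t))
        t = seg_end
    # guard against float drift in the partition
    total = sum(e for _, e in out)
    assert abs(total - HORIZON_YEARS) < 1e-9
    return out


def cif_band(h_cvd: float, h_noncvd: float, exposure: float) -> float:
    """P(die of CVD within the band | alive at band start).

    Closed form for two competing constant hazards:
    ``(h_cvd / h) * (1 - exp(-h * exposure))`` with ``h = h_cvd + h_noncvd``;
    0 when both hazards vanish.
    """
    if h_cvd < 0 or h_noncvd < 0:
        raise ValidationError("hazards must be non-negative")
    if exposure <= 0:
        raise ValidationError("exposure must be positive")
    h = h_cvd + h_noncvd
    if h == 0.0:
        return 0.0
    return (h_cvd / h) * -math.expm1(-h * exposure)


def profile_band_hazards(
    profile: RiskProfile,
    table: MortalityTable,
    means: RiskFactorMeans,
    coefs: Coefficients,
    strict_hazard_conversion: bool = False,
) -> list[BandHazards]:
    """The individual's annual hazards over the horizon partition.

    Per band: CVD hazard = observed band rate x hazard ratio recomputed
    against that band's means (the profile's measured values stay fixed;
    the reference changes with the band); the competing non-CVD hazard is
    the observed rate, unmodified by risk factors.
    """
    out = []
    for band, exposure in horizon_bands(profile.age, table, profile.sex):
        m_cvd, m_noncvd = band_rates(table, profile.sex, band)
        hr = hazard_ratio(profile, means, coefs, band)
        out.append(
            BandHazards(
                h_cvd=annualize(m_cvd, strict_hazard_conversion) * hr,
                h_noncvd=annualize(m_noncvd, strict_hazard_conversion),
                exposure=exposure,
            )
        )
    return out


def chain_cif(hazards: list[BandHazards]) -> tuple[float, float, float]:
    """Chain per-band contributions into ``(cif_cvd, cif_noncvd, survival)``.

    Each band contributes S(band start) x (conditional within-band CIF);
    survival decays by exp(-(h_cvd + h_noncvd) x exposure) per band. The
    three outputs sum to 1 exactly up to float rounding.
    """
    s = 1.0
    cif_cvd = 0.0
    cif_other = 0.0
    for bh in hazards:
        cif_cvd += s * cif_band(bh.h_cvd, bh.h_noncvd, bh.exposure)
        cif_other += s * cif_band(bh.h_noncvd, bh.h_cvd, bh.exposure)
        s *= math.exp(-(bh.h_cvd + bh.h_noncvd) * bh.exposure)
    return cif_cvd, cif_other, s


def ten_year_risk_constant(
    profile: RiskProfile,
    table: MortalityTable,
    means: RiskFactorMeans,
    coefs: Coefficients,
    strict_hazard_conversion: bool = False,
) -> float:
    """10-year fatal-CVD risk with rates held constant within 5-year bands."""
    hazards = profile_band_hazards(profile, table, means, coefs, strict_hazard_conversion)
    return chain_cif(hazards)[0]


def _midpoint_interpolator(
    table: MortalityTable, sex: str
) -> tuple[list[float], list[float], list[float]]:
    bands = table.bands(sex)
    mids = [b.midpoint for b in bands]
    rates = [band_rates(table, sex, b) for b in bands]
    return mids, [r[0] for r in rates], [r[1] for r in rates]


def _interp(x: float, xs: list[float], ys: list[float]) -> float:
    # linear between knots, constant beyond the outermost knots
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    for i in range(len(xs) - 1):
        if xs[i] <= x <= xs[i + 1]:
            w = (x - xs[i]) / (xs[i + 1] - xs[i])
            return ys[i] * (1 - w) + ys[i + 1] * w
    raise AssertionError("unreachable")  # pragma: no cover


def ten_year_risk_interpolated(
    profile: RiskProfile,
    table: MortalityTable,
    means: RiskFactorMeans,
    coefs: Coefficients,
    strict_hazard_conversion: bool = False,
) -> float:
    """Legacy variant: midpoint-interpolated annual rates, 1-year chaining.

    Band rates are read as the value at each band's midpoint; the annual
    cause-specific hazard over each step comes from linear interpolation
    in age at the step's own midpoint (constant extrapolation outside the
    outermost band midpoints). Steps are 1 year, additionally split at
    5-year band boundaries so each sub-step takes its hazard ratio from
    its own band's means (for chart-aligned integer entry ages the steps
    are exactly 1 year). With identical rates in every band this reduces
    exactly to :func:`ten_year_risk_constant`.
    """
    table.require_coverage(profile.sex, profile.age, profile.age + HORIZON_YEARS)
    mids, m_cvd_knots, m_noncvd_knots = _midpoint_interpolator(table, profile.sex)
    # cut points: every whole year offset plus every band boundary crossed
    cuts = {profile.age + k for k in range(int(HORIZON_YEARS) + 1)}
    b = math.ceil(profile.age / 5.0) * 5
    while b < profile.age + HORIZON_YEARS:
        cuts.add(float(b))
        b += 5
    grid = sorted(cuts)
    hazards = []
    for a0, a1 in zip(grid, grid[1:]):
        a_mid = (a0 + a1) / 2.0
        band = AgeBand.containing(a0)
        hr = hazard_ratio(profile, means, coefs, band)
        m_cvd = _interp(a_mid, mids, m_cvd_knots)
        m_noncvd = _interp(a_mid, mids, m_noncvd_knots)
        hazards.append(
            BandHazards(
                h_cvd=annualize(m_cvd, strict_hazard_conversion) * hr,
                h_noncvd=annualize(m_noncvd, strict_hazard_conversion),
                exposure=a1 - a0,
            )
        )
    return chain_cif(hazards)[0]


def ten_year_risk(
    profile: RiskProfile,
    table: MortalityTable,
    means: RiskFactorMeans,
    coefs: Coefficients,
    method: Method = "constant",
    strict_hazard_conversion: bool = False,
) -> float:
    """Dispatch on method: ``"constant"`` (default) or ``"interpolated"``."""
    if method == "constant":
        return ten_year_risk_constant(profile, table, means, coefs, strict_hazard_conversion)
    if method == "interpolated":
        return ten_year_risk_interpolated(profile, table, means, coefs, strict_hazard_conversion)
    raise ValidationError(f"unknown method {method!r}")


def chart_age(age: float) -> int:
    """Round an exact age to the nearest chart entry age (ties round up),
    clamped to the chart range [40, 65]."""
    a = int(math.floor(age / 5.0 + 0.5)) * 5
    return min(max(a, 40), 65)
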