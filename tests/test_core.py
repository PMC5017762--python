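"""Unit and property tests for the competing-risks risk engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scorecal import (
    AgeBand,
    BandHazards,
    CholMeasure,
    CoefficientSet,
    Coefficients,
    CoverageError,
    MeansEntry,
    MortalityEntry,
    MortalityTable,
    RiskFactorMeans,
    RiskProfile,
    ValidationError,
    band_rates,
    chain_cif,
    chart_age,
    cif_band,
    hazard_ratio,
    horizon_bands,
    profile_band_hazards,
    ten_year_risk_constant,
    ten_year_risk_interpolated,
)
from scorecal.core import annualize

from conftest import flat_table, make_means

# frozen closed-form oracles (high-precision scalar evaluation, fixed
# before wiring them through the engine)
HR_EXAMPLE = 2.849091011289214              # exp(0.015*20 + 0.25*1 + 0.71*0.7)
CIF_COMPETING = 0.0097541150998572          # 0.2 * (1 - exp(-0.05))
CIF_NO_COMPETITION = 0.009950166250831947   # 1 - exp(-0.01)
TWO_BAND_RISK = 0.007388616612872956        # chained two-band example


def two_band_table() -> MortalityTable:
    pop = 100_000.0
    entries = {}
    for sex in ("female", "male"):
        entries[(sex, 40)] = MortalityEntry(0.0005 * pop, 0.0015 * pop, pop)
        entries[(sex, 45)] = MortalityEntry(0.001 * pop, 0.003 * pop, pop)
        for s in range(50, 75, 5):
            entries[(sex, s)] = MortalityEntry(0.001 * pop, 0.003 * pop, pop)
    return MortalityTable(entries=entries)


class TestBandRates:
    @pytest.mark.parametrize(
        "d_cvd,d_non,pop,expect",
        [
            (0, 100, 100_000, (0.0, 1e-3)),
            (50, 0.0, 100_000, (5.0e-4, 0.0)),
            (50, 150, 100_000, (5.0e-4, 1.5e-3)),
        ],
    )
    def test_rates_are_deaths_over_population(self, d_cvd, d_non, pop, expect):
        entries = {
            (sex, s): MortalityEntry(d_cvd, d_non, pop)
            for sex in ("female", "male")
            for s in range(40, 75, 5)
        }
        t = MortalityTable(entries=entries)
        assert band_rates(t, "male", AgeBand(40)) == pytest.approx(expect, abs=1e-15)

    def test_missing_band_names_the_band(self, table):
        with pytest.raises(CoverageError, match="75"):
            table.entry("male", AgeBand(75))

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValidationError):
            MortalityEntry(1, 1, 0.0)

    def test_strict_hazard_conversion(self):
        assert annualize(0.01, strict=True) == pytest.approx(-math.log(0.99), abs=1e-15)
        assert annualize(0.01, strict=False) == 0.01


class TestHazardRatio:
    def make_means_simple(self):
        e = MeansEntry(mean_sbp=140.0, mean_tc=5.5, mean_ratio=4.0, smoking_prev=0.30)
        return RiskFactorMeans(entries={("male", s): e for s in range(40, 75, 5)}
                               | {("female", s): e for s in range(40, 75, 5)})

    def test_profile_at_means_gives_unit_ratio(self, coefs):
        means = self.make_means_simple()
        # smoker "status" equal to the prevalence is unattainable for a real
        # person, so emulate x == xbar by zeroing smoking prevalence and flag
        e = MeansEntry(mean_sbp=140.0, mean_tc=5.5, mean_ratio=4.0, smoking_prev=0.0)
        means = RiskFactorMeans(entries={(sx, s): e for sx in ("female", "male")
                                         for s in range(40, 75, 5)})
        p = RiskProfile(sex="male", age=50, sbp=140.0, chol_value=5.5,
                        chol_measure=CholMeasure.TC, smoker=False)
        assert hazard_ratio(p, means, coefs, AgeBand(50)) == pytest.approx(1.0, abs=1e-12)

    def test_null_coefficients_give_unit_ratio(self, null_coefs):
        means = self.make_means_simple()
        p = RiskProfile(sex="female", age=44, sbp=190.0, chol_value=8.0,
                        chol_measure=CholMeasure.TC, smoker=True)
        assert hazard_ratio(p, means, null_coefs, AgeBand(40)) == 1.0

    def test_worked_example_against_closed_form(self):
        means = self.make_means_simple()
        coefs = Coefficients(
            shared=CoefficientSet(beta_sbp=0.015, beta_tc=0.25, beta_ratio=0.0,
                                  beta_smoke=0.71))
        p = RiskProfile(sex="male", age=55, sbp=160.0, chol_value=6.5,
                        chol_measure=CholMeasure.TC, smoker=True)
        assert hazard_ratio(p, means, coefs, AgeBand(55)) == pytest.approx(
            HR_EXAMPLE, abs=1e-12)

    def test_ratio_measure_uses_ratio_coefficient(self):
        means = self.make_means_simple()
        coefs = Coefficients(
            shared=CoefficientSet(beta_sbp=0.0, beta_tc=0.0, beta_ratio=0.2,
                                  beta_smoke=0.0))
        p = RiskProfile(sex="male", age=50, sbp=140.0, chol_value=5.0,
                        chol_measure=CholMeasure.RATIO, smoker=False)
        assert hazard_ratio(p, means, coefs, AgeBand(50)) == pytest.approx(
            math.exp(0.2 * 1.0), abs=1e-12)

    def test_per_sex_override(self):
        means = self.make_means_simple()
        coefs = Coefficients(
            shared=CoefficientSet(0.0, 0.0, 0.0, 0.0),
            per_sex={"female": CoefficientSet(0.02, 0.0, 0.0, 0.0)},
        )
        kwargs = dict(age=50, sbp=150.0, chol_value=5.5,
                      chol_measure=CholMeasure.TC, smoker=False)
        male = RiskProfile(sex="male", **kwargs)
        female = RiskProfile(sex="female", **kwargs)
        assert hazard_ratio(male, means, coefs, AgeBand(50)) == 1.0
        assert hazard_ratio(female, means, coefs, AgeBand(50)) == pytest.approx(
            math.exp(0.02 * 10), abs=1e-12)


class TestHorizonBands:
    @pytest.mark.parametrize(
        "age,expected",
        [
            (40, [(40, 5.0), (45, 5.0)]),
            (65, [(65, 5.0), (70, 5.0)]),
            (43, [(40, 2.0), (45, 5.0), (50, 3.0)]),
            (61.5, [(60, 3.5), (65, 5.0), (70, 1.5)]),
        ],
    )
    def test_partition(self, table, age, expected):
        got = [(b.start, e) for b, e in horizon_bands(age, table, "male")]
        assert got == pytest.approx(expected)

    def test_exposures_sum_to_ten(self, table):
        for age in np.linspace(40, 65, 26):
            parts = horizon_bands(float(age), table, "female")
            assert sum(e for _, e in parts) == pytest.approx(10.0, abs=1e-9)

    def test_insufficient_coverage_names_missing_band(self, means, coefs):
        pop = 100_000.0
        entries = {(sex, s): MortalityEntry(50, 150, pop)
                   for sex in ("female", "male") for s in range(40, 70, 5)}
        t = MortalityTable(entries=entries)  # lacks 70-74
        with pytest.raises(CoverageError, match="70"):
            horizon_bands(65, t, "male")

    def test_age_out_of_range(self, table):
        with pytest.raises(ValidationError):
            horizon_bands(39, table, "male")


class TestCifBand:
    def test_no_event_hazard_gives_zero(self):
        assert cif_band(0.0, 0.5, 5.0) == 0.0
        assert cif_band(0.0, 0.0, 5.0) == 0.0

    def test_no_competition_closed_form(self):
        assert cif_band(0.002, 0.0, 5.0) == pytest.approx(CIF_NO_COMPETITION, abs=1e-15)

    def test_competing_closed_form(self):
        assert cif_band(0.002, 0.008, 5.0) == pytest.approx(CIF_COMPETING, abs=1e-15)

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValidationError):
            cif_band(-0.001, 0.0, 5.0)

    @given(h_cvd=st.floats(0, 0.5), h_non=st.floats(0, 0.5),
           exposure=st.floats(0.1, 5.0))
    @settings(max_examples=200, deadline=None)
    def test_bounds(self, h_cvd, h_non, exposure):
        v = cif_band(h_cvd, h_non, exposure)
        assert 0.0 <= v < 1.0


class TestTenYearRisk:
    def test_zero_rates_give_zero_risk(self, means, null_coefs):
        pop = 100_000.0
        entries = {(sex, s): MortalityEntry(0.0, 0.0, pop)
                   for sex in ("female", "male") for s in range(40, 75, 5)}
        t = MortalityTable(entries=entries)
        p = RiskProfile(sex="male", age=52, sbp=140, chol_value=5.5,
                        chol_measure=CholMeasure.TC, smoker=False)
        assert ten_year_risk_constant(p, t, means, null_coefs) == 0.0
        assert ten_year_risk_interpolated(p, t, means, null_coefs) == 0.0

    def test_two_band_worked_example(self, null_coefs):
        t = two_band_table()
        means = make_means()
        p = RiskProfile(sex="male", age=40, sbp=140, chol_value=5.5,
                        chol_measure=CholMeasure.TC, smoker=False)
        assert ten_year_risk_constant(p, t, means, null_coefs) == pytest.approx(
            TWO_BAND_RISK, abs=1e-12)

    def test_smoking_raises_risk(self, means):
        t = two_band_table()
        coefs = Coefficients(shared=CoefficientSet(0.0, 0.0, 0.0, 0.7))
        base = dict(sex="male", age=40, sbp=140, chol_value=5.5,
                    chol_measure=CholMeasure.TC)
        r_smoke = ten_year_risk_constant(
            RiskProfile(smoker=True, **base), t, means, coefs)
        r_non = ten_year_risk_constant(
            RiskProfile(smoker=False, **base), t, means, coefs)
        assert r_smoke > r_non

    def test_conservation(self, table, means, coefs):
        p = RiskProfile(sex="female", age=58.3, sbp=165, chol_value=6.8,
                        chol_measure=CholMeasure.TC, smoker=True)
        hz = profile_band_hazards(p, table, means, coefs)
        cif_cvd, cif_other, surv = chain_cif(hz)
        assert cif_cvd + cif_other + surv == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_limit_no_competing_hazard(self, means, null_coefs):
        pop = 100_000.0
        rates = {40: 0.0004, 45: 0.0007, 50: 0.0012, 55: 0.002, 60: 0.0033,
                 65: 0.0055, 70: 0.009}
        entries = {(sex, s): MortalityEntry(rates[s] * pop, 0.0, pop)
                   for sex in ("female", "male") for s in rates}
        t = MortalityTable(entries=entries)
        p = RiskProfile(sex="male", age=47, sbp=140, chol_value=5.5,
                        chol_measure=CholMeasure.TC, smoker=False)
        hz = profile_band_hazards(p, t, means, null_coefs)
        expected = -math.expm1(-sum(b.h_cvd * b.exposure for b in hz))
        assert ten_year_risk_constant(p, t, means, null_coefs) == pytest.approx(
            expected, abs=1e-12)

    def test_flat_rates_make_methods_agree(self, means, coefs):
        t = flat_table()
        for age in (40, 43.7, 55, 65):
            p = RiskProfile(sex="male", age=age, sbp=155, chol_value=6.0,
                            chol_measure=CholMeasure.TC, smoker=True)
            rc = ten_year_risk_constant(p, t, means, coefs)
            ri = ten_year_risk_interpolated(p, t, means, coefs)
            assert ri == pytest.approx(rc, abs=1e-9)

    def test_interpolated_against_yearly_chaining_oracle(self, table, means, coefs):
        """Independent year-by-year product-sum with explicit midpoint
        interpolation, written without the engine's chaining helper."""
        p = RiskProfile(sex="male", age=50, sbp=150, chol_value=6.0,
                        chol_measure=CholMeasure.TC, smoker=False)
        mids = [s + 2.5 for s in range(40, 75, 5)]
        m_cvd = [band_rates(table, "male", AgeBand(s))[0] for s in range(40, 75, 5)]
        m_non = [band_rates(table, "male", AgeBand(s))[1] for s in range(40, 75, 5)]

        def interp(x, xs, ys):
            if x <= xs[0]:
                return ys[0]
            if x >= xs[-1]:
                return ys[-1]
            i = max(j for j in range(len(xs)) if xs[j] <= x)
            w = (x - xs[i]) / (xs[i + 1] - xs[i])
            return ys[i] * (1 - w) + ys[i + 1] * w

        surv, cif = 1.0, 0.0
        for k in range(10):
            a = 50 + k
            band = AgeBand(int(a // 5) * 5)
            hr = hazard_ratio(p, means, coefs, band)
            hc = interp(a + 0.5, mids, m_cvd) * hr
            hn = interp(a + 0.5, mids, m_non)
            h = hc + hn
            cif += surv * (hc / h) * (1 - math.exp(-h))
            surv *= math.exp(-h)
        got = ten_year_risk_interpolated(p, table, means, coefs)
        assert got == pytest.approx(cif, abs=1e-12)

    def test_scale_property_first_order_limit(self, means, null_coefs):
        eps = 1e-6
        pop = 100_000.0
        rates = {s: (0.001 * (1 + 0.1 * i), 0.003 * (1 + 0.1 * i))
                 for i, s in enumerate(range(40, 75, 5))}
        entries = {(sex, s): MortalityEntry(rc * eps * pop, rn * eps * pop, pop)
                   for sex in ("female", "male") for s, (rc, rn) in rates.items()}
        t = MortalityTable(entries=entries)
        p = RiskProfile(sex="male", age=48, sbp=140, chol_value=5.5,
                        chol_measure=CholMeasure.TC, smoker=False)
        hz = profile_band_hazards(p, t, means, null_coefs)
        linear = sum(b.h_cvd * b.exposure for b in hz)
        risk = ten_year_risk_constant(p, t, means, null_coefs)
        assert risk / linear == pytest.approx(1.0, rel=1e-3)

    @given(
        sbp=st.floats(100, 200),
        delta=st.floats(0.1, 40),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_sbp_for_positive_beta(self, sbp, delta):
        t = flat_table()
        means = make_means()
        coefs = Coefficients(shared=CoefficientSet(0.02, 0.0, 0.0, 0.0))
        base = dict(sex="male", age=50, chol_value=5.5,
                    chol_measure=CholMeasure.TC, smoker=False)
        lo = ten_year_risk_constant(RiskProfile(sbp=sbp, **base), t, means, coefs)
        hi = ten_year_risk_constant(RiskProfile(sbp=sbp + delta, **base), t, means, coefs)
        assert hi >= lo

    def test_monotone_decreasing_for_negative_beta(self):
        t = flat_table()
        means = make_means()
        coefs = Coefficients(shared=CoefficientSet(0.0, -0.1, 0.0, 0.0))
        base = dict(sex="female", age=55, sbp=140,
                    chol_measure=CholMeasure.TC, smoker=False)
        r_lo = ten_year_risk_constant(RiskProfile(chol_value=4.0, **base), t, means, coefs)
        r_hi = ten_year_risk_constant(RiskProfile(chol_value=7.0, **base), t, means, coefs)
        assert r_hi <= r_lo


class TestChartAge:
    @pytest.mark.parametrize("age,expected", [
        (40.0, 40), (42.4, 40), (42.5, 45), (47.4, 45), (47.5, 50),
        (63.0, 65), (65.0, 65), (41.0, 40), (64.9, 65),
    ])
    def test_nearest_chart_age_ties_up(self, age, expected):
        assert chart_age(age) == expected


class TestBandHazardsType:
    def test_rejects_bad_values(self):
        with pytest.raises(ValidationError):
            BandHazards(h_cvd=-0.1, h_noncvd=0.0, exposure=1.0)
        with pytest.raises(ValidationError):
            BandHazards(h_cvd=0.1, h_noncvd=0.0, exposure=0.0)
        with pytest.raises(ValidationError):
            BandHazards(h_cvd=0.1, h_noncvd=0.0, exposure=5.5)
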