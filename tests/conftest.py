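import pytest

from scorecal import (
    CoefficientSet,
    Coefficients,
    MeansEntry,
    MortalityEntry,
    MortalityTable,
    RiskFactorMeans,
    SEXES,
    SimParams,
    default_coefficients,
    synth_mortality,
)

BAND_STARTS = range(40, 75, 5)


def make_means(params: SimParams | None = None) -> RiskFactorMeans:
    """Deterministic band means at the generator's configured expectations
    (band midpoint values of the linear age trends)."""
    p = params or SimParams()
    entries = {}
    for sex in SEXES:
        for start in BAND_STARTS:
            mid = start + 2.5
            entries[(sex, start)] = MeansEntry(
                mean_sbp=p.expected_sbp(sex, mid),
                mean_tc=p.expected_tc(sex, mid),
                mean_ratio=p.expected_tc(sex, mid) / p.hdl_mean[sex],
                smoking_prev=p.smoking_prev[sex],
            )
    return RiskFactorMeans(entries=entries)


def flat_table(m_cvd: float = 0.002, m_noncvd: float = 0.006) -> MortalityTable:
    """Identical rates in every band (flat-limit fixture)."""
    pop = 100_000.0
    entries = {
        (sex, s): MortalityEntry(m_cvd * pop, m_noncvd * pop, pop)
        for sex in SEXES
        for s in BAND_STARTS
    }
    return MortalityTable(entries=entries)


@pytest.fixture(scope="session")
def params() -> SimParams:
    return SimParams(seed=12345)


@pytest.fixture(scope="session")
def table(params) -> MortalityTable:
    return synth_mortality(params)


@pytest.fixture(scope="session")
def means(params) -> RiskFactorMeans:
    return make_means(params)


@pytest.fixture(scope="session")
def coefs() -> Coefficients:
    return default_coefficients()


@pytest.fixture(scope="session")
def null_coefs() -> Coefficients:
    return Coefficients(
        shared=CoefficientSet(beta_sbp=0.0, beta_tc=0.0, beta_ratio=0.0, beta_smoke=0.0),
        provenance="null",
    )
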