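"""Verify the analytic engine against simulated lifetimes.

Draws 200,000 synthetic individuals through the piecewise-constant
two-cause exponential model at one profile's hazards and compares the
simulated CVD-death fraction to the closed-form cumulative incidence.
"""

from scorecal import (
    CholMeasure,
    RiskProfile,
    SimParams,
    chain_cif,
    estimate_means,
    profile_band_hazards,
    simulate_deaths,
    synth_mortality,
    synth_survey,
)
from scorecal.synthdata import default_coefficients

table = synth_mortality(SimParams(seed=1))
means = estimate_means(synth_survey(SimParams(seed=2, n=50_000))[0])
coefs = default_coefficients()

profile = RiskProfile(sex="female", age=58.5, sbp=150.0, chol_value=6.0,
                      chol_measure=CholMeasure.TC, smoker=True)
hazards = profile_band_hazards(profile, table, means, coefs)
analytic, other, surviving = chain_cif(hazards)
frac, se = simulate_deaths(hazards, n=200_000, seed=7)

print(f"analytic 10-year CVD risk:   {100 * analytic:.3f}%")
print(f"simulated fraction (n=2e5):  {100 * frac:.3f}%  (binomial SE {100 * se:.3f})")
print(f"z-score of the discrepancy:  {(frac - analytic) / se:+.2f}")
print(f"competing (non-CVD) deaths:  {100 * other:.3f}%, survivors {100 * surviving:.3f}%")
print("Agreement within a few SE confirms the chained cumulative-incidence "
      "formula; the three outcomes sum to 100% by construction.")
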