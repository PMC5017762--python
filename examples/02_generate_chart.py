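"""Generate a full 480-cell risk chart and print one panel.

The chart tabulates the risk function over sex x smoking x entry age
(40..65 by 5) x SBP (120..180) x cholesterol (TC 4..8 mmol/L); each cell
holds the raw 10-year risk, displayed as a rounded percentage (<1 for
values under 0.5%).
"""

from scorecal import (
    ChartAxes,
    CholMeasure,
    SimParams,
    estimate_means,
    generate_chart,
    synth_mortality,
    synth_survey,
)
from scorecal.render import render_text
from scorecal.synthdata import default_coefficients

table = synth_mortality(SimParams(seed=1))
means = estimate_means(synth_survey(SimParams(seed=2, n=50_000))[0])
coefs = default_coefficients()

grid = generate_chart(ChartAxes.default(CholMeasure.TC), table, means, coefs,
                      CholMeasure.TC)
print(f"chart cells: {len(grid.cells)} "
      f"(ages 50-65 restriction: {len(grid.restrict_ages(50, 65).cells)})")

text = render_text(grid)
panel = text.split("\n\n")
wanted = [p for p in panel if p.startswith("male, smoker, age 65")]
print()
print(wanted[0])
print("Rows are SBP (mmHg, high to low), columns total cholesterol "
      "(mmol/L); entries are the rounded 10-year risk in percent.")
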