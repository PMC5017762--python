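"""Sensitivity comparison: constant-rate vs interpolated-rate calibration.

Generates the same chart under both methods and compares the 320 cells of
the 50-65 age range cell-by-cell: counts of higher/lower/equal rounded
values, the mean absolute raw difference in percentage points, and the
intraclass correlation coefficient ICC(A,1) measuring absolute agreement.
"""

from scorecal import (
    ChartAxes,
    CholMeasure,
    SimParams,
    compare_charts,
    estimate_means,
    generate_chart,
    synth_mortality,
    synth_survey,
)
from scorecal.synthdata import default_coefficients

table = synth_mortality(SimParams(seed=1))
means = estimate_means(synth_survey(SimParams(seed=2, n=50_000))[0])
coefs = default_coefficients()
axes = ChartAxes.default(CholMeasure.TC)

constant = generate_chart(axes, table, means, coefs, CholMeasure.TC, method="constant")
interp = generate_chart(axes, table, means, coefs, CholMeasure.TC, method="interpolated")

stats = compare_charts(interp, constant, age_range=(50, 65))
print(f"cells compared (ages 50-65):      {stats.n_cells_compared}")
print(f"interpolated higher / lower / equal (rounded): "
      f"{stats.n_higher} / {stats.n_lower} / {stats.n_equal}")
print(f"mean |difference|:                {stats.mean_abs_diff:.3f} "
      f"(SD {stats.sd_abs_diff:.3f}) percentage points")
print(f"ICC(A,1):                         {stats.icc:.4f}")
print("An ICC near 1 means switching from the legacy interpolated rates "
      "to constant within-band rates barely changes the chart; most cells "
      "round to the same displayed percentage.")
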