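"""Risk-chart tabulation, rendering and comparison.

A chart is a pure tabulation of the 10-year risk function over a grid of
cells: sex x smoking status x entry age x systolic blood pressure x
cholesterol level, for one cholesterol measure (total cholesterol or the
TC/HDL-C ratio). The default axes give 2 x 2 x 6 x 4 x 5 = 480 cells;
restricting to entry ages 50-65 gives 320.

Chart comparison counts cells whose rounded display values are higher,
lower or equal between two grids, summarises raw differences in
percentage points, and optionally measures agreement with the intraclass
correlation coefficient ICC(A,1) (two-way random effects, absolute
agreement, single measurement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .core import Method, ten_year_risk
from .domain import Coefficients, CholMeasure, MortalityTable, RiskFactorMeans, RiskProfile, SEXES
from .errors import ValidationError

DEFAULT_AGES = (40, 45, 50, 55, 60, 65)
DEFAULT_SBP = (120, 140, 160, 180)
DEFAULT_TC = (4, 5, 6, 7, 8)
DEFAULT_RATIO = (3, 4, 5, 6, 7)

#: Display colour categories, (label, inclusive lower display bound).
CATEGORIES = (("<1", 0), ("1", 1), ("2", 2), ("3-4", 3), ("5-9", 5), ("10-14", 10), (">=15", 15))

CellKey = tuple[str, bool, int, float, float]  # (sex, smoker, age, sbp, chol)


def _strictly_increasing(xs: Sequence[float]) -> bool:
    return all(a < b for a, b in zip(xs, xs[1:]))


@dataclass(frozen=True)
class ChartAxes:
    """Axis levels of a chart grid."""

    ages: tuple[int, ...] = DEFAULT_AGES
    sbp_levels: tuple[float, ...] = DEFAULT_SBP
    chol_levels: tuple[float, ...] = DEFAULT_TC

    def __post_init__(self) -> None:
        for name, xs in (("ages", self.ages), ("sbp_levels", self.sbp_levels),
                         ("chol_levels", self.chol_levels)):
            if not xs:
                raise ValidationError(f"{name} must be non-empty")
            if not _strictly_increasing(xs):
                raise ValidationError(f"{name} must be strictly increasing")
        for a in self.ages:
            if a % 5 != 0 or not 40 <= a <= 65:
                raise ValidationError(f"chart age {a} must be a multiple of 5 in [40, 65]")

    @staticmethod
    def default(measure: CholMeasure) -> "ChartAxes":
        chol = DEFAULT_TC if measure is CholMeasure.TC else DEFAULT_RATIO
        return ChartAxes(chol_levels=tuple(chol))

    @property
    def n_cells(self) -> int:
        return 2 * 2 * len(self.ages) * len(self.sbp_levels) * len(self.chol_levels)

    def keys(self) -> list[CellKey]:
        return [
            (sex, smoker, age, sbp, chol)
            for sex in SEXES
            for smoker in (False, True)
            for age in self.ages
            for sbp in self.sbp_levels
            for chol in self.chol_levels
        ]

    def restrict_ages(self, age_min: int, age_max: int) -> "ChartAxes":
        ages = tuple(a for a in self.ages if age_min <= a <= age_max)
        if not ages:
            raise ValidationError(f"no chart ages in [{age_min}, {age_max}]")
        return ChartAxes(ages=ages, sbp_levels=self.sbp_levels, chol_levels=self.chol_levels)


@dataclass
class ChartGrid:
    """Tabulated 10-year risks over all chart cells (raw, unrounded)."""

    chol_measure: CholMeasure
    axes: ChartAxes
    cells: dict[CellKey, float]
    method: Method = "constant"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.cells) != self.axes.n_cells:
            raise ValidationError(
                f"grid has {len(self.cells)} cells, axes imply {self.axes.n_cells}"
            )
        for k, v in self.cells.items():
            if not (math.isfinite(v) and 0 <= v <= 1):
                raise ValidationError(f"cell {k} has invalid risk {v}")

    def restrict_ages(self, age_min: int, age_max: int) -> "ChartGrid":
        axes = self.axes.restrict_ages(age_min, age_max)
        cells = {k: v for k, v in self.cells.items() if age_min <= k[2] <= age_max}
        return ChartGrid(self.chol_measure, axes, cells, self.method, dict(self.provenance))


def generate_chart(
    axes: ChartAxes,
    table: MortalityTable,
    means: RiskFactorMeans,
    coefs: Coefficients,
    chol_measure: CholMeasure,
    method: Method = "constant",
    strict_hazard_conversion: bool = False,
) -> ChartGrid:
    """Tabulate the risk function over the grid — no smoothing, each cell
    is exactly the direct risk call for that profile."""
    cells: dict[CellKey, float] = {}
    for key in axes.keys():
        sex, smoker, age, sbp, chol = key
        profile = RiskProfile(
            sex=sex, age=age, sbp=sbp, chol_value=chol,
            chol_measure=chol_measure, smoker=smoker,
        )
        try:
            cells[key] = ten_year_risk(
                profile, table, means, coefs, method, strict_hazard_conversion
            )
        except ValidationError as e:
            raise ValidationError(f"cell {key}: {e}") from e
    return ChartGrid(chol_measure=chol_measure, axes=axes, cells=cells, method=method)


def display_value(risk: float) -> str:
    """Rounded chart display: half-away-from-zero of 100 x risk; values
    below 0.5% display as "<1"."""
    pct = 100.0 * risk
    if pct < 0.5:
        return "<1"
    return str(int(math.floor(pct + 0.5)))


def display_number(risk: float) -> int:
    """Numeric display value with "<1" mapped to 0 (used for ordering)."""
    pct = 100.0 * risk
    return 0 if pct < 0.5 else int(math.floor(pct + 0.5))


def category(risk: float) -> str:
    """Colour-bin label for a cell."""
    d = display_number(risk)
    label = CATEGORIES[0][0]
    for lab, lo in CATEGORIES:
        if d >= lo:
            label = lab
    return label


@dataclass
class ComparisonStats:
    """Cell-wise comparison of chart A against chart B."""

    n_cells_compared: int
    n_higher: int      # A displays higher than B
    n_lower: int
    n_equal: int
    mean_abs_diff: float  # |A - B| in percentage points, raw values
    sd_abs_diff: float
    mean_diff: float      # signed A - B, percentage points
    icc: float | None
    age_range: tuple[int, int] | None

    def __post_init__(self) -> None:
        if self.n_higher + self.n_lower + self.n_equal != self.n_cells_compared:
            raise ValidationError("higher + lower + equal must equal cells compared")
        if self.mean_abs_diff < 0:
            raise ValidationError("mean_abs_diff must be non-negative")

    def to_dict(self) -> dict:
        return {
            "n_cells_compared": self.n_cells_compared,
            "n_higher": self.n_higher,
            "n_lower": self.n_lower,
            "n_equal": self.n_equal,
            "mean_abs_diff": self.mean_abs_diff,
            "sd_abs_diff": self.sd_abs_diff,
            "mean_diff": self.mean_diff,
            "icc": self.icc,
            "age_range": list(self.age_range) if self.age_range else None,
        }


def icc(pairs: Sequence[tuple[float, float]]) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single
    measurement, from the standard mean-squares decomposition.

    With n targets and k=2 raters:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    Exact elementwise agreement returns 1.0 (including the zero-variance
    degenerate case); zero variance with disagreement is an error.
    """
    n = len(pairs)
    if n < 2:
        raise ValidationError("ICC requires at least 2 pairs")
    k = 2
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    if all(x == y for x, y in pairs):
        return 1.0
    grand = (sum(a) + sum(b)) / (n * k)
    row_means = [(x + y) / 2 for x, y in pairs]
    col_means = [sum(a) / n, sum(b) / n]
    ssr = k * sum((r - grand) ** 2 for r in row_means)
    ssc = n * sum((c - grand) ** 2 for c in col_means)
    sst = sum((x - grand) ** 2 for x in a) + sum((x - grand) ** 2 for x in b)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValidationError("degenerate pairs: zero variance with disagreement")
    return (msr - mse) / denom


def compare_charts(
    grid_a: ChartGrid,
    grid_b: ChartGrid,
    age_range: tuple[int, int] | None = None,
    icc_on: bool = True,
    on_display: bool = True,
    age_map: Callable[[int], int] | None = None,
) -> ComparisonStats:
    """Cell-wise comparison of two grids.

    ``age_map`` maps an age of grid A onto the age of grid B whose cell it
    should be compared with, allowing one-to-many matching against legacy
    grids with a merged 40-49 band. Counts of higher/lower/equal run on
    rounded display values by default (``on_display=False`` compares raw).
    """
    a = grid_a.restrict_ages(*age_range) if age_range else grid_a
    if age_range and age_map is None:
        grid_b = grid_b.restrict_ages(*age_range)
    diffs: list[float] = []
    n_hi = n_lo = n_eq = 0
    pairs: list[tuple[float, float]] = []
    for key, va in sorted(a.cells.items()):
        sex, smoker, age, sbp, chol = key
        bkey = (sex, smoker, age_map(age) if age_map else age, sbp, chol)
        if bkey not in grid_b.cells:
            raise ValidationError(f"grid B has no cell matching {bkey}; provide an age_map")
        vb = grid_b.cells[bkey]
        pairs.append((va, vb))
        diffs.append(100.0 * (va - vb))
        if on_display:
            da, db = display_number(va), display_number(vb)
        else:
            da, db = va, vb
        if da > db:
            n_hi += 1
        elif da < db:
            n_lo += 1
        else:
            n_eq += 1
    n = len(diffs)
    abs_diffs = [abs(d) for d in diffs]
    mean_abs = sum(abs_diffs) / n
    var = sum((d - mean_abs) ** 2 for d in abs_diffs) / (n - 1) if n > 1 else 0.0
    return ComparisonStats(
        n_cells_compared=n,
        n_higher=n_hi,
        n_lower=n_lo,
        n_equal=n_eq,
        mean_abs_diff=mean_abs,
        sd_abs_diff=math.sqrt(var),
        mean_diff=sum(diffs) / n,
        icc=icc(pairs) if icc_on else None,
        age_range=age_range,
    )
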