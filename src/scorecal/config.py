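"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .chart import ChartAxes
from .domain import CholMeasure
from .errors import IOFormatError, ValidationError


@dataclass
class RunConfig:
    """Everything a pipeline run needs, overridable from a JSON file.

    File paths are checked at load; ``axes`` overrides the default chart
    axes; ``strict_hazard_conversion`` switches rates -> hazards to the
    exact -log(1-m) mapping.
    """

    mortality: str | None = None
    means: str | None = None
    coefficients: str | None = None
    cohort: str | None = None
    chol_measure: str = "tc"
    method: str = "constant"
    threshold: float = 0.05
    ci_level: float = 0.95
    seed: int = 0
    outdir: str = "."
    strict_hazard_conversion: bool = False
    axes: dict = field(default_factory=dict)  # keys: ages, sbp_levels, chol_levels

    def validate(self) -> None:
        for name in ("mortality", "means", "coefficients", "cohort"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise IOFormatError(f"{name} file not found: {p}")
        CholMeasure(self.chol_measure)
        if self.method not in ("constant", "interpolated"):
            raise ValidationError(f"unknown method {self.method!r}")
        if not 0 < self.threshold < 1:
            raise ValidationError("threshold must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")

    def chart_axes(self) -> ChartAxes:
        base = ChartAxes.default(CholMeasure(self.chol_measure))
        kw = {}
        for k in ("ages", "sbp_levels", "chol_levels"):
            if k in self.axes and self.axes[k]:
                kw[k] = tuple(self.axes[k])
        if not kw:
            return base
        return ChartAxes(
            ages=kw.get("ages", base.ages),
            sbp_levels=kw.get("sbp_levels", base.sbp_levels),
            chol_levels=kw.get("chol_levels", base.chol_levels),
        )

    @staticmethod
    def from_json(path: str | Path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise IOFormatError(f"config file not found: {p}")
        try:
            raw = json.loads(p.read_text(encoding="utf-8"))
        except json.JSONDecodeError as e:
            raise IOFormatError(f"{p}: invalid JSON ({e})") from e
        known = set(RunConfig.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise IOFormatError(f"{p}: unknown config key(s) {sorted(unknown)}")
        return RunConfig(**raw)
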