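"""Readers and writers for the package's CSV/JSON schemas.

All CSVs are comma-separated UTF-8 with a mandatory header and dot
decimals; sexes are encoded ``female``/``male``, booleans ``0``/``1``,
empty fields mean missing. Validation errors carry 1-based data-row
numbers. Every reader/writer pair round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .chart import ChartAxes, ChartGrid
from .cohort import CohortRecord
from .domain import (
    CoefficientSet,
    Coefficients,
    CholMeasure,
    DEFAULT_CAUSE_DEFINITION,
    MeansEntry,
    MortalityEntry,
    MortalityTable,
    RiskFactorMeans,
    SEXES,
)
from .errors import IOFormatError, ValidationError

log = logging.getLogger(__name__)

MORTALITY_COLUMNS = ["sex", "age_band_start", "deaths_cvd", "deaths_noncvd", "population"]
MEANS_COLUMNS = ["sex", "age_band_start", "mean_sbp", "mean_tc", "mean_ratio", "smoking_prev"]
COHORT_COLUMNS = [
    "id", "age", "sex", "sbp", "tc", "hdl", "smoker", "weight",
    "prior_chd", "prior_stroke", "prior_hf",
]
_IGNORED_DESIGN_COLUMNS = ("stratum", "cluster", "psu")


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, for run logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:
        raise IOFormatError(f"{path}: cannot parse CSV ({e})") from e
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IOFormatError(f"{path}: missing column(s) {missing}")
    ignored = [c for c in df.columns if c.lower() in _IGNORED_DESIGN_COLUMNS]
    if ignored:
        log.info("%s: survey design columns %s accepted but ignored "
                 "(no design-based variance)", path, ignored)
    return df


def _numeric(df: pd.DataFrame, col: str, path, allow_missing: bool = False) -> pd.Series:
    s = pd.to_numeric(df[col], errors="coerce")
    if not allow_missing:
        bad = df.index[s.isna() & df[col].notna()]
        if len(bad):
            raise IOFormatError(
                f"{path}: non-numeric value in column {col!r} at data row {bad[0] + 1}"
            )
        empt = df.index[df[col].isna()]
        if len(empt):
            raise IOFormatError(f"{path}: empty value in column {col!r} at data row {empt[0] + 1}")
    return s


def read_mortality(path: str | Path) -> MortalityTable:
    """Load a mortality table CSV, enforcing all domain invariants."""
    df = _read_csv(path, MORTALITY_COLUMNS)
    entries: dict[tuple[str, int], MortalityEntry] = {}
    starts = _numeric(df, "age_band_start", path)
    d_cvd = _numeric(df, "deaths_cvd", path)
    d_non = _numeric(df, "deaths_noncvd", path)
    pop = _numeric(df, "population", path)
    for i in df.index:
        sex = str(df.loc[i, "sex"]).strip()
        if sex not in SEXES:
            raise IOFormatError(f"{path}: unknown sex {sex!r} at data row {i + 1}")
        key = (sex, int(starts[i]))
        if key in entries:
            raise IOFormatError(
                f"{path}: duplicate (sex={sex}, band {int(starts[i])}) at data row {i + 1}"
            )
        try:
            entries[key] = MortalityEntry(float(d_cvd[i]), float(d_non[i]), float(pop[i]))
        except ValidationError as e:
            raise IOFormatError(f"{path}: data row {i + 1}: {e}") from e
    table = MortalityTable(entries=entries)
    for sex in SEXES:
        table.require_coverage(sex, 40, 75)
    return table


def write_mortality(table: MortalityTable, path: str | Path) -> None:
    rows = [
        {"sex": sex, "age_band_start": band.start, "deaths_cvd": e.deaths_cvd,
         "deaths_noncvd": e.deaths_noncvd, "population": e.population}
        for sex, band, e in table
    ]
    pd.DataFrame(rows, columns=MORTALITY_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_means(path: str | Path) -> RiskFactorMeans:
    df = _read_csv(path, MEANS_COLUMNS)
    entries: dict[tuple[str, int], MeansEntry] = {}
    starts = _numeric(df, "age_band_start", path)
    cols = {c: _numeric(df, c, path) for c in MEANS_COLUMNS[2:]}
    for i in df.index:
        sex = str(df.loc[i, "sex"]).strip()
        if sex not in SEXES:
            raise IOFormatError(f"{path}: unknown sex {sex!r} at data row {i + 1}")
        key = (sex, int(starts[i]))
        if key in entries:
            raise IOFormatError(f"{path}: duplicate (sex, band) at data row {i + 1}")
        try:
            entries[key] = MeansEntry(
                mean_sbp=float(cols["mean_sbp"][i]),
                mean_tc=float(cols["mean_tc"][i]),
                mean_ratio=float(cols["mean_ratio"][i]),
                smoking_prev=float(cols["smoking_prev"][i]),
            )
        except ValidationError as e:
            raise IOFormatError(f"{path}: data row {i + 1}: {e}") from e
    return RiskFactorMeans(entries=entries)


def write_means(means: RiskFactorMeans, path: str | Path) -> None:
    rows = []
    for (sex, start), e in sorted(means.entries.items()):
        rows.append({"sex": sex, "age_band_start": start, "mean_sbp": e.mean_sbp,
                     "mean_tc": e.mean_tc, "mean_ratio": e.mean_ratio,
                     "smoking_prev": e.smoking_prev})
    pd.DataFrame(rows, columns=MEANS_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_coefficients(path: str | Path) -> Coefficients:
    """Load log-hazard-ratio configuration JSON.

    Schema: top-level ``beta_sbp``, ``beta_tc``, ``beta_ratio``,
    ``beta_smoke``; optional ``female`` / ``male`` objects overriding any
    subset per sex; optional ``provenance`` string.
    """
    path = Path(path)
    if not path.exists():
        raise IOFormatError(f"{path}: file not found")
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise IOFormatError(f"{path}: invalid JSON ({e})") from e
    required = ("beta_sbp", "beta_tc", "beta_ratio", "beta_smoke")
    missing = [k for k in required if k not in raw]
    if missing:
        raise IOFormatError(f"{path}: missing key(s) {missing}")
    try:
        shared = CoefficientSet(**{k: float(raw[k]) for k in required})
        per_sex = {}
        for sex in SEXES:
            if sex in raw:
                merged = {k: float(raw[sex].get(k, raw[k])) for k in required}
                per_sex[sex] = CoefficientSet(**merged)
    except (TypeError, ValueError, ValidationError) as e:
        raise IOFormatError(f"{path}: {e}") from e
    return Coefficients(shared=shared, per_sex=per_sex,
                        provenance=str(raw.get("provenance", "unspecified")))


def write_coefficients(coefs: Coefficients, path: str | Path) -> None:
    doc: dict = {
        "beta_sbp": coefs.shared.beta_sbp,
        "beta_tc": coefs.shared.beta_tc,
        "beta_ratio": coefs.shared.beta_ratio,
        "beta_smoke": coefs.shared.beta_smoke,
        "provenance": coefs.provenance,
    }
    for sex, cs in coefs.per_sex.items():
        doc[sex] = {"beta_sbp": cs.beta_sbp, "beta_tc": cs.beta_tc,
                    "beta_ratio": cs.beta_ratio, "beta_smoke": cs.beta_smoke}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def _opt_float(v) -> float | None:
    return None if pd.isna(v) else float(v)


def _opt_bool(v) -> bool | None:
    if pd.isna(v):
        return None
    return bool(int(v))


def read_cohort(path: str | Path) -> list[CohortRecord]:
    """Load survey microdata; empty fields become missing values.

    Malformed cells are treated as missing with a logged warning (the
    eligibility filter then counts the record under the missing step).
    """
    df = _read_csv(path, COHORT_COLUMNS)
    records: list[CohortRecord] = []
    for i in df.index:
        row = df.loc[i]
        rid = str(row["id"])
        vals: dict = {"id": rid}
        try:
            sex = None if pd.isna(row["sex"]) else str(row["sex"]).strip()
            vals["sex"] = sex if sex in SEXES else None
            for col in ("age", "sbp", "tc", "hdl", "weight"):
                vals[col] = _opt_float(pd.to_numeric(row[col], errors="coerce"))
            for col in ("smoker", "prior_chd", "prior_stroke", "prior_hf"):
                vals[col] = _opt_bool(pd.to_numeric(row[col], errors="coerce"))
        except (TypeError, ValueError) as e:  # pragma: no cover - defensive
            log.warning("%s: data row %d malformed (%s); fields set missing", path, i + 1, e)
        records.append(CohortRecord(**vals))
    return records


def write_cohort(records: Sequence[CohortRecord], path: str | Path) -> None:
    def enc_bool(v):
        return "" if v is None else int(v)

    rows = []
    for r in records:
        rows.append({
            "id": r.id, "age": r.age, "sex": r.sex or "", "sbp": r.sbp, "tc": r.tc,
            "hdl": r.hdl, "smoker": enc_bool(r.smoker), "weight": r.weight,
            "prior_chd": enc_bool(r.prior_chd), "prior_stroke": enc_bool(r.prior_stroke),
            "prior_hf": enc_bool(r.prior_hf),
        })
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_chart_csv(path: str | Path) -> ChartGrid:
    """Load a long-format chart CSV back into a grid (inverse of the CSV
    renderer; raw risks are authoritative, display values are recomputed)."""
    df = _read_csv(path, ["chol_measure", "sex", "smoker", "age", "sbp", "chol", "risk_raw"])
    measures = set(df["chol_measure"].astype(str))
    if len(measures) != 1:
        raise IOFormatError(f"{path}: chart CSV must hold exactly one chol_measure, got {measures}")
    measure = CholMeasure(measures.pop())
    cells = {}
    for i in df.index:
        row = df.loc[i]
        key = (str(row["sex"]), bool(int(row["smoker"])), int(row["age"]),
               float(row["sbp"]), float(row["chol"]))
        if key in cells:
            raise IOFormatError(f"{path}: duplicate cell at data row {i + 1}")
        cells[key] = float(row["risk_raw"])
    ages = tuple(sorted({k[2] for k in cells}))
    sbps = tuple(sorted({k[3] for k in cells}))
    chols = tuple(sorted({k[4] for k in cells}))
    axes = ChartAxes(ages=ages, sbp_levels=sbps, chol_levels=chols)
    return ChartGrid(chol_measure=measure, axes=axes, cells=cells)
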