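"""Shared data model: microdata schema, equity dimensions, indicators, CSV I/O.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per live birth, carrying the mother's survey-design variables and equity
stratifiers alongside the birth-level outcomes.  Dates use the DHS
century-month code (CMC): ``cmc = (year - 1900) * 12 + month`` with month in
1..12, i.e. months elapsed since January 1900.

Equity stratifiers come in three kinds:

``ordered``
    Subgroups carry an inherent advantage ordering (wealth quintiles,
    education).  ``levels`` are listed worst-off first and the declared
    ``advantaged_level`` is the last level (richest quintile, secondary+).
``binary``
    Exactly two subgroups (urban/rural residence, neonate sex); the
    advantaged level is declared explicitly.
``non_ordered``
    No inherent ordering (subnational region); the best-off subgroup is
    found empirically from the estimates, so no advantaged level is declared.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import EmptyInputError, SchemaError

# ---------------------------------------------------------------------------
# canonical columns

#: Canonical microdata columns, one row per live birth.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "survey_year",
    "stratum_id",
    "cluster_id",
    "household_id",
    "woman_id",
    "weight",
    "region",
    "residence",
    "education",
    "wealth_quintile",
    "birth_cmc",
    "interview_cmc",
    "sba",
    "child_sex",
    "age_at_death_days",
)

#: Columns that must be present (``age_at_death_days`` may be absent entirely;
#: absent values mean the child survived the neonatal period).
REQUIRED_COLUMNS: tuple[str, ...] = tuple(
    c for c in CANONICAL_COLUMNS if c != "age_at_death_days"
)

WEALTH_LEVELS = ("Q1", "Q2", "Q3", "Q4", "Q5")
EDUCATION_LEVELS = ("none", "primary", "secondary+")
RESIDENCE_LEVELS = ("rural", "urban")
SEX_LEVELS = ("male", "female")

#: Guinea administrative regions: five domains in 1999, eight from 2005 on.
REGIONS_5 = ("Lower Guinea", "Central Guinea", "Upper Guinea", "Forest Guinea", "Conakry")
REGIONS_8 = ("Boke", "Conakry", "Faranah", "Kankan", "Kindia", "Labe", "Mamou", "Nzerekore")


def cmc(year: int, month: int) -> int:
    """Century-month code of a calendar month (month in 1..12)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return (year - 1900) * 12 + month


# ---------------------------------------------------------------------------
# dimension and indicator specs


@dataclass(frozen=True)
class DimensionSpec:
    """An equity stratifier: name, ordering kind, subgroup levels.

    Parameters
    ----------
    name : str
        Canonical column name holding the subgroup label.
    kind : {"ordered", "binary", "non_ordered"}
    levels : sequence of str
        Subgroup labels; for ordered dimensions listed worst-off -> best-off.
    advantaged_level : str, optional
        The structurally advantaged subgroup; required for ordered (must be
        the last level) and binary kinds, forbidden for non-ordered kinds.
    """

    name: str
    kind: str
    levels: tuple[str, ...]
    advantaged_level: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if self.kind not in ("ordered", "binary", "non_ordered"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if not self.levels:
            raise ValueError("levels must be non-empty")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("levels must be unique")
        if self.kind == "binary" and len(self.levels) != 2:
            raise ValueError("binary dimension needs exactly 2 levels")
        if self.kind == "non_ordered":
            if self.advantaged_level is not None:
                raise ValueError("non_ordered dimension must not declare an advantaged level")
        else:
            if self.advantaged_level is None:
                raise ValueError(f"{self.kind} dimension requires an advantaged_level")
            if self.advantaged_level not in self.levels:
                raise ValueError("advantaged_level must be one of the levels")
            if self.kind == "ordered" and self.advantaged_level != self.levels[-1]:
                raise ValueError("ordered levels must be listed worst->best "
                                 "(advantaged level last)")

    @property
    def disadvantaged_level(self) -> str | None:
        """The opposite extreme of the declared ordering (None if non-ordered)."""
        if self.kind == "non_ordered":
            return None
        if self.kind == "ordered":
            return self.levels[0]
        return next(l for l in self.levels if l != self.advantaged_level)


WEALTH = DimensionSpec("wealth_quintile", "ordered", WEALTH_LEVELS, "Q5")
EDUCATION = DimensionSpec("education", "ordered", EDUCATION_LEVELS, "secondary+")
RESIDENCE = DimensionSpec("residence", "binary", RESIDENCE_LEVELS, "urban")
CHILD_SEX = DimensionSpec("child_sex", "binary", SEX_LEVELS, "female")


def region_dimension(survey_year: int) -> DimensionSpec:
    """Region stratifier for a survey year (5 domains before 2005, 8 after)."""
    levels = REGIONS_5 if survey_year < 2005 else REGIONS_8
    return DimensionSpec("region", "non_ordered", levels)


def default_dimensions(survey_year: int, indicator: "IndicatorSpec | str | None" = None
                       ) -> list[DimensionSpec]:
    """Standard stratifier set for a survey: wealth, education, residence,
    region, plus neonate sex for the mortality indicator."""
    dims = [WEALTH, EDUCATION, RESIDENCE, region_dimension(survey_year)]
    name = indicator.name if isinstance(indicator, IndicatorSpec) else indicator
    if name == "nmr":
        dims.append(CHILD_SEX)
    return dims


@dataclass(frozen=True)
class IndicatorSpec:
    """A health indicator with its polarity, reporting scale and recall window.

    ``favorable`` indicators (coverage of care, e.g. skilled birth
    attendance) are better when higher; ``adverse`` indicators (mortality)
    are worse when higher.  Polarity flips the sign conventions of the
    summary measures.
    """

    name: str
    polarity: str  # favorable | adverse
    scale: str  # percent | per_1000
    recall_window_years: int

    def __post_init__(self) -> None:
        if self.polarity not in ("favorable", "adverse"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.scale not in ("percent", "per_1000"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.recall_window_years <= 0:
            raise ValueError("recall_window_years must be positive")

    @property
    def scale_factor(self) -> float:
        return 100.0 if self.scale == "percent" else 1000.0


#: Skilled birth attendance: favorable, percent scale, births in the 3 years
#: preceding the interview (configurable to 2 in the estimators).
SBA = IndicatorSpec("sba", "favorable", "percent", 3)
#: Neonatal mortality rate: adverse, per 1000 live births, deaths in the first
#: 28 completed days among births in the 5 years preceding the interview.
NMR = IndicatorSpec("nmr", "adverse", "per_1000", 5)

INDICATORS: Mapping[str, IndicatorSpec] = {"sba": SBA, "nmr": NMR}


def as_indicator(indicator: IndicatorSpec | str) -> IndicatorSpec:
    if isinstance(indicator, IndicatorSpec):
        return indicator
    try:
        return INDICATORS[indicator]
    except KeyError:
        raise ValueError(f"unknown indicator {indicator!r}; "
                         f"expected one of {sorted(INDICATORS)}") from None


# ---------------------------------------------------------------------------
# microdata I/O


@dataclass
class ReadReport:
    """Bookkeeping from :func:`read_microdata`: rows read, kept, dropped."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    reasons: dict[str, int] = field(default_factory=dict)


def load_schema(path: str | Path) -> dict[str, str]:
    """Load a column-name -> canonical-field map from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    schema = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(schema, dict):
        raise SchemaError(f"schema map in {path} must be a flat mapping")
    bad = [v for v in schema.values() if v not in CANONICAL_COLUMNS]
    if bad:
        raise SchemaError(f"schema maps to unknown canonical fields: {bad}")
    return {str(k): str(v) for k, v in schema.items()}


_INT_COLUMNS = ("survey_year", "birth_cmc", "interview_cmc", "sba")
_LABEL_COLUMNS = ("stratum_id", "cluster_id", "household_id", "woman_id",
                  "region", "residence", "education", "wealth_quintile", "child_sex")


def read_microdata(path: str | Path, schema: Mapping[str, str] | None = None
                   ) -> tuple[pd.DataFrame, ReadReport]:
    """Read birth-level microdata from CSV, validate, and drop invalid rows.

    Parameters
    ----------
    path : path
        UTF-8 comma-separated file with a header row; "." decimal marks.
    schema : mapping, optional
        Column-name -> canonical-field map for files whose headers differ
        from the canonical names (DHS/MICS exports vary).

    Returns
    -------
    (frame, report)
        ``frame`` contains only rows satisfying the record invariants
        (positive weight, birth not after interview, binary SBA flag,
        non-negative age at death); ``report`` counts dropped rows by reason.
        Missing stratifier *values* are kept (they are excluded per-dimension
        downstream), as are unknown stratifier labels, which
        :func:`validate_dimension` reports.

    Raises
    ------
    SchemaError
        If a required column is absent (the error names it).
    EmptyInputError
        If the file holds no data rows.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    if schema:
        df = df.rename(columns=dict(schema))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if "age_at_death_days" not in df.columns:
        df["age_at_death_days"] = pd.NA
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")

    report = ReadReport(n_rows=len(df))
    drop = pd.Series(False, index=df.index)

    def _flag(mask: pd.Series, reason: str) -> None:
        nonlocal drop
        mask = mask.fillna(False).astype(bool)
        n = int((mask & ~drop).sum())
        if n:
            report.reasons[reason] = report.reasons.get(reason, 0) + n
        drop = drop | mask

    weight = pd.to_numeric(df["weight"], errors="coerce")
    _flag(~(weight > 0) | ~np.isfinite(weight), "nonpositive_or_missing_weight")
    for col in ("birth_cmc", "interview_cmc"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        _flag(df[col].isna(), f"missing_{col}")
    _flag(df["birth_cmc"] > df["interview_cmc"], "birth_after_interview")
    sba = pd.to_numeric(df["sba"], errors="coerce")
    _flag(~sba.isin([0, 1]), "invalid_sba_flag")
    aad = pd.to_numeric(df["age_at_death_days"], errors="coerce")
    _flag(df["age_at_death_days"].notna() & (aad.isna() | (aad < 0)),
          "invalid_age_at_death")

    df = df.loc[~drop].copy()
    report.n_dropped = int(drop.sum())
    report.n_kept = len(df)
    if report.n_kept:
        df["weight"] = weight.loc[df.index].astype(float)
        df["sba"] = sba.loc[df.index].astype(np.int64)
        for col in ("survey_year", "birth_cmc", "interview_cmc"):
            df[col] = df[col].astype(np.int64)
        df["age_at_death_days"] = aad.loc[df.index].astype("Int64")
        for col in _LABEL_COLUMNS:
            df[col] = df[col].astype("string").str.strip()
    return df[list(CANONICAL_COLUMNS)].reset_index(drop=True), report


def write_microdata(frame: pd.DataFrame, path: str | Path) -> None:
    """Write microdata to canonical CSV (UTF-8, comma separated, "." decimal).

    Floats are written with shortest round-trip repr, so weights survive a
    write -> read cycle to full double precision.
    """
    cols = [c for c in CANONICAL_COLUMNS if c in frame.columns]
    frame[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dimension validation


@dataclass
class DimensionCheck:
    """Observed subgroup coverage of a dimension in a record set."""

    dimension: str
    counts: dict[str, int]
    unknown: dict[str, int]
    zero_levels: list[str]
    n_missing: int

    @property
    def ok(self) -> bool:
        return not self.unknown and not self.zero_levels


def validate_dimension(frame: pd.DataFrame, dim: DimensionSpec) -> DimensionCheck:
    """Count records per declared level of a stratifier.

    Unknown labels are reported separately; declared levels with zero
    observations are flagged with a warning (not an error) — e.g. a 5-region
    survey checked against an 8-region schema flags the 3 absent regions.
    """
    if dim.name not in frame.columns:
        raise SchemaError(f"dimension column {dim.name!r} not in frame")
    col = frame[dim.name]
    n_missing = int(col.isna().sum())
    observed = col.dropna().value_counts().to_dict()
    counts = {level: int(observed.pop(level, 0)) for level in dim.levels}
    unknown = {str(k): int(v) for k, v in observed.items()}
    zero_levels = [level for level, n in counts.items() if n == 0]
    if zero_levels:
        warnings.warn(
            f"dimension {dim.name!r}: no observations for level(s) "
            f"{', '.join(zero_levels)}", stacklevel=2)
    return DimensionCheck(dim.name, counts, unknown, zero_levels, n_missing)


def dimension_from_dict(d: Mapping) -> DimensionSpec:
    """Build a :class:`DimensionSpec` from a config mapping."""
    return DimensionSpec(
        name=d["name"], kind=d["kind"], levels=tuple(d["levels"]),
        advantaged_level=d.get("advantaged_level"),
    )


def indicator_from_dict(d: Mapping | str) -> IndicatorSpec:
    """Build an :class:`IndicatorSpec` from a config mapping or preset name."""
    if isinstance(d, str):
        return as_indicator(d)
    return IndicatorSpec(
        name=d["name"], polarity=d["polarity"], scale=d["scale"],
        recall_window_years=int(d["recall_window_years"]),
    )
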