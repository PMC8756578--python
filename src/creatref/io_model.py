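"""Measurement-record data model, pipeline configuration, and tabular I/O.

The pipeline's unit of data is one serum-creatinine draw: who (a
pseudonymized individual id), their sex, when they were born, when the
sample was drawn, the creatinine concentration in mg/dL, and an optional
flag marking any kidney or urinary-tract diagnosis. Records arrive as
headered CSV (UTF-8, ISO-8601 dates); a column map adapts arbitrary EHR
export headers to the canonical schema. Invalid rows are rejected and
reported with row-numbered diagnostics rather than aborting the run, unless
strict mode is requested — EHR extracts are dirty, and silent filtering at
the retrieval stage must stay auditable.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError, ValidationError

logger = logging.getLogger(__name__)

SEX_CODES = ("M", "F")

#: canonical record columns, in writing order
CANONICAL_COLUMNS = (
    "individual_id",
    "sex",
    "birth_date",
    "draw_date",
    "creatinine",
    "kidney_dx",
)

_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n", ""}


@dataclass(frozen=True)
class MeasurementRecord:
    """One validated laboratory draw.

    Invariants: ``creatinine`` is positive and finite, ``draw_date`` is not
    before ``birth_date``, and ``sex`` is one of ``"M"``/``"F"``.
    """

    individual_id: str
    sex: str
    birth_date: dt.date
    draw_date: dt.date
    creatinine: float  # mg/dL
    kidney_dx: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEX_CODES:
            raise ValidationError(f"sex must be one of {SEX_CODES}, got {self.sex!r}")
        if not np.isfinite(self.creatinine) or self.creatinine <= 0:
            raise ValidationError(
                f"creatinine must be positive and finite, got {self.creatinine!r}"
            )
        if self.draw_date < self.birth_date:
            raise ValidationError(
                f"draw_date {self.draw_date} precedes birth_date {self.birth_date}"
            )


@dataclass(frozen=True)
class PipelineConfig:
    """Constants of the estimation pipeline.

    fence_multiplier : Tukey fence factor k in Q3 + k·IQR (default 1.5).
    z_value          : normal multiplier for the parametric central-95%
                       limits, mean ± z·SD (default 1.96, the conventional
                       constant rather than the exact quantile).
    min_group_n      : adequacy threshold — a stratum with fewer reference
                       individuals is flagged as below the recommended
                       minimum of 120.
    rounding_decimals: decimals for reported limits (default 2).
    quantile_method  : interpolation rule tag for quartiles/percentiles
                       ("linear" = h=(n−1)p, the spreadsheet default; any
                       numpy.quantile method name; or "hinges").
    age_lower_days / age_upper_years : eligibility window, default
                       [30 days, 18 years) — neonates are excluded.
    study_window     : optional (start, end) draw-date filter, inclusive.
    multiplicity_scope : whether repeat-measurement counting spans the whole
                       study window ("study_window") or only age-eligible
                       draws ("age_eligible").
    collapse_same_day: collapse duplicate same-day draws per individual to
                       one before counting multiplicity (off by default:
                       same-day repeats signal monitoring).
    outlier_floor_n  : below this group size the fence is not applied.
    """

    fence_multiplier: float = 1.5
    z_value: float = 1.96
    min_group_n: int = 120
    rounding_decimals: int = 2
    quantile_method: str = "linear"
    age_lower_days: int = 30
    age_upper_years: float = 18.0
    study_window: Optional[tuple[dt.date, dt.date]] = None
    multiplicity_scope: str = "study_window"
    collapse_same_day: bool = False
    outlier_floor_n: int = 4

    def __post_init__(self) -> None:
        if self.fence_multiplier <= 0:
            raise ConfigurationError("fence_multiplier must be > 0")
        if self.z_value <= 0:
            raise ConfigurationError("z_value must be > 0")
        if self.rounding_decimals < 0:
            raise ConfigurationError("rounding_decimals must be >= 0")
        if not self.age_lower_days < self.age_upper_years * 365.25:
            raise ConfigurationError("age window is empty")
        if self.multiplicity_scope not in ("study_window", "age_eligible"):
            raise ConfigurationError(
                f"unknown multiplicity_scope {self.multiplicity_scope!r}"
            )
        if self.study_window is not None:
            start, end = self.study_window
            if start > end:
                raise ConfigurationError("study_window start is after its end")


@dataclass(frozen=True)
class ColumnMap:
    """Maps canonical field names to the CSV's actual headers.

    Either ``birth_date`` or ``age_days`` (a precomputed age at draw, whole
    days) must resolve to a present column; when both are present the birth
    date wins and a warning is logged.
    """

    individual_id: str = "individual_id"
    sex: str = "sex"
    birth_date: str = "birth_date"
    draw_date: str = "draw_date"
    creatinine: str = "creatinine"
    kidney_dx: str = "kidney_dx"
    age_days: str = "age_days"

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "ColumnMap":
        unknown = set(mapping) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown column-map keys: {sorted(unknown)}")
        return cls(**dict(mapping))


@dataclass(frozen=True)
class RowIssue:
    """A rejected input row: 1-based data-row number, field, and reason."""

    row: int
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}: {self.field}: {self.message}"


@dataclass
class ReadResult:
    """Validated records plus the diagnostics for every rejected row."""

    records: list[MeasurementRecord]
    issues: list[RowIssue] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def __len__(self) -> int:
        return len(self.records)


RecordsLike = Union[pd.DataFrame, Iterable[MeasurementRecord]]


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    """Canonical DataFrame view of a record collection (row order kept)."""
    rows = list(records)
    if not rows:
        return pd.DataFrame(
            {
                "individual_id": pd.Series(dtype=str),
                "sex": pd.Series(dtype=str),
                "birth_date": pd.Series(dtype="datetime64[ns]"),
                "draw_date": pd.Series(dtype="datetime64[ns]"),
                "creatinine": pd.Series(dtype=float),
                "kidney_dx": pd.Series(dtype=bool),
            }
        )
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in rows],
            "sex": [r.sex for r in rows],
            "birth_date": pd.to_datetime([r.birth_date for r in rows]),
            "draw_date": pd.to_datetime([r.draw_date for r in rows]),
            "creatinine": [r.creatinine for r in rows],
            "kidney_dx": [r.kidney_dx for r in rows],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[MeasurementRecord]:
    """Convert a canonical DataFrame back into validated records."""
    return [
        MeasurementRecord(
            individual_id=str(row.individual_id),
            sex=str(row.sex),
            birth_date=pd.Timestamp(row.birth_date).date(),
            draw_date=pd.Timestamp(row.draw_date).date(),
            creatinine=float(row.creatinine),
            kidney_dx=bool(row.kidney_dx),
        )
        for row in frame.itertuples(index=False)
    ]


def as_frame(records: RecordsLike) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def read_measurements(
    path: Union[str, Path],
    column_map: Union[ColumnMap, Mapping[str, str], None] = None,
    strict: bool = False,
) -> ReadResult:
    """Read a measurement CSV, validating every row.

    Rows violating the record invariants (non-positive or unparseable
    creatinine, bad dates, draw before birth, unknown sex code) are rejected
    and reported as :class:`RowIssue` with 1-based data-row numbers; the
    surviving records keep input order. With ``strict=True`` any issue
    raises :class:`ValidationError` carrying the full diagnostic list. A
    missing mapped column raises :class:`ConfigurationError`.
    """
    if column_map is None:
        cmap = ColumnMap()
    elif isinstance(column_map, ColumnMap):
        cmap = column_map
    else:
        cmap = ColumnMap.from_mapping(column_map)

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    required = {
        "individual_id": cmap.individual_id,
        "sex": cmap.sex,
        "draw_date": cmap.draw_date,
        "creatinine": cmap.creatinine,
    }
    missing = [col for col in required.values() if col not in raw.columns]
    if missing:
        raise ConfigurationError(f"missing required columns: {missing}")

    has_birth = cmap.birth_date in raw.columns
    has_age = cmap.age_days in raw.columns
    if not has_birth and not has_age:
        raise ConfigurationError(
            f"need a {cmap.birth_date!r} or {cmap.age_days!r} column"
        )
    if has_birth and has_age:
        logger.warning(
            "both %r and %r present; birth date takes precedence",
            cmap.birth_date,
            cmap.age_days,
        )

    draw = pd.to_datetime(raw[cmap.draw_date], errors="coerce", format="ISO8601")
    creat = pd.to_numeric(raw[cmap.creatinine], errors="coerce")
    if has_birth:
        birth = pd.to_datetime(raw[cmap.birth_date], errors="coerce", format="ISO8601")
    else:
        age_days = pd.to_numeric(raw[cmap.age_days], errors="coerce")
        birth = draw - pd.to_timedelta(age_days, unit="D")

    has_dx = cmap.kidney_dx in raw.columns

    records: list[MeasurementRecord] = []
    issues: list[RowIssue] = []
    for i in range(len(raw)):
        rownum = i + 1
        problems: list[tuple[str, str]] = []
        if pd.isna(draw.iloc[i]):
            problems.append(("draw_date", f"unparseable {raw[cmap.draw_date].iloc[i]!r}"))
        if pd.isna(birth.iloc[i]):
            src = cmap.birth_date if has_birth else cmap.age_days
            problems.append(("birth_date", f"unparseable {raw[src].iloc[i]!r}"))
        value = creat.iloc[i]
        if pd.isna(value) or not np.isfinite(value):
            problems.append(
                ("creatinine", f"unparseable {raw[cmap.creatinine].iloc[i]!r}")
            )
        elif value <= 0:
            problems.append(("creatinine", f"must be > 0, got {value}"))
        sex = raw[cmap.sex].iloc[i].strip().upper()
        if sex not in SEX_CODES:
            problems.append(("sex", f"unknown code {raw[cmap.sex].iloc[i]!r}"))
        kidney = False
        if has_dx:
            token = raw[cmap.kidney_dx].iloc[i].strip().lower()
            if token in _TRUE_TOKENS:
                kidney = True
            elif token in _FALSE_TOKENS:
                kidney = False
            else:
                problems.append(("kidney_dx", f"unparseable flag {token!r}"))
        if not problems and draw.iloc[i] < birth.iloc[i]:
            problems.append(
                ("draw_date", f"{draw.iloc[i].date()} precedes birth {birth.iloc[i].date()}")
            )

        if problems:
            # one diagnostic per bad row, all offending fields aggregated
            issues.append(
                RowIssue(
                    rownum,
                    ",".join(f for f, _ in problems),
                    "; ".join(m for _, m in problems),
                )
            )
            continue
        records.append(
            MeasurementRecord(
                individual_id=str(raw[cmap.individual_id].iloc[i]),
                sex=sex,
                birth_date=birth.iloc[i].date(),
                draw_date=draw.iloc[i].date(),
                creatinine=float(value),
                kidney_dx=kidney,
            )
        )

    if strict and issues:
        detail = "; ".join(str(s) for s in issues[:20])
        raise ValidationError(
            f"{len(issues)} invalid value(s) in {path}: {detail}", issues=issues
        )
    if issues:
        logger.warning("rejected values in %d row(s) of %s", len({s.row for s in issues}), path)
    return ReadResult(records=records, issues=issues)


def write_measurements(records: RecordsLike, path: Union[str, Path]) -> None:
    """Write records as canonical CSV (ISO dates, shortest-roundtrip floats)."""
    frame = as_frame(records).copy()
    frame["birth_date"] = pd.to_datetime(frame["birth_date"]).dt.strftime("%Y-%m-%d")
    frame["draw_date"] = pd.to_datetime(frame["draw_date"]).dt.strftime("%Y-%m-%d")
    frame["kidney_dx"] = frame["kidney_dx"].astype(bool).astype(int)
    frame.to_csv(path, index=False, columns=list(CANONICAL_COLUMNS))


REFERENCE_TABLE_COLUMNS = (
    "group",
    "sex",
    "n",
    "mean",
    "sd",
    "p2_5",
    "p97_5",
    "outliers_removed",
    "meets_min_n",
)


def write_reference_table(
    estimates: Sequence,
    path: Union[str, Path],
    config: Optional[PipelineConfig] = None,
) -> None:
    """Write per-stratum estimates as a reference-table CSV.

    One row per stratum with columns group label, sex, n, mean, SD, P2.5,
    P97.5 (parametric, rounded per config), outliers removed, and the
    minimum-n adequacy flag; rows ordered by ascending age with males before
    females. Duplicate (group, sex) pairs raise :class:`IntegrityError`.
    """
    from .reference_estimator import round_limit  # local import: no cycle

    config = config or PipelineConfig()
    d = config.rounding_decimals
    seen: set[tuple[str, str]] = set()
    rows = []
    for est in estimates:
        key = (est.group.label, est.group.sex)
        if key in seen:
            raise IntegrityError(f"duplicate stratum {key} in reference table")
        seen.add(key)
        rows.append(
            {
                "group": est.group.label,
                "sex": est.group.sex,
                "n": est.n,
                "mean": f"{round_limit(est.mean, d):.{d}f}",
                "sd": f"{round_limit(est.sd, d):.{d}f}",
                "p2_5": f"{round_limit(est.p2_5_param, d):.{d}f}",
                "p97_5": f"{round_limit(est.p97_5_param, d):.{d}f}",
                "outliers_removed": est.n_outliers_removed,
                "meets_min_n": int(est.meets_min_n),
                "_age": est.group.age_min_days,
            }
        )
    rows.sort(key=lambda r: (r["_age"], SEX_CODES.index(r["sex"])))
    frame = pd.DataFrame(rows, columns=list(REFERENCE_TABLE_COLUMNS) + ["_age"])
    frame.drop(columns="_age").to_csv(path, index=False)


def read_reference_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a reference-table CSV with numeric columns restored."""
    frame = pd.read_csv(path)
    for col in ("mean", "sd", "p2_5", "p97_5"):
        frame[col] = frame[col].astype(float)
    return frame
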