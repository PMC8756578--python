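"""Enrollment flow: age eligibility, single-measurement selection, and
assignment to the 36 age/sex strata.

The indirect design assumes individuals measured repeatedly are enriched
for acute or chronic kidney disease (serial renal-function follow-up), so
only individuals with a single draw in the study window enter the reference
population. Eligible ages span 1 month to 18 years; the first year is one
stratum and every later year its own stratum, per sex — 36 strata in all.
Neonates (< 30 days) are excluded: their creatinine reflects the maternal
level and falls through the first weeks of life.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, ValidationError
from .io_model import PipelineConfig, RecordsLike, SEX_CODES, as_frame

DAYS_PER_YEAR = 365.25
INFANT_MIN_DAYS = 30.0


@dataclass(frozen=True)
class AgeSexGroup:
    """One stratum: a sex and a half-open age window [min, max) in days."""

    label: str
    sex: str
    age_min_days: float
    age_max_days: float

    def __post_init__(self) -> None:
        if self.sex not in SEX_CODES:
            raise ValidationError(f"sex must be one of {SEX_CODES}")
        if not self.age_min_days < self.age_max_days:
            raise IntegrityError("age window is empty")

    def contains(self, age_days: float) -> bool:
        return self.age_min_days <= age_days < self.age_max_days


@dataclass
class FlowSummary:
    """Stage-by-stage enrollment counts.

    Invariants: final = single_measurement − outliers_removed and
    final = final_male + final_female.
    """

    n_measurements_retrieved: int = 0
    n_individuals_retrieved: int = 0
    n_single_measurement: int = 0
    n_outliers_removed: int = 0
    n_final: int = 0
    n_final_male: int = 0
    n_final_female: int = 0

    def validate(self) -> None:
        if self.n_final != self.n_single_measurement - self.n_outliers_removed:
            raise IntegrityError(
                "flow inconsistent: final != single_measurement - outliers_removed"
            )
        if self.n_final != self.n_final_male + self.n_final_female:
            raise IntegrityError("flow inconsistent: final != male + female")


def age_at_draw(birth_date: dt.date, draw_date: dt.date) -> int:
    """Age at draw as an exact count of whole calendar days."""
    days = (draw_date - birth_date).days
    if days < 0:
        raise ValidationError(
            f"draw date {draw_date} precedes birth date {birth_date}"
        )
    return days


def _bin_edges(age_lower_days: float, age_upper_years: float) -> np.ndarray:
    """Stratum edges in days: infant bin then yearly bins at 365.25-day
    multiples, the last capped below the upper age bound."""
    upper = age_upper_years * DAYS_PER_YEAR
    edges = [float(age_lower_days)]
    edges += [k * DAYS_PER_YEAR for k in range(1, int(age_upper_years))]
    edges.append(upper)
    return np.asarray(edges)


def _bin_labels(age_upper_years: float) -> list[str]:
    labels = ["Infant (1–12 months)"]
    labels += [f"{k}–{k + 1} years" for k in range(1, int(age_upper_years))]
    return labels


def default_groups(
    age_lower_days: float = INFANT_MIN_DAYS, age_upper_years: float = 18.0
) -> tuple[AgeSexGroup, ...]:
    """The default 36 strata.

    Per sex: one infant bin [30 days, 1 year) followed by seventeen 1-year
    bins with edges at 365.25-day multiples, the last ending just below 18
    years. Windows are half-open (lower bound inclusive) and tile
    [30 days, 18 years) with no gaps or overlaps.
    """
    edges = _bin_edges(age_lower_days, age_upper_years)
    labels = _bin_labels(age_upper_years)
    groups = []
    for sex in SEX_CODES:
        for label, lo, hi in zip(labels, edges[:-1], edges[1:]):
            groups.append(AgeSexGroup(label, sex, float(lo), float(hi)))
    return tuple(groups)


def _check_tiling(groups: Sequence[AgeSexGroup]) -> None:
    for sex in SEX_CODES:
        windows = sorted(
            (g.age_min_days, g.age_max_days) for g in groups if g.sex == sex
        )
        for (lo1, hi1), (lo2, _) in zip(windows, windows[1:]):
            if lo2 < hi1:
                raise IntegrityError(
                    f"overlapping {sex} age windows at {lo2:.2f} days"
                )


def assign_group(
    age_days: float, sex: str, groups: Sequence[AgeSexGroup]
) -> Optional[AgeSexGroup]:
    """The unique stratum containing this age and sex, or None.

    None is returned for ages outside every window (neonates below 30 days,
    ages at or past 18 years). Overlapping windows raise IntegrityError.
    """
    _check_tiling(groups)
    matches = [g for g in groups if g.sex == sex and g.contains(age_days)]
    if not matches:
        return None
    return matches[0]


def select_single_measurement(
    records: RecordsLike,
) -> tuple[pd.DataFrame, int]:
    """Keep only individuals with exactly one measurement.

    Returns the kept records (one row per surviving individual, input order
    preserved) and the count of excluded individuals (those with >= 2
    draws). Exclusion is by individual, not by record.
    """
    frame = as_frame(records)
    if frame.empty:
        return frame, 0
    counts = frame["individual_id"].value_counts()
    single_ids = counts[counts == 1].index
    kept = frame[frame["individual_id"].isin(single_ids)]
    return kept, int((counts > 1).sum())


def build_cohort(
    records: RecordsLike,
    groups: Optional[Sequence[AgeSexGroup]] = None,
    config: Optional[PipelineConfig] = None,
) -> tuple[dict[AgeSexGroup, np.ndarray], FlowSummary]:
    """Run the enrollment flow and pool creatinine values per stratum.

    Stages, in order: optional study-window filter; age-window eligibility
    at the draw date; single-measurement selection (multiplicity counted
    over the whole study window by default, see
    ``PipelineConfig.multiplicity_scope``); stratum assignment. Every kept
    record lands in exactly one stratum; values within a stratum are sorted
    ascending so the output is invariant under input row order.

    Returns the per-stratum value arrays (every stratum present, empty ones
    as zero-length arrays) and a flow-summary skeleton whose outlier fields
    are zero — the outlier stage completes it downstream.
    """
    config = config or PipelineConfig()
    if groups is None:
        groups = default_groups(config.age_lower_days, config.age_upper_years)
    _check_tiling(groups)

    frame = as_frame(records)
    if not frame.empty:
        bad_sex = ~frame["sex"].isin(SEX_CODES)
        if bad_sex.any():
            raise ValidationError(
                f"unmappable sex codes: {sorted(frame.loc[bad_sex, 'sex'].unique())}"
            )

    flow = FlowSummary()
    values: dict[AgeSexGroup, np.ndarray] = {
        g: np.empty(0, dtype=float) for g in groups
    }
    if frame.empty:
        return values, flow

    frame = frame.copy()
    if config.study_window is not None:
        start, end = (pd.Timestamp(d) for d in config.study_window)
        draw = pd.to_datetime(frame["draw_date"])
        frame = frame[(draw >= start) & (draw <= end)]
    if config.collapse_same_day:
        frame = frame.drop_duplicates(subset=["individual_id", "draw_date"])

    age = (
        pd.to_datetime(frame["draw_date"]) - pd.to_datetime(frame["birth_date"])
    ).dt.days.to_numpy()
    if (age < 0).any():
        raise ValidationError("draw before birth in cohort input")

    upper_days = config.age_upper_years * DAYS_PER_YEAR
    eligible = (age >= config.age_lower_days) & (age < upper_days)

    flow.n_measurements_retrieved = int(eligible.sum())
    flow.n_individuals_retrieved = int(
        frame.loc[eligible, "individual_id"].nunique()
    )

    if config.multiplicity_scope == "study_window":
        counts = frame["individual_id"].value_counts()
    else:
        counts = frame.loc[eligible, "individual_id"].value_counts()
    single_ids = set(counts[counts == 1].index)

    keep = eligible & frame["individual_id"].isin(single_ids).to_numpy()
    kept = frame[keep]
    kept_age = age[keep]
    flow.n_single_measurement = int(len(kept))
    flow.n_final = flow.n_single_measurement  # before outlier stage

    sexes = kept["sex"].to_numpy()
    creat = kept["creatinine"].to_numpy(dtype=float)
    by_sex_groups: dict[str, list[AgeSexGroup]] = {
        s: sorted((g for g in groups if g.sex == s), key=lambda g: g.age_min_days)
        for s in SEX_CODES
    }
    for sex in SEX_CODES:
        sgroups = by_sex_groups[sex]
        if not sgroups:
            continue
        edges = np.array([g.age_min_days for g in sgroups] + [sgroups[-1].age_max_days])
        mask = sexes == sex
        idx = np.searchsorted(edges, kept_age[mask], side="right") - 1
        vals = creat[mask]
        in_range = (idx >= 0) & (idx < len(sgroups))
        # within-tiling ages always land in a bin; guard for custom group sets
        for j, g in enumerate(sgroups):
            values[g] = np.sort(vals[in_range & (idx == j)])

    n_by_sex = kept["sex"].value_counts()
    flow.n_final_male = int(n_by_sex.get("M", 0))
    flow.n_final_female = int(n_by_sex.get("F", 0))
    return values, flow
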