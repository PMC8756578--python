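"""Per-stratum statistics, 95% reference limits, and their validity checks.

After exclusion and trimming, creatinine within an age/sex stratum is
treated as normal, so the central-95% reference interval is the parametric
mean ± 1.96·SD; the empirical 2.5th/97.5th order-statistic percentiles are
computed alongside as a distribution-free cross-check. The upper limit
(URL, the P97.5) is the clinically actionable threshold, and a valid URL
column must rise with age — creatinine tracks muscle mass — so any stratum
whose URL drops below its younger neighbour's is reported as a reversion
point. Strata below the recommended minimum of 120 reference individuals
are flagged as inadequate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort_builder import AgeSexGroup, FlowSummary
from .errors import DomainError
from .io_model import PipelineConfig, SEX_CODES
from .outlier_filter import remove_upper_outliers

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupEstimate:
    """Descriptive statistics and reference limits for one stratum.

    Parametric limits are mean ± z·sd, unrounded; empirical limits are the
    configured order-statistic percentiles. ``meets_min_n`` flags adequacy
    against the minimum-n recommendation.
    """

    group: AgeSexGroup
    n: int
    mean: float
    sd: float
    p2_5_param: float
    p97_5_param: float
    p2_5_emp: float
    p97_5_emp: float
    n_outliers_removed: int
    meets_min_n: bool


@dataclass(frozen=True)
class ReversionReport:
    """Age bins of one sex whose URL falls below the preceding bin's."""

    sex: str
    reversion_ages: tuple[str, ...] = ()

    @property
    def is_monotone(self) -> bool:
        return not self.reversion_ages


@dataclass(frozen=True)
class SensitivityResult:
    """Per-stratum agreement of rounded mean/SD between the full cohort and
    the cohort without diagnosis-flagged individuals."""

    agreement: Mapping[tuple[str, str], bool]
    excluded_fraction: float

    @property
    def all_agree(self) -> bool:
        return all(self.agreement.values())


def group_statistics(values) -> tuple[int, float, float]:
    """Sample size, arithmetic mean, and sample SD (n−1 denominator).

    n = 0 raises :class:`DomainError`; n = 1 yields sd = NaN with a logged
    flag, since a single observation carries no dispersion information.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DomainError("statistics of an empty sample are undefined")
    mean = float(np.mean(v))
    if v.size == 1:
        logger.warning("stratum of size 1: SD undefined")
        return 1, mean, float("nan")
    return int(v.size), mean, float(np.std(v, ddof=1))


def parametric_limits(mean: float, sd: float, z: float = 1.96) -> tuple[float, float]:
    """Normal-theory central-95% limits (mean − z·sd, mean + z·sd), unrounded."""
    if sd < 0 or not math.isfinite(sd):
        raise DomainError(f"sd must be finite and >= 0, got {sd}")
    return mean - z * sd, mean + z * sd


def empirical_limits(
    values, method: str = "linear", flag_below: int = 40
) -> tuple[float, float]:
    """Order-statistic 2.5th and 97.5th percentiles.

    Below ``flag_below`` observations the tails are poorly resolved and a
    warning is logged; the empty input raises :class:`DomainError`.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DomainError("percentiles of an empty sample are undefined")
    if v.size < flag_below:
        logger.warning("only %d values: empirical 95%% limits unreliable", v.size)
    if method == "hinges":  # hinge rule defines quartiles only; fall back
        method = "linear"
    lo, hi = np.quantile(v, [0.025, 0.975], method=method)
    return float(lo), float(hi)


def round_limit(x: float, decimals: int = 2) -> float:
    """Round half away from zero to the given decimals.

    Ordinary decimal rounding as a spreadsheet performs it (0.125 → 0.13),
    not banker's rounding.
    """
    if not math.isfinite(x):
        raise DomainError(f"cannot round non-finite value {x}")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def estimate_all(
    values_by_group: Mapping[AgeSexGroup, np.ndarray],
    config: Optional[PipelineConfig] = None,
    flow: Optional[FlowSummary] = None,
) -> tuple[list[GroupEstimate], FlowSummary]:
    """Fence, then estimate, every stratum; complete the flow summary.

    Applies the upper Tukey fence per stratum, computes descriptive
    statistics and both parametric and empirical limits on the kept values,
    and folds the per-stratum outlier counts into the flow summary. Empty
    strata are omitted with a logged warning. Estimates are returned in
    ascending age order, males before females within an age bin.
    """
    config = config or PipelineConfig()
    if flow is None:
        n_by_sex = {
            s: sum(len(v) for g, v in values_by_group.items() if g.sex == s)
            for s in SEX_CODES
        }
        n_total = sum(n_by_sex.values())
        flow = FlowSummary(
            n_single_measurement=n_total,
            n_final=n_total,
            n_final_male=n_by_sex["M"],
            n_final_female=n_by_sex["F"],
        )

    ordered = sorted(
        values_by_group.items(),
        key=lambda kv: (kv[0].age_min_days, SEX_CODES.index(kv[0].sex)),
    )
    estimates: list[GroupEstimate] = []
    total_removed = 0
    removed_by_sex = {s: 0 for s in SEX_CODES}
    for group, vals in ordered:
        if len(vals) == 0:
            logger.warning("stratum %s %s is empty; omitted", group.label, group.sex)
            continue
        fence = remove_upper_outliers(
            vals,
            fence_multiplier=config.fence_multiplier,
            method=config.quantile_method,
            size_floor=config.outlier_floor_n,
        )
        total_removed += fence.n_removed
        removed_by_sex[group.sex] += fence.n_removed
        n, mean, sd = group_statistics(fence.kept)
        if math.isnan(sd):
            lo_p = hi_p = mean
        else:
            lo_p, hi_p = parametric_limits(mean, sd, config.z_value)
        lo_e, hi_e = empirical_limits(fence.kept, method=config.quantile_method)
        estimates.append(
            GroupEstimate(
                group=group,
                n=n,
                mean=mean,
                sd=sd,
                p2_5_param=lo_p,
                p97_5_param=hi_p,
                p2_5_emp=lo_e,
                p97_5_emp=hi_e,
                n_outliers_removed=fence.n_removed,
                meets_min_n=n >= config.min_group_n,
            )
        )

    flow = replace(
        flow,
        n_outliers_removed=total_removed,
        n_final=flow.n_single_measurement - total_removed,
        n_final_male=flow.n_final_male - removed_by_sex["M"],
        n_final_female=flow.n_final_female - removed_by_sex["F"],
    )
    return estimates, flow


def detect_reversions(
    url_series: Sequence[tuple[str, float]], sex: str = "?"
) -> ReversionReport:
    """Find URL reversion points in an age-ordered (label, URL) series.

    A reversion is a bin whose URL is strictly lower than the preceding
    (younger) bin's; ties are not reversions. Fewer than two bins yield an
    empty report.
    """
    reversions = tuple(
        label
        for (_, prev), (label, cur) in zip(url_series, url_series[1:])
        if cur < prev
    )
    return ReversionReport(sex=sex, reversion_ages=reversions)


def sex_url_differences(
    estimates: Sequence[GroupEstimate],
    age_floor_years: float = 13.0,
    decimals: int = 2,
) -> tuple[float, float]:
    """Extremes of the male−female URL difference at and above an age floor.

    Differences are taken on rounded parametric URLs per shared age bin
    whose lower edge is at or above the floor; a bin present for one sex
    only raises :class:`DomainError`.
    """
    from .cohort_builder import DAYS_PER_YEAR

    floor_days = age_floor_years * DAYS_PER_YEAR - 1e-9
    urls: dict[str, dict[str, float]] = {s: {} for s in SEX_CODES}
    for est in estimates:
        if est.group.age_min_days >= floor_days:
            urls[est.group.sex][est.group.label] = round_limit(
                est.p97_5_param, decimals
            )
    if set(urls["M"]) != set(urls["F"]):
        raise DomainError(
            f"unpaired age bins above the floor: {set(urls['M']) ^ set(urls['F'])}"
        )
    if not urls["M"]:
        raise DomainError("no age bins at or above the floor")
    diffs = [
        round(urls["M"][label] - urls["F"][label], decimals) for label in urls["M"]
    ]
    return min(diffs), max(diffs)


def sensitivity_compare(
    full: Sequence[GroupEstimate],
    reduced: Sequence[GroupEstimate],
    decimals: int = 2,
) -> SensitivityResult:
    """Does dropping diagnosis-flagged individuals change any stratum?

    For each stratum, agreement is true iff the rounded means are equal and
    the rounded SDs are equal between the full cohort and the cohort with
    flagged individuals excluded. Also reports the overall excluded
    fraction. Mismatched stratum sets raise :class:`DomainError`.
    """
    fmap = {(e.group.label, e.group.sex): e for e in full}
    rmap = {(e.group.label, e.group.sex): e for e in reduced}
    if set(fmap) != set(rmap):
        raise DomainError("full and reduced estimates cover different strata")
    agreement = {
        key: (
            round_limit(fmap[key].mean, decimals) == round_limit(rmap[key].mean, decimals)
            and round_limit(fmap[key].sd, decimals) == round_limit(rmap[key].sd, decimals)
        )
        for key in fmap
    }
    n_full = sum(e.n for e in full)
    n_reduced = sum(e.n for e in reduced)
    fraction = 0.0 if n_full == 0 else 1.0 - n_reduced / n_full
    return SensitivityResult(agreement=agreement, excluded_fraction=fraction)
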