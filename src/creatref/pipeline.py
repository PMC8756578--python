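"""End-to-end driver: records in, reference table and validity checks out.

Chains the enrollment flow, the per-stratum upper fence, and the limit
estimation, then runs the validity checks (URL monotonicity per sex, the
adolescent sex-difference summary, and — when diagnosis flags are present —
the sensitivity comparison with flagged individuals excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort_builder import AgeSexGroup, FlowSummary, build_cohort
from .errors import DomainError
from .io_model import PipelineConfig, RecordsLike, SEX_CODES, as_frame
from .reference_estimator import (
    GroupEstimate,
    ReversionReport,
    SensitivityResult,
    detect_reversions,
    estimate_all,
    round_limit,
    sensitivity_compare,
    sex_url_differences,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    estimates: list[GroupEstimate]
    flow: FlowSummary
    reversions: dict[str, ReversionReport]
    sex_differences: Optional[tuple[float, float]] = None
    sensitivity: Optional[SensitivityResult] = None


def url_series_from_estimates(
    estimates: Sequence[GroupEstimate], sex: str, decimals: int = 2
) -> tuple[tuple[str, float], ...]:
    """Age-ordered (label, rounded parametric URL) series for one sex."""
    rows = sorted(
        (e for e in estimates if e.group.sex == sex),
        key=lambda e: e.group.age_min_days,
    )
    return tuple((e.group.label, round_limit(e.p97_5_param, decimals)) for e in rows)


def run_pipeline(
    records: RecordsLike,
    config: Optional[PipelineConfig] = None,
    groups: Optional[Sequence[AgeSexGroup]] = None,
    sex_difference_floor_years: float = 13.0,
) -> PipelineResult:
    """Full estimation run on a measurement collection."""
    config = config or PipelineConfig()
    frame = as_frame(records)

    values, flow = build_cohort(frame, groups=groups, config=config)
    estimates, flow = estimate_all(values, config=config, flow=flow)
    flow.validate()

    d = config.rounding_decimals
    reversions = {
        sex: detect_reversions(url_series_from_estimates(estimates, sex, d), sex)
        for sex in SEX_CODES
    }

    sex_differences = None
    try:
        sex_differences = sex_url_differences(
            estimates, age_floor_years=sex_difference_floor_years, decimals=d
        )
    except DomainError as exc:
        logger.warning("sex-difference summary unavailable: %s", exc)

    sensitivity = None
    if not frame.empty and bool(frame["kidney_dx"].any()):
        reduced_frame = frame[~frame["kidney_dx"].astype(bool)]
        red_values, red_flow = build_cohort(reduced_frame, groups=groups, config=config)
        red_estimates, _ = estimate_all(red_values, config=config, flow=red_flow)
        try:
            sensitivity = sensitivity_compare(estimates, red_estimates, decimals=d)
        except DomainError as exc:
            logger.warning("sensitivity comparison unavailable: %s", exc)

    return PipelineResult(
        estimates=estimates,
        flow=flow,
        reversions=reversions,
        sex_differences=sex_differences,
        sensitivity=sensitivity,
    )
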