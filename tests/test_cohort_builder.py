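"""Stratum definitions, enrollment flow, and its conservation properties."""

import datetime as dt

import numpy as np
import pytest

from creatref.cohort_builder import (
    DAYS_PER_YEAR,
    AgeSexGroup,
    age_at_draw,
    assign_group,
    build_cohort,
    default_groups,
    select_single_measurement,
)
from creatref.errors import IntegrityError, ValidationError
from creatref.io_model import PipelineConfig
from creatref.synthetic_cohort import SyntheticCohortConfig, generate_cohort

from conftest import make_frame


@pytest.mark.parametrize(
    "birth, draw, expected",
    [
        (dt.date(2010, 1, 1), dt.date(2010, 1, 31), 30),
        (dt.date(2010, 1, 1), dt.date(2010, 1, 1), 0),
        (dt.date(2004, 2, 29), dt.date(2018, 2, 28), 5113),
    ],
)
def test_age_at_draw_exact_calendar_days(birth, draw, expected):
    assert age_at_draw(birth, draw) == expected


def test_age_at_draw_rejects_draw_before_birth():
    with pytest.raises(ValidationError):
        age_at_draw(dt.date(2010, 1, 2), dt.date(2010, 1, 1))


def test_default_groups_structure():
    groups = default_groups()
    assert len(groups) == 36
    for sex in ("M", "F"):
        windows = sorted(
            (g.age_min_days, g.age_max_days) for g in groups if g.sex == sex
        )
        assert len(windows) == 18
        assert windows[0][0] == 30.0
        assert windows[-1][1] == pytest.approx(18 * DAYS_PER_YEAR)
        for (_, hi1), (lo2, _) in zip(windows, windows[1:]):
            assert hi1 == lo2  # no gaps, no overlaps


def test_assign_group_boundaries():
    groups = default_groups()
    infant = assign_group(180, "M", groups)
    assert infant is not None and infant.label == "Infant (1–12 months)"
    assert assign_group(20, "F", groups) is None  # neonate
    assert assign_group(18 * DAYS_PER_YEAR, "M", groups) is None  # adult
    at_edge = assign_group(14 * DAYS_PER_YEAR, "M", groups)
    assert at_edge is not None and at_edge.label == "14–15 years"


def test_assign_group_detects_overlap():
    bad = (
        AgeSexGroup("a", "M", 30, 400),
        AgeSexGroup("b", "M", 390, 800),
    )
    with pytest.raises(IntegrityError):
        assign_group(395, "M", bad)


def test_single_measurement_selection_by_individual():
    frame = make_frame(
        [
            ("A", "M", dt.date(2014, 1, 1), dt.date(2015, 1, 1), 0.30),
            ("B", "F", dt.date(2013, 1, 1), dt.date(2015, 1, 1), 0.35),
            ("B", "F", dt.date(2013, 1, 1), dt.date(2015, 2, 1), 0.90),
            ("B", "F", dt.date(2013, 1, 1), dt.date(2015, 3, 1), 1.10),
        ]
    )
    kept, excluded = select_single_measurement(frame)
    assert list(kept["individual_id"]) == ["A"]
    assert excluded == 1

    all_single = make_frame(
        [("x", "M", dt.date(2014, 1, 1), dt.date(2015, 1, 1), 0.3),
         ("y", "F", dt.date(2014, 1, 1), dt.date(2015, 1, 1), 0.3)]
    )
    kept, excluded = select_single_measurement(all_single)
    assert len(kept) == 2 and excluded == 0


def test_build_cohort_empty_input():
    values, flow = build_cohort(make_frame([]))
    assert len(values) == 36
    assert all(len(v) == 0 for v in values.values())
    assert flow.n_measurements_retrieved == 0
    assert flow.n_final == 0


def test_build_cohort_single_infant_lands_in_one_group():
    frame = make_frame(
        [("A", "M", dt.date(2015, 1, 1), dt.date(2015, 7, 1), 0.27)]
    )
    values, flow = build_cohort(frame)
    nonempty = {g: v for g, v in values.items() if len(v)}
    assert len(nonempty) == 1
    (group, vals), = nonempty.items()
    assert group.label == "Infant (1–12 months)" and group.sex == "M"
    assert vals.tolist() == [0.27]
    assert flow.n_single_measurement == 1


def test_build_cohort_rejects_unmappable_sex():
    frame = make_frame(
        [("A", "M", dt.date(2015, 1, 1), dt.date(2015, 7, 1), 0.27)]
    )
    frame.loc[0, "sex"] = "U"
    with pytest.raises(ValidationError):
        build_cohort(frame)


def test_multiplicity_counted_over_whole_window_by_default():
    # B's second draw is age-ineligible (>=18y) but still marks B as repeat-measured
    frame = make_frame(
        [
            ("B", "M", dt.date(2000, 1, 6), dt.date(2015, 1, 1), 0.60),
            ("B", "M", dt.date(2000, 1, 6), dt.date(2018, 6, 1), 0.90),
        ]
    )
    values, flow = build_cohort(frame)
    assert flow.n_single_measurement == 0
    eligible_only = PipelineConfig(multiplicity_scope="age_eligible")
    values, flow = build_cohort(frame, config=eligible_only)
    assert flow.n_single_measurement == 1


def test_conservation_and_order_invariance(default_cohort):
    config, frame = default_cohort
    sample = frame.iloc[:20000]
    values, flow = build_cohort(sample)
    assert sum(len(v) for v in values.values()) == flow.n_single_measurement
    assert flow.n_final_male + flow.n_final_female == flow.n_single_measurement

    shuffled = sample.sample(frac=1.0, random_state=3)
    values2, flow2 = build_cohort(shuffled)
    assert flow2 == flow
    for g in values:
        assert np.array_equal(values[g], values2[g])


def test_no_individual_kept_twice(default_cohort):
    _, frame = default_cohort
    kept, _ = select_single_measurement(frame.iloc[:30000])
    assert kept["individual_id"].is_unique


def test_kept_fraction_matches_binomial_oracle():
    p_multi = 0.3
    config = SyntheticCohortConfig(
        n_individuals=5000, p_multi=p_multi, contamination=0.0, seed=11
    )
    frame = generate_cohort(config)
    n = config.n_individuals
    kept, excluded = select_single_measurement(frame)
    se = np.sqrt(p_multi * (1 - p_multi) / n)
    assert abs(excluded / n - p_multi) < 3 * se
    assert abs(len(kept) / n - (1 - p_multi)) < 3 * se
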