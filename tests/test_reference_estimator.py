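"""Limits, rounding, reversion detection, and sensitivity comparison."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from creatref import published
from creatref.cohort_builder import AgeSexGroup, default_groups
from creatref.errors import DomainError
from creatref.io_model import PipelineConfig
from creatref.outlier_filter import remove_upper_outliers
from creatref.reference_estimator import (
    GroupEstimate,
    detect_reversions,
    empirical_limits,
    estimate_all,
    group_statistics,
    parametric_limits,
    round_limit,
    sensitivity_compare,
    sex_url_differences,
)


def test_group_statistics_hand_example():
    n, mean, sd = group_statistics([0.2, 0.4])
    assert n == 2
    assert mean == pytest.approx(0.3)
    assert sd == pytest.approx(0.1414, abs=1e-4)  # n-1 denominator


def test_group_statistics_degenerate():
    assert group_statistics([0.5, 0.5, 0.5])[2] == 0.0
    with pytest.raises(DomainError):
        group_statistics([])
    n, mean, sd = group_statistics([0.7])
    assert n == 1 and mean == 0.7 and math.isnan(sd)


@pytest.mark.parametrize(
    "mean, sd, expected",
    [
        (0.25, 0.07, (0.1128, 0.3872)),
        (0.61, 0.09, (0.4336, 0.7864)),
        (0.4, 0.0, (0.4, 0.4)),
    ],
)
def test_parametric_limits_hand_arithmetic(mean, sd, expected):
    lo, hi = parametric_limits(mean, sd, 1.96)
    assert (lo, hi) == (pytest.approx(expected[0]), pytest.approx(expected[1]))


def test_parametric_limits_rejects_negative_sd():
    with pytest.raises(DomainError):
        parametric_limits(0.5, -0.1)


@given(
    mean=st.floats(min_value=0.1, max_value=2, allow_nan=False),
    sd=st.floats(min_value=0, max_value=0.5, allow_nan=False),
)
def test_parametric_limits_symmetric_about_mean(mean, sd):
    lo, hi = parametric_limits(mean, sd)
    assert lo + hi == pytest.approx(2 * mean, rel=1e-12)


def test_empirical_limits_matches_sorted_interpolation_oracle():
    values = np.arange(1.0, 41.0)  # 1..40
    lo, hi = empirical_limits(values, method="linear")
    # oracle: h = (n-1)p on the sorted values
    for p, got in ((0.025, lo), (0.975, hi)):
        h = (len(values) - 1) * p
        f = int(np.floor(h))
        expected = values[f] + (h - f) * (values[f + 1] - values[f])
        assert got == pytest.approx(expected)


def test_empirical_limits_degenerate():
    assert empirical_limits([0.3] * 50) == (0.3, 0.3)
    with pytest.raises(DomainError):
        empirical_limits([])


def test_empirical_agrees_with_parametric_on_large_normal_sample():
    rng = np.random.default_rng(5)
    values = rng.normal(0.5, 0.08, size=100_000)
    n, mean, sd = group_statistics(values)
    plo, phi = parametric_limits(mean, sd)
    elo, ehi = empirical_limits(values)
    assert abs(plo - elo) < 0.01
    assert abs(phi - ehi) < 0.01


@pytest.mark.parametrize(
    "x, decimals, expected",
    [
        (0.7864, 2, 0.79),
        (0.125, 2, 0.13),  # half away from zero, not banker's
        (-0.125, 2, -0.13),
        (0.4336, 2, 0.43),
        (2.5, 0, 3.0),
    ],
)
def test_round_limit_half_away_from_zero(x, decimals, expected):
    assert round_limit(x, decimals) == expected


@given(st.floats(min_value=-10, max_value=10, allow_nan=False))
def test_round_limit_idempotent(x):
    once = round_limit(x, 2)
    assert round_limit(once, 2) == once


@given(
    values=st.lists(
        st.floats(min_value=0.05, max_value=2, allow_nan=False),
        min_size=8, max_size=40,
    ),
    shift=st.floats(min_value=0.0, max_value=5.0, allow_nan=False),
)
def test_constant_shift_moves_all_statistics_by_shift(values, shift):
    n, mean, sd = group_statistics(values)
    lo, hi = parametric_limits(mean, sd)
    fence = remove_upper_outliers(values).upper_fence
    shifted = [v + shift for v in values]
    n2, mean2, sd2 = group_statistics(shifted)
    lo2, hi2 = parametric_limits(mean2, sd2)
    fence2 = remove_upper_outliers(shifted).upper_fence
    assert mean2 == pytest.approx(mean + shift, abs=1e-9)
    assert lo2 == pytest.approx(lo + shift, abs=1e-9)
    assert hi2 == pytest.approx(hi + shift, abs=1e-9)
    assert fence2 == pytest.approx(fence + shift, abs=1e-9)


def _values_by_group(rng, n_per_group=80):
    values = {}
    for g in default_groups():
        mean, sd = published.GROUP_PARAMS[(g.label, g.sex)]
        values[g] = rng.normal(mean, sd, size=n_per_group)
    return values


def test_estimate_all_counts_and_flow():
    rng = np.random.default_rng(2)
    values = _values_by_group(rng)
    config = PipelineConfig(min_group_n=120)
    estimates, flow = estimate_all(values, config=config)
    assert len(estimates) == 36
    # per-group n equals the post-fence kept count
    for est in estimates:
        fence = remove_upper_outliers(
            values[est.group], method=config.quantile_method
        )
        assert est.n == len(fence.kept)
        assert est.n_outliers_removed == fence.n_removed
        assert not est.meets_min_n  # 80 per group is below the minimum
    flow.validate()
    assert flow.n_outliers_removed == sum(e.n_outliers_removed for e in estimates)
    assert flow.n_final == sum(e.n for e in estimates)


def test_estimate_all_omits_empty_groups():
    groups = default_groups()
    values = {g: np.empty(0) for g in groups}
    values[groups[0]] = np.array([0.2, 0.25, 0.3, 0.31])
    estimates, _ = estimate_all(values)
    assert len(estimates) == 1


def _published_estimates():
    """GroupEstimate stand-ins carrying the published rounded values."""
    groups = {(g.label, g.sex): g for g in default_groups()}
    return [
        GroupEstimate(
            group=groups[(label, sex)], n=n, mean=mean, sd=sd,
            p2_5_param=p25, p97_5_param=p975, p2_5_emp=p25, p97_5_emp=p975,
            n_outliers_removed=0, meets_min_n=n >= 120,
        )
        for label, sex, n, mean, sd, p25, p975 in published.REFERENCE_TABLE
    ]


def test_reversions_on_external_study_fixtures():
    for name, series in published.EXTERNAL_URL_SERIES.items():
        sex = "F" if name.endswith("female") else "M"
        report = detect_reversions(series, sex=sex)
        assert report.reversion_ages == published.EXTERNAL_REVERSION_CELLS[name]


def test_no_reversions_in_monotone_series():
    assert detect_reversions(published.url_series("M"), "M").is_monotone
    increasing = tuple((f"g{i}", 0.3 + 0.05 * i) for i in range(10))
    assert detect_reversions(increasing, "M").is_monotone
    assert detect_reversions(increasing[:1], "M").is_monotone  # < 2 bins


def test_ties_are_not_reversions():
    series = (("a", 0.40), ("b", 0.40), ("c", 0.45))
    assert detect_reversions(series, "F").is_monotone


def test_sex_url_differences_from_published_table():
    estimates = _published_estimates()
    assert sex_url_differences(estimates, age_floor_years=13) == (0.11, 0.23)
    only_16_17 = [
        e for e in estimates if e.group.label == "16–17 years"
    ]
    assert sex_url_differences(only_16_17, age_floor_years=16) == (0.23, 0.23)


def test_sex_url_differences_identical_sexes_and_missing_pair():
    estimates = _published_estimates()
    males = [e for e in estimates if e.group.sex == "M"]
    with pytest.raises(DomainError):
        sex_url_differences(males, age_floor_years=13)
    # identical values for both sexes -> zero differences
    groups = {(g.label, g.sex): g for g in default_groups()}
    same = [
        GroupEstimate(groups[("17–18 years", s)], 500, 0.7, 0.1,
                      0.504, 0.896, 0.5, 0.9, 0, True)
        for s in ("M", "F")
    ]
    assert sex_url_differences(same, age_floor_years=17) == (0.0, 0.0)


def test_sensitivity_compare_identity_and_mismatch():
    estimates = _published_estimates()
    result = sensitivity_compare(estimates, estimates)
    assert result.all_agree
    assert result.excluded_fraction == 0.0
    with pytest.raises(DomainError):
        sensitivity_compare(estimates, estimates[:-1])
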