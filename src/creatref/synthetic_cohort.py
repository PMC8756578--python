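"""Synthetic EHR-like creatinine cohorts with known ground truth.

The source population for indirect reference intervals is a hospital
database that cannot be redistributed, so the generator emulates its
statistical structure: ~44k children with ~152k draws between 1 month and
18 years of age, where most individuals are healthy and measured once,
while repeat-measured individuals (serial renal-function follow-up) are
enriched for elevated creatinine. Healthy values are normal within each
age/sex stratum, truncated at a small positive floor; a configurable
fraction of repeat-measured individuals carries a multiplicative
log-normal elevation shared across their draws (an AKI/CKD state persists
across a follow-up episode). Single-measurement individuals carry a
kidney/urinary diagnosis flag with a small probability, independent of
their value.

Because the true per-stratum mean and SD are known, every downstream stage
can be tested for parameter recovery without any external data.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import published
from .cohort_builder import AgeSexGroup, default_groups
from .errors import ConfigurationError, GroupLookupError
from .io_model import SEX_CODES

GroupKey = tuple[str, str]  # (age-bin label, sex)


def _default_group_params() -> dict[GroupKey, tuple[float, float]]:
    return dict(published.GROUP_PARAMS)


@dataclass
class SyntheticCohortConfig:
    """Generator parameters.

    n_individuals   : cohort size (default 44,197, the emulated study's
                      retrieved-individual count).
    group_params    : true (mean, SD) in mg/dL per (age-bin label, sex);
                      defaults to the published reference table, so the
                      default cohort reproduces a table of that shape end
                      to end.
    group_weights   : how individuals spread over strata — "reference_n"
                      (proportional to the published per-stratum counts,
                      the default), "age_uniform" (proportional to bin
                      width), or an explicit per-stratum weight mapping.
    p_multi         : probability an individual is repeat-measured
                      (default 0.353 = 1 − 28,595/44,197).
    repeat_count_law: draw-count distribution for repeat-measured
                      individuals, ("constant", k) or
                      ("shifted_geometric", mean); the default mean of 7.9
                      draws reproduces the emulated ~152k total draws.
    contamination   : fraction of repeat-measured individuals with an
                      elevated-creatinine state (default 0.2).
    elevation_median: median multiplicative elevation factor (default 2);
                      factors are 1 + log-normal excess, hence always > 1.
    elevation_sigma : log-scale spread of the elevation excess.
    p_kidney_dx_single: probability a single-measurement individual carries
                      the kidney/urinary diagnosis flag (default 0.021),
                      independent of the value.
    draw_window     : calendar window for first draws.
    value_floor     : truncation floor for healthy values, mg/dL.
    seed            : RNG seed; identical configs yield identical cohorts.
    """

    n_individuals: int = 44_197
    group_params: Mapping[GroupKey, tuple[float, float]] = field(
        default_factory=_default_group_params
    )
    group_weights: Union[str, Mapping[GroupKey, float]] = "reference_n"
    p_multi: float = 0.353
    repeat_count_law: tuple[str, float] = ("shifted_geometric", 7.9)
    contamination: float = 0.2
    elevation_median: float = 2.0
    elevation_sigma: float = 0.5
    p_kidney_dx_single: float = 0.021
    draw_window: tuple[dt.date, dt.date] = (dt.date(2011, 5, 1), dt.date(2018, 1, 31))
    value_floor: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_multi", "contamination", "p_kidney_dx_single"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.n_individuals < 0:
            raise ConfigurationError("n_individuals must be >= 0")
        law, param = self.repeat_count_law
        if law not in ("constant", "shifted_geometric"):
            raise ConfigurationError(f"unknown repeat_count_law {law!r}")
        if param < 2:
            raise ConfigurationError("repeat-measured individuals need >= 2 draws")
        if self.elevation_median <= 1:
            raise ConfigurationError("elevation_median must exceed 1")
        missing = [
            (g.label, g.sex)
            for g in default_groups()
            if (g.label, g.sex) not in self.group_params
        ]
        if missing:
            raise ConfigurationError(f"group_params missing strata: {missing}")
        for key, (mean, sd) in self.group_params.items():
            if mean <= 0 or sd < 0:
                raise ConfigurationError(f"invalid (mean, sd) for {key}")


def true_limits(
    config: SyntheticCohortConfig,
    group: Union[AgeSexGroup, GroupKey],
    z: float = 1.96,
) -> tuple[float, float]:
    """True parametric central-95% limits (unrounded) of one stratum."""
    key = (group.label, group.sex) if isinstance(group, AgeSexGroup) else tuple(group)
    try:
        mean, sd = config.group_params[key]
    except KeyError:
        raise GroupLookupError(f"no true parameters for stratum {key}") from None
    return mean - z * sd, mean + z * sd


def truth_table(config: SyntheticCohortConfig, z: float = 1.96) -> pd.DataFrame:
    """Per-stratum true parameters and limits, in reference-table order."""
    rows = []
    for g in default_groups():
        mean, sd = config.group_params[(g.label, g.sex)]
        lo, hi = true_limits(config, g, z=z)
        rows.append(
            {"group": g.label, "sex": g.sex, "true_mean": mean, "true_sd": sd,
             "true_p2_5": lo, "true_p97_5": hi}
        )
    return pd.DataFrame(rows)


def _group_weights(config: SyntheticCohortConfig, groups) -> np.ndarray:
    if isinstance(config.group_weights, str):
        if config.group_weights == "reference_n":
            w = np.array([published.GROUP_N[(g.label, g.sex)] for g in groups], float)
        elif config.group_weights == "age_uniform":
            w = np.array([g.age_max_days - g.age_min_days for g in groups], float)
        else:
            raise ConfigurationError(
                f"unknown group_weights tag {config.group_weights!r}"
            )
    else:
        try:
            w = np.array(
                [config.group_weights[(g.label, g.sex)] for g in groups], float
            )
        except KeyError as exc:
            raise ConfigurationError(f"group_weights missing stratum {exc}") from None
    if (w < 0).any() or w.sum() <= 0:
        raise ConfigurationError("group weights must be non-negative, not all zero")
    return w / w.sum()


def _repeat_counts(config: SyntheticCohortConfig, n: int, rng) -> np.ndarray:
    law, param = config.repeat_count_law
    if law == "constant":
        return np.full(n, int(param))
    # shifted geometric: 1 + Geometric with mean (param - 1), support >= 2
    return 1 + rng.geometric(1.0 / (param - 1.0), size=n)


def _truncated_normal(mean, sd, floor, rng) -> np.ndarray:
    """Normal draws re-sampled until every value exceeds the floor."""
    out = rng.normal(mean, sd)
    bad = out <= floor
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd[bad])
        bad = out <= floor
    return out


def generate_cohort(config: Optional[SyntheticCohortConfig] = None) -> pd.DataFrame:
    """Generate one cohort as a canonical measurement DataFrame.

    Deterministic given the config (including its seed). Each individual
    gets a sex, a stratum, a birth date back-computed from a uniformly
    placed first draw, and 1 or >= 2 draws; repeat draws are spaced days to
    weeks apart and their values follow the stratum the individual has
    aged into at each draw.
    """
    config = config or SyntheticCohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = default_groups()
    n = config.n_individuals
    if n == 0:
        from .io_model import records_to_frame

        return records_to_frame([])

    # per-individual structure
    gidx = rng.choice(len(groups), size=n, p=_group_weights(config, groups))
    sex = np.array([g.sex for g in groups])[gidx]
    lo = np.array([g.age_min_days for g in groups])[gidx]
    hi = np.array([g.age_max_days for g in groups])[gidx]
    age0 = np.floor(rng.uniform(lo, hi)).astype(np.int64)

    window_start, window_end = config.draw_window
    window_days = (window_end - window_start).days
    draw0 = rng.integers(0, window_days + 1, size=n)

    is_multi = rng.random(n) < config.p_multi
    counts = np.ones(n, dtype=np.int64)
    n_multi = int(is_multi.sum())
    if n_multi:
        counts[is_multi] = _repeat_counts(config, n_multi, rng)

    contaminated = is_multi & (rng.random(n) < config.contamination)
    factor = np.ones(n)
    n_cont = int(contaminated.sum())
    if n_cont:
        factor[contaminated] = 1.0 + rng.lognormal(
            np.log(config.elevation_median - 1.0), config.elevation_sigma, size=n_cont
        )
    kidney = np.where(
        is_multi, contaminated, rng.random(n) < config.p_kidney_dx_single
    )

    # expand to one row per draw
    owner = np.repeat(np.arange(n), counts)
    total = len(owner)
    offsets = np.zeros(total, dtype=np.int64)
    extra = total - n
    if extra:
        gaps = rng.integers(3, 29, size=extra)  # days between successive draws
        first_of_owner = np.ones(total, dtype=bool)
        first_of_owner[1:] = owner[1:] != owner[:-1]
        raw = np.zeros(total, dtype=np.int64)
        raw[~first_of_owner] = gaps
        csum = np.cumsum(raw)
        # subtract each individual's first-row cumsum to restart at zero
        offsets = csum - np.repeat(csum[first_of_owner], counts)

    draw_day = draw0[owner] + offsets
    age_at_draw = age0[owner] + offsets

    # stratum parameters at each draw's age (clamped to the covered range)
    edges = np.array(
        [g.age_min_days for g in groups if g.sex == "M"]
        + [max(g.age_max_days for g in groups)]
    )
    bin_idx = np.clip(
        np.searchsorted(edges, age_at_draw, side="right") - 1, 0, len(edges) - 2
    )
    labels_by_bin = [g.label for g in groups if g.sex == "M"]
    mean_lut = np.array(
        [
            [config.group_params[(label, s)][0] for label in labels_by_bin]
            for s in SEX_CODES
        ]
    )
    sd_lut = np.array(
        [
            [config.group_params[(label, s)][1] for label in labels_by_bin]
            for s in SEX_CODES
        ]
    )
    sex_idx = (sex[owner] == "F").astype(int)
    means = mean_lut[sex_idx, bin_idx]
    sds = sd_lut[sex_idx, bin_idx]
    values = _truncated_normal(means, sds, config.value_floor, rng)
    values = values * factor[owner]

    start = pd.Timestamp(window_start)
    draw_dates = start + pd.to_timedelta(draw_day, unit="D")
    birth_dates = start + pd.to_timedelta(draw0 - age0, unit="D")

    width = max(6, len(str(n)))
    ids = np.char.add("P", np.char.zfill(np.arange(n).astype(str), width))
    return pd.DataFrame(
        {
            "individual_id": ids[owner],
            "sex": sex[owner],
            "birth_date": birth_dates[owner],
            "draw_date": draw_dates,
            "creatinine": values,
            "kidney_dx": kidney[owner],
        }
    )
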