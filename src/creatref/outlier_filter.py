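"""Per-stratum Tukey upper-fence outlier removal.

Some individuals with impaired renal function have only a single draw and
so survive the repeat-measurement exclusion; a one-sided Tukey fence per
stratum counters this. Values strictly above Q3 + k·IQR (k = 1.5 by
default) are removed in a single pass — the fence is never recomputed on
the trimmed data, and low values are retained by design: only elevated
creatinine marks disease here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

#: method tags accepted for quantile interpolation; "hinges" is Tukey's
#: median-of-halves rule, the rest are numpy.quantile method names.
QUANTILE_METHODS = (
    "linear",
    "hinges",
    "hazen",
    "weibull",
    "median_unbiased",
    "normal_unbiased",
    "inverted_cdf",
    "averaged_inverted_cdf",
    "closest_observation",
    "interpolated_inverted_cdf",
    "lower",
    "higher",
    "midpoint",
    "nearest",
)


@dataclass(frozen=True)
class FenceResult:
    """Outcome of one fence application on one stratum's values."""

    q1: float
    q3: float
    iqr: float
    upper_fence: float
    kept: np.ndarray
    n_removed: int
    below_size_floor: bool = False

    @property
    def n_input(self) -> int:
        return len(self.kept) + self.n_removed


def _hinges(values: np.ndarray) -> tuple[float, float]:
    """Tukey hinges: medians of the lower and upper half, median included
    in both halves when n is odd."""
    v = np.sort(values)
    n = len(v)
    half = (n + 1) // 2
    return float(np.median(v[:half])), float(np.median(v[n - half:]))


def quartiles(values, method: str = "linear") -> tuple[float, float]:
    """First and third quartile of the values under the chosen rule.

    "linear" interpolates at h = (n−1)p, the spreadsheet-default rule the
    original analysis toolchain implies. The input is never modified; the
    empty input raises :class:`DomainError`.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DomainError("quartiles of an empty sample are undefined")
    if not np.isfinite(v).all():
        raise DomainError("quartiles require finite values")
    if method not in QUANTILE_METHODS:
        raise ConfigurationError(f"unknown quantile method {method!r}")
    if method == "hinges":
        return _hinges(v)
    q1, q3 = np.quantile(v, [0.25, 0.75], method=method)
    return float(q1), float(q3)


def remove_upper_outliers(
    values,
    fence_multiplier: float = 1.5,
    method: str = "linear",
    size_floor: int = 4,
) -> FenceResult:
    """Single-pass upper Tukey fence on one stratum.

    Removes exactly the values strictly above Q3 + fence_multiplier·IQR.
    Groups smaller than ``size_floor`` are flagged and returned untrimmed —
    quartiles of a handful of points carry no outlier information.
    """
    if fence_multiplier <= 0:
        raise ConfigurationError("fence_multiplier must be > 0")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DomainError("cannot fence an empty sample")
    q1, q3 = quartiles(v, method=method)
    iqr = q3 - q1
    fence = q3 + fence_multiplier * iqr
    if v.size < size_floor:
        return FenceResult(q1, q3, iqr, fence, kept=v.copy(), n_removed=0,
                           below_size_floor=True)
    keep_mask = v <= fence
    return FenceResult(
        q1=q1,
        q3=q3,
        iqr=iqr,
        upper_fence=fence,
        kept=v[keep_mask],
        n_removed=int((~keep_mask).sum()),
    )
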