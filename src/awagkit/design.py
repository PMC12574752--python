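"""Sample-size design for a single-proportion precision target.

n = ceil( z^2 * p * (1 - p) / delta^2 ),  z = z_{1 - alpha*/2},

where alpha* is the Bonferroni-adjusted significance level alpha/n_tests
and delta the absolute precision.  The adjusted level is rounded to 4
decimal places before taking the quantile, matching the convention of
reporting the adjusted level to that precision (e.g. 0.05/3 -> .0167,
z = 2.393); the rounding is configurable.  A nonresponse inflation step
divides by the expected response fraction, again with ceiling rounding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

__all__ = ["SampleSizeSpec", "required_sample_size", "adjust_for_nonresponse"]


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the single-proportion sample-size formula."""

    alpha: float = 0.05
    n_tests: int = 3
    p: float = 0.5
    delta: float = 0.04
    nonresponse_rate: float = 0.0
    alpha_precision: int | None = 4
    z_override: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not 0 <= self.nonresponse_rate < 1:
            raise ValueError("nonresponse_rate must be in [0, 1)")

    @property
    def adjusted_alpha(self) -> float:
        a = self.alpha / self.n_tests
        if self.alpha_precision is not None:
            a = round(a, self.alpha_precision)
        return a

    @property
    def z(self) -> float:
        z = float(stats.norm.ppf(1 - self.adjusted_alpha / 2))
        if self.z_override is not None:
            if abs(self.z_override - z) > 5e-3:
                warnings.warn(
                    f"supplied z={self.z_override} differs from the quantile "
                    f"z={z:.4f} at the adjusted level {self.adjusted_alpha}",
                    UserWarning,
                    stacklevel=2,
                )
            return float(self.z_override)
        return z


def required_sample_size(spec: SampleSizeSpec) -> int:
    """Minimum sample size before nonresponse inflation (ceiling-rounded)."""
    z = spec.z
    n = z * z * spec.p * (1 - spec.p) / (spec.delta * spec.delta)
    return math.ceil(n)


def adjust_for_nonresponse(n: int, rate: float) -> int:
    """Inflate a sample size for an anticipated nonresponse fraction."""
    if not 0 <= rate < 1:
        raise ValueError("nonresponse rate must be in [0, 1)")
    if n < 0:
        raise ValueError("n must be >= 0")
    return math.ceil(n / (1 - rate))
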