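"""DNA bend-angle estimation from circular-permutation gel-shift assays.

A protein-induced bend retards a DNA fragment most when it sits at the
fragment centre.  Under a planar-bend assumption the ratio of relative
mobilities, mu_M / mu_E (binding site at the middle vs at the end), gives the
apparent bend angle alpha through  mu_M / mu_E = cos(alpha / 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["BendMeasurement", "BendSummary", "bend_angle", "summarize_angles"]


@dataclass(frozen=True)
class BendMeasurement:
    """Relative mobilities from one circular-permutation experiment."""

    mu_M: float      # site centred
    mu_E: float      # site at the end
    replicate: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.mu_M <= self.mu_E):
            raise ValueError(
                "need 0 < mu_M <= mu_E (bent DNA migrates slower when the "
                "bend is central)"
            )


@dataclass(frozen=True)
class BendSummary:
    mean_deg: float
    sd_deg: float
    ci_low_deg: float | None
    ci_high_deg: float | None
    confidence: float
    n: int
    angles_deg: tuple[float, ...]


def bend_angle(mu_M: float, mu_E: float) -> float:
    """Apparent bend angle in degrees from the mobility ratio mu_M / mu_E."""
    if mu_E <= 0:
        raise ValueError("mu_E must be > 0")
    ratio = mu_M / mu_E
    if not 0 < ratio <= 1:
        raise ValueError(f"mobility ratio must be in (0, 1], got {ratio:.4g}")
    return math.degrees(2.0 * math.acos(ratio))


def summarize_angles(measurements: list[BendMeasurement],
                     confidence: float = 0.95) -> BendSummary:
    """Per-replicate angles, their mean, SD and a t-based confidence interval.

    With fewer than two replicates only the mean is reported (no interval).
    """
    if not measurements:
        raise ValueError("need at least one measurement")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    angles = np.array([bend_angle(m.mu_M, m.mu_E) for m in measurements])
    n = angles.size
    mean = float(angles.mean())
    if n < 2:
        return BendSummary(mean, 0.0, None, None, confidence, n,
                           tuple(angles.tolist()))
    sd = float(angles.std(ddof=1))
    half = stats.t.ppf(0.5 + confidence / 2, df=n - 1) * sd / math.sqrt(n)
    return BendSummary(mean, sd, mean - half, mean + half, confidence, n,
                       tuple(angles.tolist()))
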