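"""Point estimators of volume from a section series.

Three estimators are provided.  With section areas A_k = Area(S_k) at
positions x_0 < ... < x_N and slice thicknesses h_k = x_k - x_{k-1}:

* Cavalieri:             Q^ = T * sum_k A_k              (fixed spacing T)
* generalized Cavalieri: Q^ = mean(h) * sum_k A_k        (average spacing)
* trapezoidal:           Q^1 = sum_{k=1}^{N-1} (h_k + h_{k+1})/2 * A_k

The trapezoidal estimator is the trapezoid-rule integral of the observed
(position, area) profile; it uses the actual section locations and is the
recommended estimator when sections are not equidistant.  On equidistant
series it coincides with the Cavalieri estimator.  All three are unbiased
under stationary sampling when the object lies strictly between the end
planes (first and last area zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ContractViolationError, InvalidInputError, InvalidParameterError
from .sampling import SectionSeries

__all__ = [
    "VolumeEstimate",
    "cavalieri_estimate",
    "generalized_cavalieri_estimate",
    "trapezoidal_estimate",
]


@dataclass(frozen=True)
class VolumeEstimate:
    value: float  # mm^3
    method: str  # cavalieri | generalized_cavalieri | trapezoidal
    n_sections: int


def cavalieri_estimate(T: float, areas) -> VolumeEstimate:
    """Classical Cavalieri estimate with a fixed, known spacing T."""
    if not T > 0:
        raise InvalidParameterError("T must be positive")
    a = np.asarray(areas, dtype=float)
    if np.any(a < 0):
        raise InvalidInputError("areas must be nonnegative")
    return VolumeEstimate(float(T * a.sum()), "cavalieri", len(a))


def generalized_cavalieri_estimate(series: SectionSeries) -> VolumeEstimate:
    """Cavalieri estimate with T replaced by the average observed gap.

    This is the traditional fallback when sections are not equidistant;
    it is unbiased but its variance can be much larger than in the
    equidistant case, which is what the trapezoidal estimator fixes.
    """
    if series.n_gaps < 2:
        raise InvalidInputError("need at least 2 gaps")
    mean_gap = float(series.gaps.mean())
    return VolumeEstimate(
        float(mean_gap * series.areas.sum()),
        "generalized_cavalieri",
        len(series.areas),
    )


def trapezoidal_estimate(series: SectionSeries) -> VolumeEstimate:
    """Trapezoid-rule volume estimate from a non-equidistant series.

    Requires an estimation-ready series (first and last area zero).  The
    sum over interior sections of (h_k + h_{k+1})/2 * A_k is algebraically
    identical to the per-slice trapezoid sum
    sum_k h_k (A_{k-1} + A_k)/2 because the end areas vanish.
    """
    if not series.is_estimation_ready:
        raise ContractViolationError(
            "trapezoidal estimator requires zero first and last area "
            "(object strictly contained between the end planes)"
        )
    h = series.gaps
    value = float(np.sum((h[:-1] + h[1:]) / 2.0 * series.areas[1:-1]))
    return VolumeEstimate(value, "trapezoidal", len(series.areas))
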