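"""Variance estimation for the trapezoidal volume estimator.

The variance of the trapezoidal estimator decomposes, for an m-oriented
object (m in {0, 1}) sampled with mean slice thickness T, into an
*extension term* c*T^(2m+2), an oscillating *Zitterbewegung* and a faster
decaying remainder.  Following standard stereological practice, the
estimators here target the extension term.

All estimators combine the empirical covariogram of the section areas,

    g^(k) = sum_j A_j A_{j+k},

with moment estimates of the slice-thickness law:

* *model-free* (works for any stationary gap process, also after
  dropouts): gap moments gamma^_{i,j} estimated directly from the
  observed thicknesses;
* *perturbed model*: gamma moments expressed through the mean, variance
  and fourth centred moment (T^, theta^_2, theta^_4) of the thickness of
  a typical slice;
* *cumulative model*: gamma moments expressed through the raw thickness
  moments nu^_j = mean(h^j), j = 1..5.

The model-specific forms are only valid without dropouts.  With constant
gaps every estimator reduces to the classical Cavalieri variance
estimates T^2/12 * (3g^(0) - 4g^(1) + g^(2)) for m = 0 and
T^2/240 * (3g^(0) - 4g^(1) + g^(2)) for m = 1.

For a 1-oriented object the Zitterbewegung never exceeds the extension
term, so doubling the estimate gives a conservative variance bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .exceptions import (
    ContractViolationError,
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
    NegativeVarianceWarning,
)
from .sampling import SectionSeries

__all__ = [
    "CovariogramEstimate",
    "MomentSet",
    "VarianceEstimate",
    "covariogram",
    "gamma_moment",
    "perturbed_moments",
    "cumulative_moments",
    "compute_moments",
    "varest_model_free",
    "varest_perturbed",
    "varest_cumulative",
    "varest_equidistant",
    "varest_after_dropout",
    "conservative_bound",
]

# gamma indices needed by the m=1 formula
_GAMMA_KEYS = ((1, 2), (2, 2), (1, 3), (2, 3), (1, 5))


@dataclass(frozen=True)
class CovariogramEstimate:
    values: np.ndarray  # g^(0..max_lag), mm^4
    max_lag: int


@dataclass(frozen=True)
class MomentSet:
    """All slice-thickness moment estimates used by the variance formulas."""

    gamma: Dict[Tuple[int, int], float]
    T_hat: float
    theta2: float
    theta4: float
    nu: Tuple[float, float, float, float, float]  # nu^_1..nu^_5


@dataclass(frozen=True)
class VarianceEstimate:
    value: float  # mm^6
    method: str  # model_free | perturbed | cumulative | equidistant
    smoothness_m: int
    conservative: bool = False


@dataclass(frozen=True)
class PerturbedMoments:
    T_hat: float
    theta2: float
    theta4: float
    # bias-corrected estimates of theta_2 and T^2 (refined variant)
    theta2_refined: Optional[float] = None
    T2_refined: Optional[float] = None


def covariogram(areas, max_lag: int) -> CovariogramEstimate:
    """Empirical covariogram g^(k) = sum_{j=0}^{N-k} A_j A_{k+j}."""
    a = np.asarray(areas, dtype=float)
    n = len(a) - 1
    if not 0 <= max_lag <= n:
        raise InvalidParameterError(f"max_lag must be in [0, {n}], got {max_lag}")
    full = np.correlate(a, a, mode="full")
    return CovariogramEstimate(full[len(a) - 1 : len(a) + max_lag], max_lag)


def gamma_moment(gaps, i: int, j: int) -> float:
    """Estimate gamma_{i,j} from observed slice thicknesses.

    T*gamma_{i,j} is the expected j-th power of the distance from a
    section to its i-th neighbour; the model-free estimate is

        gamma^_{i,j} = N/(N-i+1) * sum_k (h_{k+1}+...+h_{k+i})^j / sum(h).
    """
    h = np.asarray(gaps, dtype=float)
    n = len(h)
    if not 1 <= i <= n:
        raise InvalidParameterError(f"lag i must be in [1, {n}], got {i}")
    if j < 1:
        raise InvalidParameterError("power j must be >= 1")
    windows = np.convolve(h, np.ones(i), mode="valid")  # sums of i consecutive gaps
    return float(n / (n - i + 1) * np.sum(windows**j) / h.sum())


def perturbed_moments(gaps, refined: bool = False) -> PerturbedMoments:
    """Mean, variance and fourth centred moment of the slice thickness.

    With ``refined=True`` the slightly bias-corrected estimates
    theta^_2 * N^2/(N^2-1) for theta_2 and T^^2 - theta^_2/(N^2-1) for T^2
    are filled in as well.
    """
    h = np.asarray(gaps, dtype=float)
    n = len(h)
    if n < 2:
        raise InvalidInputError("need at least 2 gaps")
    T_hat = float(h.mean())
    d = h - T_hat
    theta2 = float(np.mean(d**2))
    theta4 = float(np.mean(d**4))
    if not refined:
        return PerturbedMoments(T_hat, theta2, theta4)
    corr = n * n / (n * n - 1.0)
    return PerturbedMoments(
        T_hat,
        theta2,
        theta4,
        theta2_refined=theta2 * corr,
        T2_refined=T_hat**2 - theta2 / (n * n - 1.0),
    )


def cumulative_moments(gaps) -> Tuple[float, float, float, float, float]:
    """Raw thickness moments nu^_j = mean(h^j) for j = 1..5."""
    h = np.asarray(gaps, dtype=float)
    if len(h) < 1:
        raise InvalidInputError("need at least one gap")
    return tuple(float(np.mean(h**j)) for j in range(1, 6))


def compute_moments(series: SectionSeries) -> MomentSet:
    """All moment estimates for a series, for reporting/diagnostics."""
    h = series.gaps
    gamma = {
        (i, j): gamma_moment(h, i, j) for (i, j) in _GAMMA_KEYS if i <= len(h)
    }
    pm = perturbed_moments(h)
    return MomentSet(gamma, pm.T_hat, pm.theta2, pm.theta4, cumulative_moments(h))


# ---------------------------------------------------------------------------
# variance kernels


def _smoothed(g: np.ndarray) -> float:
    """The second-difference covariogram combination 3g^(0)-4g^(1)+g^(2)."""
    return float(3.0 * g[0] - 4.0 * g[1] + g[2])


def _clamp(value: float, method: str) -> float:
    if value < 0:
        warnings.warn(
            f"{method} variance estimate was negative ({value:.3g}); "
            "clamped to 0 (pathological or very short series)",
            NegativeVarianceWarning,
            stacklevel=3,
        )
        return 0.0
    return value


def _var_m0(g: np.ndarray, gamma13: float) -> float:
    return _smoothed(g) * gamma13 / 12.0


def _var_m1(g: np.ndarray, gam: Dict[Tuple[int, int], float]) -> float:
    num = (
        g[0] * (gam[2, 2] - gam[1, 2])
        - g[1] * gam[2, 2]
        + g[2] * gam[1, 2]
    )
    den = gam[1, 2] * gam[2, 3] - gam[2, 2] * gam[1, 3]
    scale = abs(gam[1, 2] * gam[2, 3]) + abs(gam[2, 2] * gam[1, 3])
    if den == 0 or (scale > 0 and abs(den) < 1e-14 * scale):
        raise DegenerateInputError(
            "degenerate gap moments: gamma_{1,2}gamma_{2,3} = "
            "gamma_{2,2}gamma_{1,3}"
        )
    return num / den * (12.0 * gam[1, 5] - 10.0 * gam[1, 3] ** 2) / 120.0


def _check_series(series: SectionSeries, m: int, min_gaps: int = 2) -> None:
    if m not in (0, 1):
        raise InvalidParameterError("smoothness m must be 0 or 1")
    if not series.is_estimation_ready:
        raise ContractViolationError(
            "variance estimation requires an estimation-ready series"
        )
    if series.n_gaps < min_gaps:
        raise InvalidInputError(
            f"need at least {min_gaps} gaps, got {series.n_gaps}"
        )


# ---------------------------------------------------------------------------
# public estimators


def varest_model_free(series: SectionSeries, m: int) -> VarianceEstimate:
    """Variance estimate without any model for the section positions.

    Valid for any stationary gap process, including series after dropout
    thinning.  Uses the model-free gamma moments.
    """
    _check_series(series, m)
    g = covariogram(series.areas, 2).values
    h = series.gaps
    if m == 0:
        value = _var_m0(g, gamma_moment(h, 1, 3))
    else:
        gam = {(i, j): gamma_moment(h, i, j) for (i, j) in _GAMMA_KEYS}
        value = _var_m1(g, gam)
    return VarianceEstimate(_clamp(value, "model_free"), "model_free", m)


def _perturbed_gammas(T2: float, th2: float, th4: float, T_hat: float):
    """Gamma moments implied by the perturbed model.

    With D, D' iid perturbations and W = D' - D one has E W^2 = theta_2,
    E W^4 = theta_4 and odd moments zero, whence
    T*gamma_{i,j} = E (iT + W)^j expands into the closed forms below.
    """
    return {
        (1, 2): (T2 + th2) / T_hat,
        (2, 2): (4.0 * T2 + th2) / T_hat,
        (1, 3): T2 + 3.0 * th2,
        (2, 3): 8.0 * T2 + 6.0 * th2,
        (1, 5): T2 * T2 + 10.0 * T2 * th2 + 5.0 * th4,
    }


def varest_perturbed(
    series: SectionSeries, m: int, refined: bool = False
) -> VarianceEstimate:
    """Variance estimate exploiting the perturbed sampling model.

    Only valid for series sampled *without* dropouts; a thinned series is
    refused.  For m = 0 the estimate is
    (3g^(0)-4g^(1)+g^(2)) * (T^^2 + 3 theta^_2)/12, and ``refined=True``
    substitutes the bias-corrected theta_2 and T^2 estimates (the
    correction is only stated for the m = 0 form and is ignored for
    m = 1, where its analogue is not available).
    """
    _check_series(series, m)
    if series.dropout_applied:
        raise ContractViolationError(
            "perturbed-model variance estimation is invalid after dropouts; "
            "use varest_after_dropout / varest_model_free"
        )
    g = covariogram(series.areas, 2).values
    pm = perturbed_moments(series.gaps, refined=refined)
    if m == 0:
        if refined:
            T2, th2 = pm.T2_refined, pm.theta2_refined
        else:
            T2, th2 = pm.T_hat**2, pm.theta2
        value = _var_m0(g, T2 + 3.0 * th2)
    else:
        gam = _perturbed_gammas(pm.T_hat**2, pm.theta2, pm.theta4, pm.T_hat)
        value = _var_m1(g, gam)
    return VarianceEstimate(_clamp(value, "perturbed"), "perturbed", m)


def _cumulative_gammas(T_hat: float, nu):
    """Gamma moments implied by iid gaps: T*gamma_{i,j} = E (h_1+..+h_i)^j."""
    nu1, nu2, nu3, _, nu5 = nu
    return {
        (1, 2): nu2 / T_hat,
        (2, 2): 2.0 * (nu2 + T_hat * T_hat) / T_hat,
        (1, 3): nu3 / T_hat,
        (2, 3): (2.0 * nu3 + 6.0 * T_hat * nu2) / T_hat,
        (1, 5): nu5 / T_hat,
    }


def varest_cumulative(series: SectionSeries, m: int) -> VarianceEstimate:
    """Variance estimate exploiting the cumulative (iid-gap) model.

    Only valid for series sampled without dropouts.  For m = 0 the
    estimate is (3g^(0)-4g^(1)+g^(2)) * nu^_3/(12 T^).
    """
    _check_series(series, m)
    if series.dropout_applied:
        raise ContractViolationError(
            "cumulative-model variance estimation is invalid after dropouts; "
            "use varest_after_dropout / varest_model_free"
        )
    g = covariogram(series.areas, 2).values
    h = series.gaps
    T_hat = float(h.mean())
    nu = cumulative_moments(h)
    if m == 0:
        value = _var_m0(g, nu[2] / T_hat)
    else:
        value = _var_m1(g, _cumulative_gammas(T_hat, nu))
    return VarianceEstimate(_clamp(value, "cumulative"), "cumulative", m)


def varest_equidistant(areas, T: float, m: int) -> VarianceEstimate:
    """Classical Cavalieri variance estimate for equidistant sections:
    T^2/12 (m=0) or T^2/240 (m=1) times 3g^(0)-4g^(1)+g^(2)."""
    if not T > 0:
        raise InvalidParameterError("T must be positive")
    if m not in (0, 1):
        raise InvalidParameterError("smoothness m must be 0 or 1")
    a = np.asarray(areas, dtype=float)
    if len(a) < 3:
        raise InvalidInputError("need at least 3 sections")
    g = covariogram(a, 2).values
    denom = 12.0 if m == 0 else 240.0
    value = T * T / denom * _smoothed(g)
    return VarianceEstimate(_clamp(value, "equidistant"), "equidistant", m)


def varest_after_dropout(series: SectionSeries, m: int) -> VarianceEstimate:
    """Variance estimation after dropouts.

    The model-free estimator remains valid on the thinned series (the
    positions of lost sections are simply disregarded and their gaps
    merge), so this delegates to :func:`varest_model_free`.
    """
    return varest_model_free(series, m)


def conservative_bound(est: VarianceEstimate) -> VarianceEstimate:
    """Double a 1-oriented variance estimate to cover the Zitterbewegung.

    For 1-oriented objects the oscillating variance component is bounded
    by the extension term, so twice the estimated extension term is a
    conservative variance estimate.  No such bound is available for
    0-oriented objects.
    """
    if est.smoothness_m != 1:
        raise InvalidParameterError(
            "the conservative x2 bound is only available for m = 1"
        )
    return replace(est, value=2.0 * est.value, conservative=True)
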