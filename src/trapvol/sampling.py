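"""Random section-position models and section series.

Three stationary sampling models for the positions of parallel section
planes along the sampling axis are supported:

* ``equidistant`` — a grid ``{U + jT}`` with a uniform start ``U`` on
  ``[0, T)``; all slices have thickness exactly T.
* ``perturbed`` — each grid position is displaced independently by a
  zero-mean truncated normal perturbation.  This models cutting devices
  with equidistant *intended* positions and independent knife drift.
  Truncation at +-T/2 guarantees the planes stay ordered.
* ``cumulative`` — consecutive slice thicknesses are iid (a renewal
  sequence), modelling free-hand cutting where placement errors
  accumulate.  Gaps are normal with mean T truncated to (T/2, 3T/2).

Dispersion is parametrized by the *average relative deviation* of the
slice thickness h from the intended thickness T, ``E|h - T| / T``
(default 0.05), and the underlying scale parameter is calibrated
numerically to match it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import truncnorm

from .area import AreaFunction
from .exceptions import (
    CalibrationError,
    CoverageError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "SamplingSpec",
    "SectionSeries",
    "calibrate_dispersion",
    "sample_positions",
    "sections_from_area_function",
    "apply_dropout",
]

_MODELS = ("equidistant", "perturbed", "cumulative")


@dataclass(frozen=True)
class SamplingSpec:
    """Parameters of a section-position sampling model.

    Attributes
    ----------
    model : {"equidistant", "perturbed", "cumulative"}
    mean_gap : float
        Intended / mean slice thickness T (mm).
    rel_dev : float
        Average relative deviation E|h - T|/T of the slice thickness
        (dimensionless, default 0.05).  Ignored by the equidistant model.
    dropout_prob : float
        Probability in [0, 1) that an interior section is lost.
    seed : int, optional
        Root seed for reproducibility.
    """

    model: str
    mean_gap: float
    rel_dev: float = 0.05
    dropout_prob: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.model not in _MODELS:
            raise InvalidParameterError(
                f"unknown model {self.model!r}; expected one of {_MODELS}"
            )
        if not self.mean_gap > 0:
            raise InvalidParameterError("mean_gap must be positive")
        if not 0 <= self.rel_dev < 0.5:
            raise InvalidParameterError("rel_dev must be in [0, 0.5)")
        if not 0 <= self.dropout_prob < 1:
            raise InvalidParameterError("dropout_prob must be in [0, 1)")


@dataclass(frozen=True)
class SectionSeries:
    """Ordered section positions with their measured cross-section areas.

    ``positions`` are the axial locations x_0 < ... < x_N (mm), ``areas``
    the areas Area(S_0)..Area(S_N) (mm^2).  The slice thicknesses are the
    increments h_k = x_k - x_{k-1}.

    A series is *estimation-ready* when the first and last area are zero,
    i.e. the object lies strictly between the end planes; the volume and
    variance estimators require this.
    """

    positions: np.ndarray
    areas: np.ndarray
    dropout_applied: bool = False

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        ar = np.asarray(self.areas, dtype=float)
        if pos.ndim != 1 or pos.shape != ar.shape:
            raise InvalidInputError("positions and areas must be 1-D, equal length")
        if len(pos) < 2:
            raise InvalidInputError("a series needs at least two sections")
        if not np.all(np.diff(pos) > 0):
            raise InvalidInputError("positions must be strictly increasing")
        if np.any(ar < 0):
            raise InvalidInputError("areas must be nonnegative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "areas", ar)

    @property
    def gaps(self) -> np.ndarray:
        """Slice thicknesses h_1..h_N (mm)."""
        return np.diff(self.positions)

    @property
    def n_gaps(self) -> int:
        """N, the number of slices (sections minus one)."""
        return len(self.positions) - 1

    @property
    def is_estimation_ready(self) -> bool:
        return (
            len(self.positions) >= 3
            and self.areas[0] == 0.0
            and self.areas[-1] == 0.0
        )


# ---------------------------------------------------------------------------
# dispersion calibration

# Largest average relative deviation reachable under the truncation bounds
# (attained in the limit of a flat/uniform law on the truncation interval):
# perturbed: E|U - U'| = 1/3 for U, U' iid uniform(-T/2, T/2), divided by T;
# cumulative: E|U| = T/4 for U uniform(-T/2, T/2).
_MAX_REL_DEV = {"perturbed": 1.0 / 3.0, "cumulative": 0.25}


def _rel_dev_perturbed(sigma: float) -> float:
    """E|D - D'|/T at T=1 for iid N(0, sigma^2) truncated to (-1/2, 1/2).

    Uses E|X - Y| = 2 * integral of F(1-F) for iid X, Y with cdf F.
    """
    if sigma == 0:
        return 0.0
    a, b = -0.5 / sigma, 0.5 / sigma
    F = truncnorm(a, b, loc=0.0, scale=sigma).cdf
    val, _ = quad(lambda x: F(x) * (1.0 - F(x)), -0.5, 0.5, limit=200)
    return 2.0 * val


def _rel_dev_cumulative(scale: float) -> float:
    """E|Z|/T at T=1 for Z ~ N(0, scale^2) truncated to (-1/2, 1/2)."""
    if scale == 0:
        return 0.0
    z = 0.5 / scale
    # closed form for the mean absolute value of a symmetric truncated normal
    num = scale * math.sqrt(2.0 / math.pi) * (1.0 - math.exp(-(z * z) / 2.0))
    den = 2.0 * ndtr(z) - 1.0
    return num / den


@lru_cache(maxsize=None)
def _calibrate_unit(model: str, rel_dev: float) -> float:
    """Scale parameter at T=1 achieving the requested relative deviation."""
    if rel_dev == 0:
        return 0.0
    fun = _rel_dev_perturbed if model == "perturbed" else _rel_dev_cumulative
    limit = _MAX_REL_DEV[model]
    hi = 50.0
    if rel_dev >= fun(hi) or rel_dev >= limit:
        raise CalibrationError(
            f"rel_dev={rel_dev} is not attainable under the {model} model's "
            f"truncation bounds (supremum {limit:.4g})"
        )
    return brentq(lambda s: fun(s) - rel_dev, 1e-12, hi, xtol=1e-12, rtol=1e-12)


def calibrate_dispersion(model: str, mean_gap: float, rel_dev: float) -> float:
    """Scale parameter of the gap/perturbation law matching ``rel_dev``.

    For the perturbed model, returns the standard deviation sigma of the
    zero-mean normal perturbation truncated to (-T/2, T/2) such that the
    average relative thickness deviation E|D - D'|/T equals ``rel_dev``.
    For the cumulative model, returns the scale of the normal gap law
    (mean T, truncated to (T/2, 3T/2)) such that E|h - T|/T = rel_dev.
    Scales linearly with T.
    """
    if model not in ("perturbed", "cumulative"):
        raise InvalidParameterError(
            "calibration applies to the perturbed and cumulative models"
        )
    if not mean_gap > 0:
        raise InvalidParameterError("mean_gap must be positive")
    if not 0 <= rel_dev < 0.5:
        raise InvalidParameterError("rel_dev must be in [0, 0.5)")
    return mean_gap * _calibrate_unit(model, float(rel_dev))


def _truncated_normal(rng, sigma: float, bound: float, size) -> np.ndarray:
    """Draw N(0, sigma^2) truncated to (-bound, bound) by inverse cdf."""
    if sigma == 0:
        return np.zeros(size)
    lo = ndtr(-bound / sigma)
    hi = ndtr(bound / sigma)
    u = rng.random(size)
    d = sigma * ndtri(lo + u * (hi - lo))
    # guard against rounding at the truncation bounds
    return np.clip(d, -bound * (1 - 1e-12), bound * (1 - 1e-12))


# ---------------------------------------------------------------------------
# position sampling


def _positions_batch(spec: SamplingSpec, window, reps: int, rng) -> np.ndarray:
    """Matrix of section positions, one replicate per row.

    Positions cover ``window`` with at least one plane beyond each end
    (margin at least one mean gap), so no part of the window is missed.
    Rows are strictly increasing.
    """
    lo, hi = float(window[0]), float(window[1])
    T = spec.mean_gap
    if not hi - lo > 2 * T:
        raise InvalidParameterError("window length must exceed 2 * mean_gap")

    if spec.model in ("equidistant", "perturbed"):
        n_cols = int(math.ceil((hi - lo + 4 * T) / T)) + 1
        base = lo - 2 * T + np.arange(n_cols) * T
        u = rng.random((reps, 1)) * T
        pos = base[None, :] + u
        if spec.model == "perturbed":
            sigma = calibrate_dispersion("perturbed", T, spec.rel_dev)
            pos = pos + _truncated_normal(rng, sigma, T / 2.0, (reps, n_cols))
        return pos

    # cumulative: renewal sequence started one window-margin below
    scale = calibrate_dispersion("cumulative", T, spec.rel_dev)
    start = lo - 2 * T + rng.random((reps, 1)) * T
    span = hi + 2 * T - (lo - 2 * T)
    n_gaps = int(math.ceil(span / (T / 2.0))) + 1  # gaps are > T/2, so this covers
    gaps = T + _truncated_normal(rng, scale, T / 2.0, (reps, n_gaps))
    pos = np.concatenate([start, start + np.cumsum(gaps, axis=1)], axis=1)
    return pos


def sample_positions(spec: SamplingSpec, window, rng=None) -> np.ndarray:
    """Draw one realization of section positions covering ``window``.

    ``window`` is an interval (lo, hi) in mm; the returned positions are
    strictly increasing and extend at least one mean gap beyond each end
    of the window.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return _positions_batch(spec, window, 1, rng)[0]


# ---------------------------------------------------------------------------
# series construction


def sections_from_area_function(
    fn: AreaFunction, positions
) -> SectionSeries:
    """Evaluate the area function at the section positions and trim.

    Keeps exactly one zero-area plane before the first hitting plane and
    one after the last, so the result is estimation-ready.  If no plane
    hits the object (possible at very coarse spacing), a minimal 3-plane
    zero series around the support centre is returned: the volume estimate
    is legitimately zero for such a replicate.
    """
    pos = np.asarray(positions, dtype=float)
    if pos[0] > fn.support_lo or pos[-1] < fn.support_hi:
        raise CoverageError(
            "section positions do not cover the object's support; "
            "the volume estimate would be biased"
        )
    areas = fn.evaluate(pos)
    hit = np.flatnonzero(areas > 0)
    if hit.size == 0:
        centre = 0.5 * (fn.support_lo + fn.support_hi)
        i = int(np.clip(np.argmin(np.abs(pos - centre)), 1, len(pos) - 2))
        return SectionSeries(pos[i - 1 : i + 2], np.zeros(3))
    first, last = hit[0], hit[-1]
    if first == 0 or last == len(pos) - 1:
        raise CoverageError(
            "no non-hitting plane on one side of the object; extend the "
            "sampling window"
        )
    sl = slice(first - 1, last + 2)
    out_areas = areas[sl].copy()
    out_areas[0] = 0.0
    out_areas[-1] = 0.0
    return SectionSeries(pos[sl], out_areas)


def apply_dropout(
    series: SectionSeries, dropout_prob: float, seed=None, rng=None
) -> SectionSeries:
    """Independently thin interior sections with probability ``dropout_prob``.

    Models lost or unmeasurable sections on an already-trimmed series.  The
    end planes (zero areas) are always retained; gaps of removed sections
    merge additively, so the positions of the surviving sections are
    unchanged.

    Note: because the bracketing planes are pinned, thinning a trimmed
    series slightly shortens the weights of the outermost hitting sections;
    simulation studies therefore thin the full sampled plane set *before*
    trimming, which keeps the trapezoidal estimator exactly unbiased.
    """
    if not 0 <= dropout_prob < 1:
        raise InvalidParameterError("dropout_prob must be in [0, 1)")
    if not series.is_estimation_ready:
        raise InvalidInputError("apply_dropout requires an estimation-ready series")
    if dropout_prob == 0:
        return series
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(series.positions)
    keep = np.ones(n, dtype=bool)
    keep[1:-1] = rng.random(n - 2) >= dropout_prob
    return SectionSeries(
        series.positions[keep], series.areas[keep], dropout_applied=True
    )
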