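"""Area functions of three-dimensional objects along a sampling axis.

The cross-sectional area of a bounded object, as a function of position
along the sampling axis, is the *area function* f.  Its integral is the
object's volume, so volume estimation from planar sections is numerical
integration of f from finitely many (randomly placed) evaluations.

The smoothness of f controls how fast estimator variances shrink with the
section spacing.  We track it through ``smoothness_m``:

* ``m = 0`` — f has a jump (e.g. a flat face of the object is parallel to
  the section planes);
* ``m = 1`` — f is continuous but its derivative jumps (typical for convex
  objects with smooth boundary, e.g. a ball sampled along any axis).

This module provides the ball benchmark, cubic-spline area functions built
from measured section tables, truncation (to manufacture a 0-oriented
example from a 1-oriented one), and a synthesizer that emulates section
tables like those obtained from agar-embedded primate parietal lobes cut
into ~2.5 mm slabs with areas estimated by point counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "AreaFunction",
    "ball_area_function",
    "spline_area_function",
    "truncate_area_function",
    "synthesize_lobe_profile",
    "typical_lobe_area_function",
    "point_counts_to_areas",
]


@dataclass(frozen=True)
class AreaFunction:
    """A nonnegative, compactly supported area profile f(x).

    Parameters
    ----------
    support_lo, support_hi : float
        Endpoints (mm) of the support; f vanishes outside ``[lo, hi]``.
    smoothness_m : int
        0 or 1, see module docstring.
    true_volume : float
        Integral of f over its support (mm^3).
    """

    support_lo: float
    support_hi: float
    smoothness_m: int
    true_volume: float
    # profile(x) is only consulted inside the support and is clipped at 0
    _profile: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    # exact integral of the (clipped) profile over [a, b] within the support
    _integrate: Callable[[float, float], float] = field(repr=False)

    def __post_init__(self):
        if not self.support_lo < self.support_hi:
            raise InvalidParameterError("support_lo must be < support_hi")
        if self.smoothness_m not in (0, 1):
            raise InvalidParameterError("smoothness_m must be 0 or 1")

    @property
    def support_length(self) -> float:
        return self.support_hi - self.support_lo

    def evaluate(self, x):
        """Evaluate f at scalar or array x (mm); returns area(s) in mm^2."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.zeros_like(x)
        inside = (x >= self.support_lo) & (x <= self.support_hi)
        if inside.any():
            out[inside] = np.clip(self._profile(x[inside]), 0.0, None)
        return float(out[0]) if scalar else out

    __call__ = evaluate

    def integral(self, a: float, b: float) -> float:
        """Integral of f over [a, b] (clipped to the support)."""
        a = max(a, self.support_lo)
        b = min(b, self.support_hi)
        if b <= a:
            return 0.0
        return float(self._integrate(a, b))


def ball_area_function(radius: float) -> AreaFunction:
    """Area function of a ball: f(x) = pi (r^2 - x^2) on [-r, r].

    The ball is the canonical 1-oriented benchmark: f is continuous and
    its derivative jumps at the two support endpoints.
    """
    if not radius > 0:
        raise InvalidParameterError(f"radius must be positive, got {radius}")
    r = float(radius)

    def profile(x):
        return math.pi * (r * r - x * x)

    def integrate(a, b):
        anti = lambda t: math.pi * (r * r * t - t**3 / 3.0)
        return anti(b) - anti(a)

    return AreaFunction(
        support_lo=-r,
        support_hi=r,
        smoothness_m=1,
        true_volume=4.0 / 3.0 * math.pi * r**3,
        _profile=profile,
        _integrate=integrate,
    )


def _positive_part_integral(cs: CubicSpline, lo: float, hi: float):
    """Integral of max(cs, 0) over [lo, hi], exact up to root finding.

    Splits [lo, hi] at the real roots of the spline and integrates the
    pieces where the spline is positive.
    """
    roots = cs.roots(extrapolate=False)
    pts = np.concatenate(([lo], roots[(roots > lo) & (roots < hi)], [hi]))
    pts = np.unique(pts)
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        if cs((a + b) / 2.0) > 0.0:
            total += cs.integrate(a, b)
    return float(total)


def spline_area_function(
    positions: Sequence[float], areas: Sequence[float]
) -> AreaFunction:
    """Natural cubic spline through measured (position, area) pairs.

    The spline is clipped below at zero (areas are nonnegative, but an
    interpolating cubic can undershoot) and set to zero outside the first
    and last knot.  The first and last area must be zero so that the
    object is strictly contained between the end sections.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise InvalidInputError("positions and areas must be 1-D and equal length")
    if len(x) < 4:
        raise InvalidInputError("need at least 4 knots for a cubic spline")
    if not np.all(np.diff(x) > 0):
        raise InvalidInputError("positions must be strictly increasing")
    if np.any(y < 0):
        raise InvalidInputError("areas must be nonnegative")
    if y[0] != 0 or y[-1] != 0:
        raise InvalidInputError("first and last area must be zero")

    cs = CubicSpline(x, y, bc_type="natural", extrapolate=False)
    lo, hi = float(x[0]), float(x[-1])
    volume = _positive_part_integral(cs, lo, hi)

    def integrate(a, b):
        return _positive_part_integral(cs, a, b)

    return AreaFunction(
        support_lo=lo,
        support_hi=hi,
        smoothness_m=1,
        true_volume=volume,
        _profile=cs,
        _integrate=integrate,
    )


def truncate_area_function(fn: AreaFunction, cut: float) -> AreaFunction:
    """Restrict ``fn`` to [support_lo, cut], creating a jump at ``cut``.

    This manufactures a 0-oriented area function from a smoother one: the
    restricted profile drops from f(cut) > 0 to 0 at the cut.
    """
    if not (fn.support_lo < cut < fn.support_hi):
        raise InvalidParameterError(
            f"cut {cut} must lie strictly inside the support "
            f"({fn.support_lo}, {fn.support_hi})"
        )
    if not fn.evaluate(cut) > 0:
        raise InvalidParameterError(
            "f vanishes at the cut; truncation would create no discontinuity"
        )
    return AreaFunction(
        support_lo=fn.support_lo,
        support_hi=cut,
        smoothness_m=0,
        true_volume=fn.integral(fn.support_lo, cut),
        _profile=fn._profile,
        _integrate=fn._integrate,
    )


def point_counts_to_areas(counts, area_per_point: float):
    """Convert grid point counts to areas: area_k = count_k * a.

    ``area_per_point`` is the area a (mm^2) associated with one grid point
    of the counting grid.
    """
    if not area_per_point > 0:
        raise InvalidParameterError("area_per_point must be positive")
    c = np.asarray(counts)
    if np.any(c < 0):
        raise InvalidInputError("counts must be nonnegative")
    if not np.issubdtype(c.dtype, np.integer) and not np.allclose(c, np.round(c)):
        raise InvalidInputError("counts must be integers")
    return c.astype(float) * float(area_per_point)


# Asymmetry of the polynomial bump used by the lobe synthesizer.  The shape
# t(1-t)(1 + c t) is smooth and unimodal with *nonzero* slopes at both
# support endpoints, which makes the profile genuinely 1-oriented (the
# derivative of the area function jumps where the object begins and ends).
_LOBE_ASYM = 0.35
# Average total point count per specimen that the synthesizer is calibrated
# to reproduce at the default grid constant and slab thickness.
_TARGET_TOTAL_POINTS = 645.0


def synthesize_lobe_profile(
    seed: int,
    n_slabs: int = 13,
    nominal_gap: float = 2.5,
    area_per_point: float = 2.29,
    rel_dev: float = 0.05,
):
    """Generate a synthetic parietal-lobe-like section table and its spline.

    Emulates the summary characteristics of a stack of 12-15 agar slabs of
    nominal thickness ``nominal_gap`` mm cut from a primate parietal lobe,
    with cross-sectional areas estimated by point counting on a grid with
    ``area_per_point`` mm^2 per point.  The underlying "true" profile is a
    smooth, mildly asymmetric unimodal bump scaled so that the expected
    total point count across all slabs is about 645 at the defaults.  Cut
    positions deviate from the equidistant grid by independent truncated
    normal perturbations with average relative deviation ``rel_dev``.

    Returns
    -------
    table : pandas.DataFrame
        Columns ``position_mm``, ``points``, ``area_mm2``; one row per cut
        (``n_slabs + 1`` rows), first and last area zero.
    fn : AreaFunction
        Cubic-spline area function rebuilt from the noisy table, i.e. what
        a simulation study would use as a lobe-like 1-oriented object.
    """
    # local import: sampling depends on nothing here, but keep cycles out
    from .sampling import calibrate_dispersion, _truncated_normal

    if n_slabs < 3:
        raise InvalidParameterError("need at least 3 slabs")
    if not nominal_gap > 0:
        raise InvalidParameterError("nominal_gap must be positive")
    if not area_per_point > 0:
        raise InvalidParameterError("area_per_point must be positive")

    rng = np.random.default_rng(seed)
    T = float(nominal_gap)
    length = n_slabs * T  # axial extent of the cut range

    # bump support strictly inside (0, length): margins exceed the largest
    # possible cut perturbation (T/2), so the end cuts never hit the object
    a = 0.75 * T
    b = length - 0.75 * T
    target_volume = _TARGET_TOTAL_POINTS * area_per_point * T
    # integral of t(1-t)(1+ct) over [0,1] is 1/6 + c/12
    amp = target_volume / ((b - a) * (1.0 / 6.0 + _LOBE_ASYM / 12.0))

    def true_profile(x):
        t = (x - a) / (b - a)
        t = np.clip(t, 0.0, 1.0)
        return amp * t * (1.0 - t) * (1.0 + _LOBE_ASYM * t)

    # perturbed cut positions around the intended equidistant grid
    grid = np.arange(n_slabs + 1) * T
    sigma = calibrate_dispersion("perturbed", T, rel_dev)
    cuts = grid + _truncated_normal(rng, sigma, T / 2.0, size=n_slabs + 1)

    true_areas = true_profile(cuts)
    true_areas[(cuts <= a) | (cuts >= b)] = 0.0
    counts = rng.poisson(true_areas / area_per_point)
    counts[0] = counts[-1] = 0
    est_areas = point_counts_to_areas(counts, area_per_point)

    table = pd.DataFrame(
        {"position_mm": cuts, "points": counts, "area_mm2": est_areas}
    )
    fn = spline_area_function(cuts, est_areas)
    return table, fn


def typical_lobe_area_function(
    seed: int,
    n_specimens: int = 18,
    n_slabs: int = 13,
    nominal_gap: float = 2.5,
    area_per_point: float = 2.29,
) -> AreaFunction:
    """Average the spline profiles of several synthetic specimens.

    Emulates the construction of a "typical" lobe area function: each
    specimen contributes a cubic-spline profile built from its own noisy
    point-count table (:func:`synthesize_lobe_profile`), and the profiles
    are averaged on a common equidistant grid before re-interpolation.
    Averaging suppresses the knot-scale interpolation wiggles of the
    individual noisy splines, so the result is a smooth, realistic
    1-oriented test object for variance studies.
    """
    if n_specimens < 1:
        raise InvalidParameterError("need at least one specimen")
    rng = np.random.default_rng(seed)
    length = n_slabs * nominal_gap
    grid = np.linspace(0.0, length, 8 * n_slabs + 1)
    acc = np.zeros_like(grid)
    for _ in range(n_specimens):
        _, fn = synthesize_lobe_profile(
            int(rng.integers(2**31)),
            n_slabs=n_slabs,
            nominal_gap=nominal_gap,
            area_per_point=area_per_point,
        )
        # common frame: each specimen's support is mapped onto [0, length]
        x = fn.support_lo + grid / length * fn.support_length
        acc += fn.evaluate(x)
    mean_profile = acc / n_specimens
    mean_profile[0] = mean_profile[-1] = 0.0
    return spline_area_function(grid, mean_profile)
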