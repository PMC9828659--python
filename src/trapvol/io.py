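"""Reading and writing section tables, and the estimation report.

Section tables are plain CSV with a header.  Positions are given either
directly (``position_mm``) or as slice thicknesses (``thickness_mm``,
converted to cumulative positions starting at 0), and areas either
directly (``area_mm2``) or as grid point counts (``points``, converted
with the grid constant ``area_per_point``).  All lengths are mm, areas
mm^2, volumes mm^3; no unit inference is performed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .area import point_counts_to_areas
from .estimators import trapezoidal_estimate
from .exceptions import ContractViolationError, InvalidInputError, InvalidParameterError
from .sampling import SectionSeries
from .variance import (
    compute_moments,
    conservative_bound,
    covariogram,
    varest_cumulative,
    varest_model_free,
    varest_perturbed,
)

__all__ = [
    "read_section_table",
    "write_section_table",
    "EstimationReport",
    "estimate_from_series",
    "estimate_from_table",
]


def read_section_table(path, area_per_point: Optional[float] = None) -> SectionSeries:
    """Read a CSV section table into a :class:`SectionSeries`.

    Requires a ``position_mm`` or ``thickness_mm`` column and an
    ``area_mm2`` or ``points`` column (point counts need
    ``area_per_point``).  Emits a warning if the series is not
    estimation-ready (nonzero first or last area).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)

    n_rows = len(df)
    if "position_mm" in cols:
        pos = df["position_mm"].to_numpy(dtype=float)
    elif "thickness_mm" in cols:
        # N thicknesses describe the gaps between N+1 sections; the column
        # holds one blank cell (conventionally in the first row)
        th = df["thickness_mm"].dropna().to_numpy(dtype=float)
        if len(th) not in (n_rows, n_rows - 1):
            raise InvalidInputError(
                f"{path}: thickness column must hold one value per slice"
            )
        pos = np.concatenate([[0.0], np.cumsum(th)])
        bad = np.flatnonzero(~(th > 0))
        if bad.size:
            raise InvalidInputError(
                f"non-positive thickness at data row {bad[0] + 1} of {path}"
            )
    else:
        raise InvalidInputError(
            f"{path}: need a 'position_mm' or 'thickness_mm' column"
        )

    if "area_mm2" in cols:
        areas = df["area_mm2"].to_numpy(dtype=float)
    elif "points" in cols:
        if area_per_point is None:
            raise InvalidParameterError(
                f"{path}: table has point counts; area_per_point is required"
            )
        areas = point_counts_to_areas(df["points"].to_numpy(), area_per_point)
    else:
        raise InvalidInputError(f"{path}: need an 'area_mm2' or 'points' column")

    bad = np.flatnonzero(np.diff(pos) <= 0)
    if bad.size:
        raise InvalidInputError(
            f"non-increasing position at data row {bad[0] + 2} of {path}"
        )
    bad = np.flatnonzero(areas < 0)
    if bad.size:
        raise InvalidInputError(
            f"negative area at data row {bad[0] + 1} of {path}"
        )

    series = SectionSeries(pos, areas)
    if not series.is_estimation_ready:
        warnings.warn(
            f"{path}: first/last area nonzero - the object is not strictly "
            "contained between the end planes; estimates may be biased",
            stacklevel=2,
        )
    return series


def write_section_table(series: SectionSeries, path, points=None) -> None:
    """Write a series as CSV with columns position_mm[, points], area_mm2."""
    data = {"position_mm": series.positions}
    if points is not None:
        data["points"] = np.asarray(points, dtype=int)
    data["area_mm2"] = series.areas
    pd.DataFrame(data).to_csv(path, index=False)


@dataclass(frozen=True)
class EstimationReport:
    """Volume and variance estimates for one section table."""

    volume: float  # mm^3
    variance: Dict[str, float]  # mm^6, keyed by variance method
    ce: Dict[str, float]  # sqrt(variance)/volume per method
    n_sections: int
    mean_gap: float
    smoothness_m: int
    conservative: bool
    inputs_digest: str
    covariogram: Dict[str, float] = field(default_factory=dict)
    moments: Dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EstimationReport":
        return cls(**json.loads(text))


_VAREST_FUNCS = {
    "model_free": lambda s, m, refined: varest_model_free(s, m),
    "perturbed": varest_perturbed,
    "cumulative": lambda s, m, refined: varest_cumulative(s, m),
}


def estimate_from_series(
    series: SectionSeries,
    model: str = "model_free",
    m: int = 1,
    refined: bool = False,
    conservative: bool = False,
    dropouts: bool = False,
    inputs_digest: str = "",
) -> EstimationReport:
    """Trapezoidal volume estimate plus a variance estimate for a series.

    ``model`` selects the variance estimator.  The model-specific choices
    (``perturbed``, ``cumulative``) are refused when the caller declares
    that dropouts occurred, since they are invalid in that case; the
    model-free estimator remains applicable.  ``conservative`` doubles the
    variance estimate (m = 1 only) to account for the oscillating variance
    component.
    """
    if m not in (0, 1):
        raise InvalidParameterError("smoothness m must be 0 or 1")
    if model not in _VAREST_FUNCS:
        raise InvalidParameterError(f"unknown variance model {model!r}")
    if dropouts and model != "model_free":
        raise ContractViolationError(
            f"the {model} variance estimator is invalid for series with "
            "dropouts; use model='model_free'"
        )
    vol = trapezoidal_estimate(series)
    est = _VAREST_FUNCS[model](series, m, refined)
    if conservative:
        est = conservative_bound(est)
    g = covariogram(series.areas, 2).values
    ms = compute_moments(series)
    variance = {model: est.value}
    ce = {
        model: float(np.sqrt(est.value) / vol.value) if vol.value > 0 else 0.0
    }
    return EstimationReport(
        volume=vol.value,
        variance=variance,
        ce=ce,
        n_sections=len(series.areas),
        mean_gap=float(series.gaps.mean()),
        smoothness_m=m,
        conservative=est.conservative,
        inputs_digest=inputs_digest,
        covariogram={f"g{k}": float(g[k]) for k in range(3)},
        moments={
            "T_hat": ms.T_hat,
            "theta2": ms.theta2,
            "theta4": ms.theta4,
            **{f"nu{j + 1}": v for j, v in enumerate(ms.nu)},
            **{f"gamma_{i}_{j}": v for (i, j), v in ms.gamma.items()},
        },
    )


def estimate_from_table(
    path,
    model: str = "model_free",
    m: int = 1,
    refined: bool = False,
    conservative: bool = False,
    dropouts: bool = False,
    area_per_point: Optional[float] = None,
) -> EstimationReport:
    """Read a section table and produce an estimation report."""
    series = read_section_table(path, area_per_point=area_per_point)
    digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return estimate_from_series(
        series,
        model=model,
        m=m,
        refined=refined,
        conservative=conservative,
        dropouts=dropouts,
        inputs_digest=digest,
    )
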