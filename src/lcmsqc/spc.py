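"""Statistical process control over longitudinal metric series.

Each metric series (one per instrument × QC type × metric × peptide) is
compared against a baseline — mean and sample standard deviation over a
user-defined high-performance period — and every new value is classified
three ways on its standardized deviation z = (value − mean)/sd:

* conformity (green), |z| ≤ 2 — continue acquiring;
* warning (yellow), 2 < |z| ≤ 3 — take preventive action;
* nonconformity (red), |z| > 3 — stop the instrument.

Boundaries are closed on the benign side (|z| = 2 is green, |z| = 3 is
yellow) so the rule is deterministic. A degenerate baseline (sd = 0, e.g.
a constant count) classifies equal values as conformity and any deviation
as nonconformity — the limit of the rule as sd → 0.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Status",
    "Baseline",
    "ChartPoint",
    "BaselineError",
    "MIN_BASELINE_POINTS",
    "compute_baseline",
    "classify",
    "classify_series",
]

#: Fewest in-period points accepted for a baseline (sd is unstable below).
MIN_BASELINE_POINTS = 5

WARNING_SIGMA = 2.0
ACTION_SIGMA = 3.0


class Status(str, enum.Enum):
    CONFORMITY = "conformity"
    WARNING = "warning"
    NONCONFORMITY = "nonconformity"


class BaselineError(ValueError):
    """Raised when a baseline cannot be built from the given period."""


@dataclass(frozen=True)
class Baseline:
    """Per-series reference statistics over the high-performance period."""

    mean: float
    sd: float  # sample standard deviation (n − 1)
    n: int
    period: Optional[tuple[datetime, datetime]] = None
    metric_id: Optional[str] = None
    target: Optional[str] = None
    instrument: Optional[str] = None
    qc_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("baseline needs at least 2 points")


@dataclass(frozen=True)
class ChartPoint:
    """One classified control-chart observation."""

    timestamp: Optional[datetime]
    value: float
    z: float
    status: Status


def compute_baseline(
    series: Sequence[tuple[datetime, float]],
    period: tuple[datetime, datetime],
    min_points: int = MIN_BASELINE_POINTS,
    **series_key,
) -> Baseline:
    """Mean and sample sd of the in-period points of a metric series.

    ``series`` is (timestamp, value) pairs; points outside ``period``
    (inclusive bounds) are ignored. Raises :class:`BaselineError` when
    fewer than ``min_points`` points fall inside the period.
    """
    start, end = period
    values = [v for t, v in series if start <= t <= end]
    if len(values) < min_points:
        raise BaselineError(
            f"baseline period contains {len(values)} points; "
            f"at least {min_points} required"
        )
    arr = np.asarray(values, dtype=float)
    return Baseline(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n=len(values),
        period=period,
        **series_key,
    )


def z_score(value: float, baseline: Baseline) -> float:
    """Signed standardized deviation; ±inf for a deviation from an sd-0 baseline."""
    if baseline.sd == 0.0:
        if value == baseline.mean:
            return 0.0
        return math.copysign(math.inf, value - baseline.mean)
    return (value - baseline.mean) / baseline.sd


def classify(
    value: float,
    baseline: Baseline,
    warning_sigma: float = WARNING_SIGMA,
    action_sigma: float = ACTION_SIGMA,
) -> ChartPoint:
    """Three-tier classification of one value against a baseline."""
    z = z_score(value, baseline)
    a = abs(z)
    if a <= warning_sigma:
        status = Status.CONFORMITY
    elif a <= action_sigma:
        status = Status.WARNING
    else:
        status = Status.NONCONFORMITY
    return ChartPoint(timestamp=None, value=value, z=z, status=status)


def classify_series(
    series: Sequence[tuple[datetime, float]],
    baseline: Baseline,
    warning_sigma: float = WARNING_SIGMA,
    action_sigma: float = ACTION_SIGMA,
) -> list[ChartPoint]:
    """Classify every point of a series, in chronological order."""
    points = []
    for t, v in sorted(series, key=lambda tv: tv[0]):
        p = classify(v, baseline, warning_sigma, action_sigma)
        points.append(ChartPoint(timestamp=t, value=v, z=p.z, status=p.status))
    return points
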