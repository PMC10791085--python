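"""Hour-of-day crowding thresholds and forecast-exceedance detection.

Thresholds are empirical quantiles (default 0.85) of historical census
values pooled by hour of day across all days in the estimation window;
a trigger fires at the earliest forecast step whose value strictly
exceeds the threshold for that step's hour.  In conservative mode the
interval upper bound is compared instead of the point forecast.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Tuple

import numpy as np

from .config import ValidationError
from .feed import CensusSeries
from .forecast import ForecastResult


@dataclass(frozen=True)
class TriggerProfile:
    facility_id: str
    thresholds: Tuple[float, ...]  # 24 values indexed by hour of day
    quantile: float
    window: Tuple[datetime, datetime]

    def __post_init__(self):
        if len(self.thresholds) != 24:
            raise ValidationError(f"thresholds must have 24 values, got {len(self.thresholds)}")
        if any(t < 0 for t in self.thresholds):
            raise ValidationError("thresholds must be nonnegative")


@dataclass(frozen=True)
class TriggerEvent:
    detected_at: datetime
    first_breach_step: int  # 1-based horizon index
    breach_time: datetime
    forecast_value: float
    threshold_value: float

    def __post_init__(self):
        if not self.forecast_value > self.threshold_value:
            raise ValidationError("a trigger requires forecast_value > threshold_value")


def estimate_profile(history: CensusSeries, quantile: float = 0.85,
                     days: str = "all") -> TriggerProfile:
    """Hour-of-day thresholds: empirical quantile of pooled census values.

    Uses the linear-interpolation quantile definition (numpy's default).
    Requires at least 14 days of history so every hour bucket pools a
    stable sample across the week.  ``days`` restricts the pooling to
    ``"weekday"`` (Mon-Fri) or ``"weekend"`` observations; the default
    pools all days.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValidationError(f"quantile must be in (0, 1], got {quantile}")
    if days not in ("all", "weekday", "weekend"):
        raise ValidationError(f"days must be all|weekday|weekend, got {days!r}")
    span_days = len(history) * history.interval_minutes / (24 * 60.0)
    if span_days < 14:
        raise ValidationError(f"history spans {span_days:.1f} days; need >= 14")
    stamps = history.timestamps()
    hours = np.array([ts.hour for ts in stamps])
    values = np.asarray(history.values, dtype=float)
    if days != "all":
        weekend = np.array([ts.weekday() >= 5 for ts in stamps])
        keep = weekend if days == "weekend" else ~weekend
        hours, values = hours[keep], values[keep]
    thresholds = []
    for h in range(24):
        bucket = values[hours == h]
        if len(bucket) == 0:
            raise ValidationError(f"no observations for hour {h}")
        thresholds.append(float(np.quantile(bucket, quantile)))
    end = history.timestamps()[-1]
    return TriggerProfile(facility_id=history.facility_id, thresholds=tuple(thresholds),
                          quantile=quantile, window=(history.start, end))


def detect(
    forecast: ForecastResult,
    profile: TriggerProfile,
    conservative: bool = False,
) -> Optional[TriggerEvent]:
    """Return the earliest strict threshold exceedance, if any.

    Compares the point forecast (or, in ``conservative`` mode, the
    interval upper bound) at each horizon step with the threshold for
    that step's hour of day; equality does not trigger.
    """
    values = forecast.upper if conservative else forecast.point
    for step, (ts, v) in enumerate(zip(forecast.timestamps, values), start=1):
        thr = profile.thresholds[ts.hour]
        if v > thr:
            return TriggerEvent(
                detected_at=forecast.issued_at, first_breach_step=step,
                breach_time=ts, forecast_value=float(v), threshold_value=float(thr),
            )
    return None
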