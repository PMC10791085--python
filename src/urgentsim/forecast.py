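"""Short-horizon forecasting of ED patients-in-department.

Two methods at update-interval resolution (default 30 minutes, 8 steps =
4 hours ahead):

* ``seasonal_naive`` — the forecast for a slot is the last observed
  value at the same slot-of-day; prediction intervals come from the
  pooled spread of historical same-slot ("one season back") residuals.
  Exact on any perfectly periodic series, and the fallback when the
  seasonal ARIMA fit fails.
* ``sarima`` — a seasonal ARIMA fitted with statsmodels, default orders
  (1,0,1)x(0,1,1) with the daily seasonal period (48 slots at 30-minute
  resolution).  The orders are configurable; no automatic order search
  is attempted.

Point forecasts are clipped at zero and interval bounds are forced to
bracket the point forecast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .config import ValidationError
from .feed import CensusSeries

logger = logging.getLogger(__name__)

DEFAULT_ORDER = (1, 0, 1)
DEFAULT_SEASONAL = (0, 1, 1)
DEFAULT_TRAINING_DAYS = 28


@dataclass(frozen=True)
class ForecastResult:
    issued_at: datetime
    timestamps: Tuple[datetime, ...]
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    model_tag: str
    training_window: Tuple[datetime, datetime]

    def __post_init__(self):
        if not (len(self.point) == len(self.lower) == len(self.upper) == len(self.timestamps)):
            raise ValidationError("forecast arrays must share one length")
        if np.any(self.lower > self.point + 1e-9) or np.any(self.point > self.upper + 1e-9):
            raise ValidationError("interval bounds must bracket the point forecast")

    @property
    def horizon_steps(self) -> int:
        return len(self.point)


def fit_forecast(
    series: CensusSeries,
    horizon_steps: int = 8,
    method: str = "seasonal_naive",
    level: float = 0.95,
    order: Tuple[int, int, int] = DEFAULT_ORDER,
    seasonal_order: Tuple[int, int, int] = DEFAULT_SEASONAL,
    training_days: int = DEFAULT_TRAINING_DAYS,
) -> ForecastResult:
    """Forecast the next ``horizon_steps`` slots of a census series.

    Requires at least two seasonal periods of history.  A non-convergent
    or failing seasonal-ARIMA fit falls back to ``seasonal_naive`` with
    a logged warning; ``model_tag`` always records what actually ran.
    """
    period = series.slots_per_day
    if len(series) < 2 * period:
        raise ValidationError(
            f"series too short: need >= {2 * period} observations "
            f"(2 seasonal periods), got {len(series)}")
    if horizon_steps < 1:
        raise ValidationError("horizon_steps must be >= 1")
    if method not in ("seasonal_naive", "sarima"):
        raise ValidationError(f"unknown method {method!r}")

    train = series.tail(training_days * period)
    y = np.asarray(train.values, dtype=float)
    issued_at = series.start + timedelta(minutes=len(series) * series.interval_minutes)
    timestamps = tuple(issued_at + i * timedelta(minutes=series.interval_minutes)
                       for i in range(horizon_steps))
    t0 = train.start
    t1 = issued_at

    if method == "sarima":
        try:
            point, lower, upper = _sarima_forecast(y, horizon_steps, level, order,
                                                   seasonal_order, period)
            return _assemble(issued_at, timestamps, point, lower, upper, level,
                             f"sarima{order}x{seasonal_order}[{period}]", (t0, t1))
        except Exception as exc:  # noqa: BLE001 - any fit failure falls back
            logger.warning("seasonal ARIMA fit failed (%s); falling back to seasonal_naive", exc)
            point, lower, upper = _seasonal_naive(y, horizon_steps, level, period)
            return _assemble(issued_at, timestamps, point, lower, upper, level,
                             "seasonal_naive(fallback:sarima)", (t0, t1))

    point, lower, upper = _seasonal_naive(y, horizon_steps, level, period)
    return _assemble(issued_at, timestamps, point, lower, upper, level,
                     "seasonal_naive", (t0, t1))


def _assemble(issued_at, timestamps, point, lower, upper, level, tag, window) -> ForecastResult:
    point = np.maximum(0.0, np.asarray(point, dtype=float))
    lower = np.minimum(np.maximum(0.0, np.asarray(lower, dtype=float)), point)
    upper = np.maximum(np.asarray(upper, dtype=float), point)
    return ForecastResult(issued_at=issued_at, timestamps=timestamps, point=point,
                          lower=lower, upper=upper, level=level, model_tag=tag,
                          training_window=window)


def _seasonal_naive(y: np.ndarray, h: int, level: float, period: int):
    """Same-slot-yesterday forecast with pooled seasonal-residual intervals."""
    point = np.array([y[len(y) - period + (i % period)] for i in range(h)])
    resid = y[period:] - y[:-period]
    sigma = float(np.std(resid)) if len(resid) else 0.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    return point, point - z * sigma, point + z * sigma


def _sarima_forecast(y, h, level, order, seasonal_order, period):
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(y, order=order, seasonal_order=(*seasonal_order, period),
                        enforce_stationarity=False, enforce_invertibility=False)
        fit = model.fit(disp=False, maxiter=100, method="lbfgs")
        if not getattr(fit.mle_retvals, "get", lambda *_: True)("converged", True):
            raise RuntimeError("optimiser did not converge")
        pred = fit.get_forecast(steps=h)
        ci = pred.conf_int(alpha=1.0 - level)
        ci = np.asarray(ci)
    return np.asarray(pred.predicted_mean), ci[:, 0], ci[:, 1]


# ---------------------------------------------------------------------------
# Backtesting
# ---------------------------------------------------------------------------

@dataclass
class BacktestReport:
    method: str
    horizon_steps: int
    n_origins: int
    mae_per_step: np.ndarray
    mape_per_step: np.ndarray
    coverage_per_step: np.ndarray
    mae: float
    coverage: float


def rolling_backtest(
    series: CensusSeries,
    method: str = "seasonal_naive",
    horizon_steps: int = 8,
    stride: int = 8,
    level: float = 0.95,
    min_train: Optional[int] = None,
    **fit_kwargs,
) -> BacktestReport:
    """Rolling-origin evaluation: per-step MAE/MAPE and interval coverage.

    Origins advance by ``stride`` slots starting after ``min_train``
    observations (default: two seasonal periods).  Deterministic.
    """
    period = series.slots_per_day
    if stride < 1 or stride > len(series):
        raise ValidationError(f"stride must be in [1, {len(series)}], got {stride}")
    if min_train is None:
        min_train = 2 * period
    origins = list(range(min_train, len(series) - horizon_steps + 1, stride))
    if len(origins) < 5:
        raise ValidationError(
            f"series supports only {len(origins)} folds; need >= 5 "
            f"(length {len(series)}, min_train {min_train}, stride {stride})")

    abs_err = np.zeros((len(origins), horizon_steps))
    ape = np.full((len(origins), horizon_steps), np.nan)
    covered = np.zeros((len(origins), horizon_steps))
    for k, o in enumerate(origins):
        sub = CensusSeries(series.facility_id, series.start, series.interval_minutes,
                           series.values[:o])
        fc = fit_forecast(sub, horizon_steps=horizon_steps, method=method,
                          level=level, **fit_kwargs)
        actual = np.asarray(series.values[o:o + horizon_steps], dtype=float)
        abs_err[k] = np.abs(fc.point - actual)
        nz = actual != 0
        ape[k, nz] = abs_err[k, nz] / actual[nz]
        covered[k] = (fc.lower <= actual) & (actual <= fc.upper)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mape = np.nanmean(ape, axis=0)
    return BacktestReport(
        method=method, horizon_steps=horizon_steps, n_origins=len(origins),
        mae_per_step=abs_err.mean(axis=0), mape_per_step=mape,
        coverage_per_step=covered.mean(axis=0),
        mae=float(abs_err.mean()), coverage=float(covered.mean()),
    )
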