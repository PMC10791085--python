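from datetime import timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import urgentsim as u

from conftest import MONDAY


def hourly_series(day_values_by_hour, days=16):
    """Series at 60-minute resolution where hour h on day d takes
    day_values_by_hour[h][d % len]."""
    vals = []
    for d in range(days):
        for h in range(24):
            cycle = day_values_by_hour.get(h, [20])
            vals.append(cycle[d % len(cycle)])
    return u.CensusSeries("ED1", MONDAY, 60, np.array(vals))


def make_forecast(point, issued_at=None, step_minutes=30):
    issued_at = issued_at or MONDAY
    point = np.asarray(point, dtype=float)
    return u.ForecastResult(
        issued_at=issued_at,
        timestamps=tuple(issued_at + (i + 1) * timedelta(minutes=step_minutes)
                         for i in range(len(point))),
        point=point, lower=point, upper=point, level=0.95,
        model_tag="test", training_window=(issued_at, issued_at),
    )


def make_profile(thresholds):
    return u.TriggerProfile(facility_id="ED1", thresholds=tuple(thresholds),
                            quantile=0.85, window=(MONDAY, MONDAY))


def brute_force_detect(forecast, profile):
    """Independent oracle: scan every step, return the earliest breach."""
    best = None
    for step, (ts, v) in enumerate(zip(forecast.timestamps, forecast.point), start=1):
        thr = profile.thresholds[ts.hour]
        if v > thr and best is None:
            best = (step, float(v), float(thr))
    return best


class TestEstimateProfile:
    def test_quantile_one_is_maximum(self):
        s = hourly_series({9: [5, 7, 9, 11]})
        prof = u.estimate_profile(s, quantile=1.0)
        assert prof.thresholds[9] == 11.0

    def test_median_uses_linear_interpolation(self):
        s = hourly_series({9: [5, 7, 9, 11]})
        prof = u.estimate_profile(s, quantile=0.5)
        assert prof.thresholds[9] == 8.0

    def test_constant_series_all_thresholds_equal(self):
        s = hourly_series({})
        for q in (0.25, 0.5, 0.85, 1.0):
            prof = u.estimate_profile(s, quantile=q)
            assert prof.thresholds == tuple([20.0] * 24)

    def test_short_history_rejected(self):
        s = u.synth_census_series(days=7, seed=0)
        with pytest.raises(u.ValidationError, match="14"):
            u.estimate_profile(s)

    def test_weekday_weekend_split(self):
        # weekdays constant 10, weekends constant 30 at every hour
        vals = []
        for d in range(14):
            level = 30 if (d % 7) in (5, 6) else 10  # series starts on a Monday
            vals.extend([level] * 24)
        s = u.CensusSeries("ED1", MONDAY, 60, np.array(vals))
        assert u.estimate_profile(s, 0.85, days="weekday").thresholds == tuple([10.0] * 24)
        assert u.estimate_profile(s, 0.85, days="weekend").thresholds == tuple([30.0] * 24)
        with pytest.raises(u.ValidationError):
            u.estimate_profile(s, 0.85, days="tuesdays")

    def test_permutation_invariance_within_hour_bucket(self):
        a = hourly_series({9: [5, 7, 9, 11]})
        b = hourly_series({9: [11, 5, 7, 9]})
        pa = u.estimate_profile(a, 0.85)
        pb = u.estimate_profile(b, 0.85)
        assert pa.thresholds == pb.thresholds


class TestDetect:
    def test_first_strict_breach_reported(self):
        fc = make_forecast([10, 12, 15, 16, 9, 9, 9, 9])
        ev = u.detect(fc, make_profile([14.0] * 24))
        assert ev is not None
        assert ev.first_breach_step == 3
        assert ev.forecast_value == 15.0
        assert ev.threshold_value == 14.0

    def test_equality_does_not_trigger(self):
        fc = make_forecast([14.0] * 8)
        assert u.detect(fc, make_profile([14.0] * 24)) is None

    def test_all_below_no_event(self):
        fc = make_forecast([10] * 8)
        assert u.detect(fc, make_profile([14.0] * 24)) is None

    def test_conservative_mode_uses_upper_bound(self):
        point = np.array([10.0] * 8)
        fc = u.ForecastResult(
            issued_at=MONDAY,
            timestamps=tuple(MONDAY + (i + 1) * timedelta(minutes=30) for i in range(8)),
            point=point, lower=point, upper=point + 6.0, level=0.95,
            model_tag="t", training_window=(MONDAY, MONDAY))
        prof = make_profile([14.0] * 24)
        assert u.detect(fc, prof) is None
        assert u.detect(fc, prof, conservative=True) is not None

    def test_matches_brute_force_oracle_randomised(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            h = int(rng.integers(1, 12))
            issued = MONDAY + timedelta(minutes=int(rng.integers(0, 48)) * 30)
            fc = make_forecast(rng.uniform(0, 30, size=h), issued_at=issued)
            prof = make_profile(rng.uniform(0, 30, size=24))
            got = u.detect(fc, prof)
            want = brute_force_detect(fc, prof)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert (got.first_breach_step, got.forecast_value, got.threshold_value) == want

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        point=st.lists(st.floats(0, 30, allow_nan=False), min_size=1, max_size=12),
        thr=st.lists(st.floats(0, 30, allow_nan=False), min_size=24, max_size=24),
        shift=st.floats(0.1, 10),
    )
    def test_monotone_in_thresholds(self, point, thr, shift):
        """Raising every threshold can only delay or remove the event;
        lowering can only advance or create it."""
        fc = make_forecast(point)
        base = u.detect(fc, make_profile(thr))
        up = u.detect(fc, make_profile([t + shift for t in thr]))
        down = u.detect(fc, make_profile([max(0.0, t - shift) for t in thr]))
        if base is None:
            assert up is None
        else:
            assert up is None or up.first_breach_step >= base.first_breach_step
            assert down is not None and down.first_breach_step <= base.first_breach_step
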