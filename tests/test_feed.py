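from datetime import timedelta

import numpy as np
import pytest

import urgentsim as u
from urgentsim.feed import _TS_FMT

from conftest import MONDAY, constant_profile


class TestNHPP:
    def test_constant_rate_mean_matches_poisson(self):
        """Empirical rate of a flat 6/hour process over 10,000 hours: the
        count is Poisson(60,000), so the mean must sit within ~3 s.e."""
        prof = constant_profile(6.0)
        days = 10_000 // 24 + 1
        arr = u.sample_nhpp_arrivals(prof, MONDAY, days, seed=7)
        hours = days * 24
        rate = len(arr) / hours
        se = np.sqrt(6.0 / hours)
        assert abs(rate - 6.0) < 3 * se
        assert abs(rate - 6.0) / 6.0 < 0.02

    def test_hourly_rates_converge_to_lambda(self, profile):
        arr = u.sample_nhpp_arrivals(profile, MONDAY, 140, seed=3)
        ts = np.array([a.t_minutes for a in arr])
        hour = (ts // 60 % 24).astype(int)
        mean_dow = np.mean(profile.dow_factors)
        for h in range(24):
            lam = profile.hourly_rates[h] * mean_dow
            n = (hour == h).sum()
            expect = lam * 140
            assert abs(n - expect) < 3 * np.sqrt(expect) + 1e-9, f"hour {h}"

    def test_disjoint_window_counts_uncorrelated(self):
        prof = constant_profile(6.0)
        arr = u.sample_nhpp_arrivals(prof, MONDAY, 200, seed=11)
        ts = np.array([a.t_minutes for a in arr])
        counts = np.histogram(ts, bins=np.arange(0, 200 * 1440 + 1, 120))[0]
        r = np.corrcoef(counts[:-1], counts[1:])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(counts) - 1)

    def test_zero_rates_give_empty_list(self):
        prof = constant_profile(0.0)
        assert u.sample_nhpp_arrivals(prof, MONDAY, 2, seed=1) == []

    def test_seed_reproducibility(self, profile):
        a = u.sample_nhpp_arrivals(profile, MONDAY, 3, seed=5)
        b = u.sample_nhpp_arrivals(profile, MONDAY, 3, seed=5)
        assert a == b
        c = u.sample_nhpp_arrivals(profile, MONDAY, 3, seed=6)
        assert a != c

    def test_sorted_and_typed(self, profile):
        arr = u.sample_nhpp_arrivals(profile, MONDAY, 2, seed=9)
        ts = [a.t_minutes for a in arr]
        assert ts == sorted(ts)
        assert all(a.acuity in (1, 2, 3, 4, 5) for a in arr)
        assert all(a.mode in ("walkin", "ambulance") for a in arr)


class TestSynthCensus:
    def test_noiseless_series_is_weekly_periodic(self):
        s = u.synth_census_series(days=21, noise_scale=0.0, seed=0)
        period = s.slots_per_day * 7
        v = s.values
        assert np.array_equal(v[:period], v[period:2 * period])

    def test_noiseless_bounds_from_generator_formula(self):
        base, amp, dow_amp = 20.0, 10.0, 2.0
        s = u.synth_census_series(days=7, base=base, amplitude=amp,
                                  dow_amplitude=dow_amp, noise_scale=0.0, seed=0)
        from urgentsim.feed import DOW_SHAPE
        bound = dow_amp * np.abs(DOW_SHAPE).max()
        assert s.values.min() >= 0
        assert s.values.max() <= round(base + amp + bound)
        assert s.values.min() >= round(base - amp - bound)

    def test_seed_reproducibility(self):
        a = u.synth_census_series(days=7, seed=4)
        b = u.synth_census_series(days=7, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_negative_noise_scale_rejected(self):
        with pytest.raises(u.ValidationError):
            u.synth_census_series(days=7, noise_scale=-1.0)


@pytest.fixture(scope="module")
def result(network, profile, pathway):
    arr = u.sample_nhpp_arrivals(profile, MONDAY, 1, seed=2)
    return u.run_replication(network, arr, pathway, run_minutes=600, seed=3)


class TestSnapshots:

    def test_count_per_facility(self, result, network):
        snaps = u.snapshots_from_simulation(result, 30)
        per_fac = 600 // 30 + 1
        assert len(snaps) == per_fac * len(network.facilities)

    def test_invariants_hold(self, result):
        for s in u.snapshots_from_simulation(result, 30):
            assert s.waiting <= s.census
            assert (s.max_wait_minutes == 0) == (s.waiting == 0)

    def test_empty_system_snapshot_is_zero(self, network, pathway):
        res = u.run_replication(network, [], pathway, run_minutes=120, seed=1)
        snaps = u.snapshots_from_simulation(res, 30)
        assert all(s.census == 0 and s.waiting == 0 and s.max_wait_minutes == 0
                   for s in snaps)


class TestReplay:
    def _snap(self, minute, census=3, waiting=1):
        return u.RealTimeSnapshot(MONDAY + timedelta(minutes=minute), "ED1",
                                  census, waiting, 10.0 if waiting else 0.0)

    def test_batches_in_order(self):
        snaps = [self._snap(0), self._snap(30), self._snap(60)]
        batches = list(u.replay_stream(snaps))
        assert [b[0].timestamp for b in batches] == [s.timestamp for s in snaps]

    def test_empty_stream(self):
        assert list(u.replay_stream([])) == []

    def test_from_mid_stream_filters(self):
        snaps = [self._snap(0), self._snap(30), self._snap(60)]
        batches = list(u.replay_stream(snaps, from_ts=MONDAY + timedelta(minutes=30)))
        assert len(batches) == 2

    def test_unsorted_rejected(self):
        snaps = [self._snap(30), self._snap(0)]
        with pytest.raises(u.ValidationError):
            list(u.replay_stream(snaps))


class TestCsv:
    def test_census_round_trip(self, tmp_path):
        s = u.synth_census_series(days=3, seed=8)
        p = tmp_path / "census.csv"
        u.write_census_csv(s, p)
        s2 = u.read_census_csv(p)
        assert s2.facility_id == s.facility_id
        assert s2.start == s.start
        assert s2.interval_minutes == s.interval_minutes
        assert np.array_equal(s2.values, s.values)

    def test_single_gap_interpolated_to_midpoint(self, tmp_path):
        p = tmp_path / "census.csv"
        rows = ["timestamp,facility_id,census,waiting,max_wait_minutes"]
        vals = [10, 12, None, 18, 20]
        for i, v in enumerate(vals):
            ts = (MONDAY + timedelta(minutes=30 * i)).strftime(_TS_FMT)
            if v is None:
                continue
            rows.append(f"{ts},ED1,{v},,")
        p.write_text("\n".join(rows) + "\n")
        s = u.read_census_csv(p)
        assert list(s.values) == [10, 12, 15, 18, 20]

    def test_long_gap_rejected(self, tmp_path):
        p = tmp_path / "census.csv"
        rows = ["timestamp,facility_id,census,waiting,max_wait_minutes"]
        for i in [0, 1, 5, 6]:
            ts = (MONDAY + timedelta(minutes=30 * i)).strftime(_TS_FMT)
            rows.append(f"{ts},ED1,10,,")
        p.write_text("\n".join(rows) + "\n")
        with pytest.raises(u.ValidationError, match="gap"):
            u.read_census_csv(p)

    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "census.csv"
        p.write_text("")
        with pytest.raises(u.ValidationError):
            u.read_census_csv(p)

    def test_malformed_header_names_column(self, tmp_path):
        p = tmp_path / "census.csv"
        p.write_text("time,facility_id,census\n2025-01-06T00:00:00,ED1,5\n")
        with pytest.raises(u.ValidationError, match="timestamp"):
            u.read_census_csv(p)

    def test_snapshot_round_trip(self, tmp_path):
        snaps = [
            u.RealTimeSnapshot(MONDAY, "ED1", 5, 2, 40.0),
            u.RealTimeSnapshot(MONDAY, "MTC1", 0, 0, 0.0),
        ]
        p = tmp_path / "snaps.csv"
        u.write_snapshots_csv(snaps, p)
        assert u.read_snapshots_csv(p) == snaps

    def test_snapshot_invariant_enforced(self):
        with pytest.raises(u.ValidationError):
            u.RealTimeSnapshot(MONDAY, "ED1", 2, 3, 10.0)
        with pytest.raises(u.ValidationError):
            u.RealTimeSnapshot(MONDAY, "ED1", 3, 0, 10.0)
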