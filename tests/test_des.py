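import numpy as np
import pandas as pd
import pytest

import urgentsim as u
from urgentsim.des import BASELINE

from conftest import MONDAY, check_conservation, constant_profile, erlang_c_wq, mmc_setup


def open_mtc_network() -> u.NetworkSpec:
    """Default network but with MTCs open around the clock."""
    base = u.default_network()
    facs = [f if f.kind == "ED" else f.model_copy(update={"hours": (0.0, 24.0)})
            for f in base.facilities]
    return u.NetworkSpec(facilities=facs, travel_delay_minutes=base.travel_delay_minutes)


REDIRECT_ALL = u.Scenario(name="redirect_all", redirect_fraction=1.0,
                          targets={"MTC1": 0.4, "MTC2": 0.4, "MTC3": 0.2})


class TestRunReplication:
    def test_zero_arrivals_empty_system(self, network, pathway):
        res = u.run_replication(network, [], pathway, run_minutes=480, seed=0)
        assert res.kpis["n_completed"] == 0
        for frame in res.facility_series.values():
            assert (frame["census"] == 0).all()

    def test_full_redirection_keeps_low_acuity_walkins_off_ed(self, profile, pathway):
        net = open_mtc_network()
        arr = u.sample_nhpp_arrivals(profile, MONDAY, 1, seed=4)
        res = u.run_replication(net, arr, pathway, REDIRECT_ALL, run_minutes=1440, seed=5)
        eligible = {a.patient_id for a in arr
                    if a.acuity in (4, 5) and a.mode == "walkin"}
        ev = res.events
        ed_touch = ev[(ev["facility_id"] == "ED1") & (ev["event"] != "redirected")]
        assert eligible, "fixture should contain eligible patients"
        assert not set(ed_touch["patient_id"]) & eligible
        assert res.kpis["n_redirected"] == len(eligible)

    def test_redirected_count_matches_draws_exactly(self, profile, pathway):
        """With 24h MTCs the redirected count equals the number of eligible
        arrivals whose uniform draw fell below the redirect fraction."""
        net = open_mtc_network()
        sc = u.Scenario(name="half", redirect_fraction=0.5,
                        targets={"MTC1": 1.0})
        arr = u.sample_nhpp_arrivals(profile, MONDAY, 1, seed=14)
        res = u.run_replication(net, arr, pathway, sc, run_minutes=1440, seed=15)
        from urgentsim.des import _make_draws
        rng = np.random.default_rng(np.random.SeedSequence([15, 11]))
        draws = _make_draws(len(arr), pathway, rng)
        expected = sum(
            1 for i, a in enumerate(arr)
            if a.acuity in (4, 5) and a.mode == "walkin"
            and draws["u_redirect"][i] < 0.5)
        assert res.kpis["n_redirected"] == expected

    def test_conservation_at_every_boundary(self, profile, pathway):
        net = open_mtc_network()
        arr = u.sample_nhpp_arrivals(profile, MONDAY, 2, seed=6)
        sc = u.Scenario(name="r", redirect_fraction=0.4,
                        targets={"MTC1": 0.5, "MTC2": 0.5})
        res = u.run_replication(net, arr, pathway, sc, run_minutes=2880, seed=7)
        check_conservation(res)

    def test_determinism_identical_logs(self, network, profile, pathway):
        arr = u.sample_nhpp_arrivals(profile, MONDAY, 1, seed=8)
        a = u.run_replication(network, arr, pathway, run_minutes=1440, seed=9)
        b = u.run_replication(network, arr, pathway, run_minutes=1440, seed=9)
        assert a.events.to_csv(index=False) == b.events.to_csv(index=False)
        assert a.patients.to_csv(index=False) == b.patients.to_csv(index=False)

    def test_priority_discipline_from_event_log(self, pathway):
        """With cubicles never binding, no category-4/5 patient may start
        assessment while a higher-priority patient is queued for a doctor."""
        net = u.NetworkSpec(facilities=[
            u.FacilitySpec(facility_id="ED1", kind="ED",
                           servers={"triage_nurses": 5, "doctors": 2, "cubicles": 100000})])
        prof = constant_profile(8.0)
        # a six-hour burst that overloads two doctors, then drains fully
        arr = [a for a in u.sample_nhpp_arrivals(prof, MONDAY, 1, seed=10)
               if a.t_minutes < 360]
        res = u.run_replication(net, arr, pathway, run_minutes=1440, seed=11)
        pats = res.patients.dropna(subset=["assessment_start", "triage_end"])
        queued = pats[["patient_id", "acuity", "triage_end", "assessment_start"]]
        low = queued[queued["acuity"] >= 4]
        high = queued[queued["acuity"] <= 3]
        assert len(low) > 10 and len(high) > 10
        for _, lo in low.iterrows():
            blocked = high[(high["triage_end"] < lo["assessment_start"])
                           & (high["assessment_start"] > lo["assessment_start"])]
            assert blocked.empty, f"{lo['patient_id']} overtook {list(blocked['patient_id'])}"

    def test_unsorted_arrivals_rejected(self, network, pathway, profile):
        arr = u.sample_nhpp_arrivals(profile, MONDAY, 1, seed=1)
        with pytest.raises(u.ValidationError):
            u.run_replication(network, list(reversed(arr)), pathway, run_minutes=60, seed=0)

    def test_mmc_limit_smoke(self):
        """Single-server sanity check against the Erlang-C closed form.

        Pooled waits over 40 seeded runs of 5 days each (first 12 hours
        discarded as warm-up); the sampling error of this design is about
        5%, so a 15% envelope is a pure correctness check.
        """
        net, prof, pw = mmc_setup(c=1, utilisation=0.75)
        waits = []
        for r in range(40):
            arr = u.sample_nhpp_arrivals(prof, MONDAY, 5, seed=100 + r)
            res = u.run_replication(net, arr, pw, run_minutes=5 * 1440, seed=200 + r,
                                    record_interval_minutes=1440)
            p = res.patients.dropna(subset=["assessment_start"])
            p = p[(p["arrival_time"] >= 720)]
            waits.append((p["assessment_start"] - p["arrival_time"]).to_numpy())
        wq = erlang_c_wq(1, 0.75 * 6.0, 6.0) * 60.0  # minutes
        assert abs(np.concatenate(waits).mean() - wq) / wq < 0.15


class TestKpis:
    def _patients(self, rows):
        from urgentsim.des import PATIENT_COLUMNS
        recs = []
        for r in rows:
            rec = {c: None for c in PATIENT_COLUMNS}
            rec.update({"is_init": False, "redirected": False, "mode": "walkin",
                        "facility_id": "ED1", "acuity": 3})
            rec.update(r)
            recs.append(rec)
        return pd.DataFrame(recs, columns=PATIENT_COLUMNS)

    def test_cdu_clock_stops_at_entry(self):
        df = self._patients([{
            "patient_id": "a", "arrival_time": 0.0, "cdu_entry": 100.0,
            "disposition_time": 500.0, "disposition": "cdu",
        }])
        kpis = u.compute_kpis(df)
        assert kpis["mean_time_in_ed"] == 100.0
        assert kpis["four_hour_frac"] == 1.0

    def test_four_hour_boundary_inclusive(self):
        df = self._patients([
            {"patient_id": "a", "arrival_time": 0.0, "disposition_time": 230.0,
             "disposition": "discharge"},
            {"patient_id": "b", "arrival_time": 0.0, "disposition_time": 241.0,
             "disposition": "discharge"},
        ])
        assert u.compute_kpis(df)["four_hour_frac"] == 0.5

    def test_empty_log(self):
        kpis = u.compute_kpis(pd.DataFrame())
        assert kpis["n_completed"] == 0 and kpis["n_censored"] == 0

    def test_missing_disposition_counted_censored(self):
        df = self._patients([
            {"patient_id": "a", "arrival_time": 0.0, "disposition_time": 100.0,
             "disposition": "discharge"},
            {"patient_id": "b", "arrival_time": 50.0},
        ])
        kpis = u.compute_kpis(df)
        assert kpis["n_completed"] == 1
        assert kpis["n_censored"] == 1


class TestAlignment:
    def _targets(self, census, waiting, max_wait):
        return {"ED1": u.RealTimeSnapshot(MONDAY, "ED1", census, waiting, max_wait)}

    def test_target_reproduced_exactly(self, network, profile, pathway):
        init = u.warmup_then_align(network, pathway, profile, warmup_hours=0,
                                   targets=self._targets(10, 4, 30.0), seed=1)
        assert init.measure()["ED1"] == (10, 4, 30.0)

    def test_zero_target_empties_system_despite_warmup(self, network, profile, pathway):
        init = u.warmup_then_align(network, pathway, profile, warmup_hours=6,
                                   targets=self._targets(0, 0, 0.0), seed=2)
        assert init.measure().get("ED1", (0, 0, 0.0))[0] == 0

    def test_synthesised_entities_when_no_warmup(self, network, profile, pathway):
        init = u.warmup_then_align(network, pathway, profile, warmup_hours=0,
                                   targets=self._targets(5, 0, 0.0), seed=3)
        ed_patients = [p for p in init.patients if p.facility_id == "ED1"]
        assert len(ed_patients) == 5
        assert all(p.stage != "waiting" for p in ed_patients)

    def test_warmup_state_carried_and_adjusted(self, network, profile, pathway):
        init = u.warmup_then_align(network, pathway, profile, warmup_hours=12,
                                   targets=self._targets(12, 3, 45.0), seed=4)
        assert init.measure()["ED1"] == (12, 3, 45.0)
        # warm-up entities should be among those carried over
        carried = [p for p in init.patients
                   if p.facility_id == "ED1" and not p.patient_id.startswith(("W", "S"))]
        assert carried

    def test_invalid_target_rejected(self, network, profile, pathway):
        with pytest.raises(u.ValidationError):
            u.warmup_then_align(network, pathway, profile, 0,
                                {"ED1": u.RealTimeSnapshot(MONDAY, "ED1", 5, 2, 30.0),
                                 "XX": u.RealTimeSnapshot(MONDAY, "XX", 1, 0, 0.0)}, seed=0)

    def test_simulation_measures_target_at_time_zero(self, network, profile, pathway):
        snap = u.RealTimeSnapshot(MONDAY, "ED1", 14, 5, 62.5)
        init = u.warmup_then_align(network, pathway, profile, 0, {"ED1": snap}, seed=5)
        res = u.run_replication(network, [], pathway, run_minutes=60, seed=6, init=init)
        row0 = res.facility_series["ED1"].iloc[0]
        assert int(row0["census"]) == 14
        assert int(row0["waiting"]) == 5
        assert row0["max_wait"] == pytest.approx(62.5, abs=1e-9)

    def test_conservation_with_initial_state(self, network, profile, pathway):
        snap = u.RealTimeSnapshot(MONDAY, "ED1", 20, 8, 90.0)
        init = u.warmup_then_align(network, pathway, profile, 0, {"ED1": snap}, seed=7)
        arr = u.sample_nhpp_arrivals(profile, MONDAY, 1, seed=8)
        res = u.run_replication(network, arr, pathway, run_minutes=720, seed=9, init=init)
        check_conservation(res)


class TestScenarios:
    def test_null_scenario_equals_baseline(self, network, profile, pathway):
        null = u.Scenario(name="null", redirect_fraction=0.0)
        out = u.run_scenarios(network, profile, pathway, [BASELINE, null],
                              replications=3, base_seed=42, run_minutes=720)
        pd.testing.assert_frame_equal(out["baseline"].per_rep, out["null"].per_rep)

    def test_single_replication_flagged_degenerate(self, network, profile, pathway):
        out = u.run_scenarios(network, profile, pathway, [BASELINE],
                              replications=1, base_seed=1, run_minutes=360)
        s = out["baseline"]
        assert s.degenerate_ci
        for k, (lo, hi) in s.kpi_ci.items():
            assert lo == hi == pytest.approx(s.kpi_mean[k], nan_ok=True)
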