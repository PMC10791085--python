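"""Discrete-event simulation of ED patient flow and the urgent-care network.

The ED pathway is: arrival -> optional redirection of eligible
low-acuity walk-ins to a minor treatment centre -> triage (triage-nurse
pool, FIFO) -> assessment queue (doctor + cubicle, priority by triage
category ascending, FIFO within category) -> assessment -> optional
investigation (Ix) -> optional treatment (Rx) -> optional one extra
Ix/Rx cycle -> disposition {discharge | admit with downstream boarding
delay | clinical decision unit (CDU), where the waiting-time clock
stops}.  MTCs are single-queue multi-server stations.

Runs support a warm-up period and *mixed real-time initial conditions*:
:func:`warmup_then_align` warms the model up from empty, then
deterministically adjusts the frozen state until it reproduces a live
snapshot (census, waiting count, maximum wait) exactly.

Scenario comparisons use common random numbers: replication ``r`` uses
the same arrival stream and the same per-patient attribute/duration
draws in every scenario, so differences between scenarios are due to
the policy alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .config import (
    ArrivalProfile,
    NetworkSpec,
    PathwaySpec,
    Scenario,
    ServiceTime,
    ValidationError,
)
from .engine import Environment, Request, Resource, Timeout
from .feed import ArrivalRecord, RealTimeSnapshot, sample_nhpp_arrivals

DEFAULT_START = datetime(2025, 1, 6)  # a Monday

BASELINE = Scenario(name="baseline", redirect_fraction=0.0)

# stages a patient can occupy between activities
ED_SERVICE_STAGES = ("assessment", "investigation", "treatment", "boarding", "cdu")


def durations_from_uniforms(st: ServiceTime, u: np.ndarray) -> np.ndarray:
    """Map uniform(0,1) draws to durations of the configured distribution.

    Using the inverse CDF keeps draws aligned across scenarios (common
    random numbers): the same uniform always maps to the same duration.
    """
    u = np.asarray(u)
    if st.dist == "fixed" or st.mean == 0:
        return np.full(u.shape, st.mean)
    if st.dist == "exponential":
        return -st.mean * np.log1p(-u)
    sigma2 = math.log(1.0 + st.cv**2)
    mu = math.log(st.mean) - sigma2 / 2.0
    return np.exp(mu + math.sqrt(sigma2) * ndtri(np.clip(u, 1e-12, 1 - 1e-12)))


# ---------------------------------------------------------------------------
# Initial conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InitPatient:
    """A patient present at time zero, carried over or synthesised."""

    patient_id: str
    facility_id: str
    acuity: int
    mode: str
    arrival_offset: float  # minutes before time zero (<= 0)
    stage: str  # "waiting" | ED_SERVICE_STAGES | "mtc_service"
    remaining: Optional[float] = None  # minutes left in current activity


@dataclass(frozen=True)
class InitState:
    """Initial in-department population per facility at time zero."""

    patients: Tuple[InitPatient, ...]

    def by_facility(self) -> Dict[str, List[InitPatient]]:
        out: Dict[str, List[InitPatient]] = {}
        for p in self.patients:
            out.setdefault(p.facility_id, []).append(p)
        return out

    def measure(self) -> Dict[str, Tuple[int, int, float]]:
        """(census, waiting, max_wait_minutes) per facility."""
        out: Dict[str, Tuple[int, int, float]] = {}
        for fid, plist in self.by_facility().items():
            waiting = [p for p in plist if p.stage == "waiting"]
            max_wait = -min((p.arrival_offset for p in waiting), default=0.0)
            out[fid] = (len(plist), len(waiting), max_wait)
        return out


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    scenario: str
    seed: int
    start: datetime
    run_minutes: float
    record_interval_minutes: int
    facility_series: Dict[str, pd.DataFrame]  # time, census, waiting, max_wait
    patients: pd.DataFrame
    events: pd.DataFrame
    kpis: Dict
    init_counts: Dict[str, int]
    final_state: Optional[Dict] = None


PATIENT_COLUMNS = [
    "patient_id", "facility_id", "acuity", "mode", "arrival_time", "is_init",
    "triage_start", "triage_end", "assessment_start", "assessment_end",
    "cdu_entry", "boarding_start", "disposition_time", "disposition",
    "redirected", "redirected_to",
]


class _Patient:
    __slots__ = ("pid", "idx", "acuity", "mode", "arrival_time", "facility_id",
                 "stage", "stage_end", "rec", "is_init", "held")

    def __init__(self, pid, idx, acuity, mode, arrival_time, facility_id, is_init=False):
        self.pid = pid
        self.idx = idx
        self.acuity = acuity
        self.mode = mode
        self.arrival_time = arrival_time
        self.facility_id = facility_id
        self.stage = "waiting"
        self.stage_end: Optional[float] = None
        self.is_init = is_init
        self.held: List[Resource] = []
        self.rec = {
            "patient_id": pid, "facility_id": facility_id, "acuity": acuity,
            "mode": mode, "arrival_time": arrival_time, "is_init": is_init,
            "redirected": False, "redirected_to": None, "disposition": None,
        }


class _FacState:
    __slots__ = ("spec", "resources", "in_system", "waiting")

    def __init__(self, env: Environment, spec) -> None:
        self.spec = spec
        self.resources = {name: Resource(env, cap, f"{spec.facility_id}.{name}")
                          for name, cap in spec.servers.items()}
        self.in_system: Dict[str, _Patient] = {}
        self.waiting: Dict[str, float] = {}


_DRAW_KEYS = [
    "u_redirect", "u_target", "u_ix", "u_rx", "u_cycle", "u_disp",
    "t_triage", "t_assessment", "t_ix1", "t_rx1", "t_ix2", "t_rx2",
    "t_cdu", "t_boarding", "t_mtc",
]


def _make_draws(n: int, pathway: PathwaySpec, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Pre-draw every per-patient uniform, then transform durations.

    Each patient consumes a fixed-size block regardless of the path it
    ends up taking, so the draws stay synchronised across scenarios.
    """
    u = rng.random((n, len(_DRAW_KEYS))) if n else np.empty((0, len(_DRAW_KEYS)))
    d = {k: u[:, i].copy() for i, k in enumerate(_DRAW_KEYS)}
    st = pathway.service_times
    d["t_triage"] = durations_from_uniforms(st["triage"], d["t_triage"])
    d["t_assessment"] = durations_from_uniforms(st["assessment"], d["t_assessment"])
    d["t_ix1"] = durations_from_uniforms(st["investigation"], d["t_ix1"])
    d["t_rx1"] = durations_from_uniforms(st["treatment"], d["t_rx1"])
    d["t_ix2"] = durations_from_uniforms(st["investigation"], d["t_ix2"])
    d["t_rx2"] = durations_from_uniforms(st["treatment"], d["t_rx2"])
    d["t_cdu"] = durations_from_uniforms(st["cdu_stay"], d["t_cdu"])
    d["t_boarding"] = durations_from_uniforms(st["boarding"], d["t_boarding"])
    d["t_mtc"] = durations_from_uniforms(st["mtc_treatment"], d["t_mtc"])
    return d


class _Sim:
    def __init__(self, network: NetworkSpec, arrivals: Sequence[ArrivalRecord],
                 pathway: PathwaySpec, scenario: Scenario, run_minutes: float,
                 seed: int, start: datetime, record_interval: int,
                 init: Optional[InitState], capture_state: bool) -> None:
        self.network = network
        self.pathway = pathway
        self.scenario = scenario
        self.run_minutes = float(run_minutes)
        self.seed = int(seed)
        self.start = start
        self.record_interval = int(record_interval)
        self.capture_state = capture_state

        self.env = Environment()
        self.fac: Dict[str, _FacState] = {
            f.facility_id: _FacState(self.env, f) for f in network.facilities
        }
        self.ed_id = network.ed.facility_id
        self.events: List[Tuple[str, str, float, str]] = []
        self.records: List[dict] = []
        self.series_rows: Dict[str, List[tuple]] = {fid: [] for fid in self.fac}
        self._disp_cdf = np.cumsum(np.asarray(pathway.disposition_probs), axis=1)

        arrivals = [a for a in arrivals if 0.0 <= a.t_minutes < self.run_minutes]
        self.arrivals = arrivals
        rng = np.random.default_rng(np.random.SeedSequence([self.seed & 0x7FFFFFFF, 11]))
        self.D = _make_draws(len(arrivals), pathway, rng)

        init_list = list(init.patients) if init is not None else []
        self._validate_init(init_list)
        rng_i = np.random.default_rng(np.random.SeedSequence([self.seed & 0x7FFFFFFF, 13]))
        self.DI = _make_draws(len(init_list), pathway, rng_i)
        self.init_list = init_list
        self.init_counts = {fid: 0 for fid in self.fac}

    # -- setup ------------------------------------------------------
    def _validate_init(self, init_list: List[InitPatient]) -> None:
        for p in init_list:
            if p.facility_id not in self.fac:
                raise ValidationError(f"init patient {p.patient_id}: unknown facility {p.facility_id!r}")
            kind = self.fac[p.facility_id].spec.kind
            if kind == "MTC" and p.stage not in ("waiting", "mtc_service"):
                raise ValidationError(f"init patient {p.patient_id}: stage {p.stage!r} invalid for an MTC")
            if kind == "ED" and p.stage not in ("waiting",) + ED_SERVICE_STAGES:
                raise ValidationError(f"init patient {p.patient_id}: stage {p.stage!r} invalid for the ED")
            if p.arrival_offset > 0:
                raise ValidationError(f"init patient {p.patient_id}: arrival_offset must be <= 0")
            if p.stage != "waiting" and (p.remaining is None or p.remaining < 0):
                raise ValidationError(f"init patient {p.patient_id}: in-service stage needs remaining >= 0")

    def _setup(self) -> None:
        # recorders are scheduled first so that, at equal times, the state
        # is sampled before any arrival/departure at that instant fires
        n_bounds = int(self.run_minutes // self.record_interval) + 1
        for k in range(n_bounds):
            self.env.schedule(k * self.record_interval, self._record)
        self._place_init()
        for i, arr in enumerate(self.arrivals):
            self.env.schedule(arr.t_minutes, self._on_arrival, i, arr)

    def _place_init(self) -> None:
        for j, ip in enumerate(self.init_list):
            fs = self.fac[ip.facility_id]
            p = _Patient(ip.patient_id, j, ip.acuity, ip.mode, ip.arrival_offset,
                         ip.facility_id, is_init=True)
            fs.in_system[p.pid] = p
            self.init_counts[ip.facility_id] += 1
            if ip.stage == "waiting":
                fs.waiting[p.pid] = ip.arrival_offset
                if fs.spec.kind == "ED":
                    self.env.process(self._ed_from_assessment_queue(p, self.DI))
                else:
                    self.env.process(self._mtc_process(p, self.DI, skip_entry=True))
            else:
                p.stage = ip.stage
                p.stage_end = ip.remaining
                self.env.process(self._init_continuation(p, ip))

    # -- state recording --------------------------------------------
    def _record(self) -> None:
        t = self.env.now
        for fid, fs in self.fac.items():
            census = len(fs.in_system)
            waiting = len(fs.waiting)
            max_wait = t - min(fs.waiting.values()) if waiting else 0.0
            self.series_rows[fid].append((t, census, waiting, max_wait))

    def _log(self, p: _Patient, event: str) -> None:
        self.events.append((p.pid, event, self.env.now, p.facility_id))

    # -- arrivals ----------------------------------------------------
    def _on_arrival(self, i: int, arr: ArrivalRecord) -> None:
        sc = self.scenario
        if (sc.redirect_fraction > 0.0
                and arr.acuity in sc.eligible_categories
                and arr.mode in sc.eligible_modes
                and self.D["u_redirect"][i] < sc.redirect_fraction):
            target = self._choose_target(i, arr.acuity)
            if target is not None:
                self._redirect(i, arr, target)
                return
        p = _Patient(arr.patient_id, i, arr.acuity, arr.mode, self.env.now, self.ed_id)
        fs = self.fac[self.ed_id]
        fs.in_system[p.pid] = p
        fs.waiting[p.pid] = p.arrival_time
        self._log(p, "arrival")
        self.env.process(self._ed_process(p))

    def _choose_target(self, i: int, acuity: int) -> Optional[str]:
        hour = (self.start + timedelta(minutes=self.env.now)).hour \
            + (self.start + timedelta(minutes=self.env.now)).minute / 60.0
        open_targets = [
            (fid, w) for fid, w in sorted(self.scenario.targets.items())
            if acuity in self.network.facility(fid).accepts_categories
            and self.network.facility(fid).is_open(hour)
        ]
        total = sum(w for _, w in open_targets)
        if total <= 0:
            return None
        u = self.D["u_target"][i] * total
        acc = 0.0
        for fid, w in open_targets:
            acc += w
            if u < acc:
                return fid
        return open_targets[-1][0]

    def _redirect(self, i: int, arr: ArrivalRecord, target: str) -> None:
        p = _Patient(arr.patient_id, i, arr.acuity, arr.mode, self.env.now, self.ed_id)
        p.rec["redirected"] = True
        p.rec["redirected_to"] = target
        p.rec["disposition"] = "redirected"
        self._log(p, "redirected")
        self.records.append(p.rec)
        delay = self.network.travel_delay_minutes
        self.env.schedule(delay, self._mtc_arrival, i, arr, target)

    def _mtc_arrival(self, i: int, arr: ArrivalRecord, target: str) -> None:
        p = _Patient(arr.patient_id + "@mtc", i, arr.acuity, arr.mode, self.env.now, target)
        p.rec["redirected"] = True
        fs = self.fac[target]
        fs.in_system[p.pid] = p
        fs.waiting[p.pid] = p.arrival_time
        self._log(p, "arrival")
        self.env.process(self._mtc_process(p, self.D, skip_entry=True))

    # -- ED pathway ---------------------------------------------------
    def _ed_process(self, p: _Patient):
        fs = self.fac[self.ed_id]
        tri = fs.resources["triage_nurses"]
        yield Request(tri, priority=p.arrival_time)
        p.rec["triage_start"] = self.env.now
        self._log(p, "triage_start")
        yield Timeout(self.D["t_triage"][p.idx])
        tri.release()
        p.rec["triage_end"] = self.env.now
        self._log(p, "triage_end")
        yield from self._ed_from_assessment_queue(p, self.D)

    def _ed_from_assessment_queue(self, p: _Patient, D):
        fs = self.fac[self.ed_id]
        prio = (p.acuity, p.arrival_time)
        cub = fs.resources["cubicles"]
        doc = fs.resources["doctors"]
        yield Request(cub, priority=prio)
        p.held.append(cub)
        yield Request(doc, priority=prio)
        p.held.append(doc)
        del fs.waiting[p.pid]
        t_assess = D["t_assessment"][p.idx]
        p.stage = "assessment"
        p.stage_end = self.env.now + t_assess
        p.rec["assessment_start"] = self.env.now
        self._log(p, "assessment_start")
        yield Timeout(t_assess)
        doc.release()
        p.held.remove(doc)
        p.rec["assessment_end"] = self.env.now
        self._log(p, "assessment_end")
        yield from self._cycles_then_disposition(p, D)

    def _cycles_then_disposition(self, p: _Patient, D, skip_first_ix=False, skip_first_rx=False):
        i = p.idx
        acu = p.acuity - 1
        needs_ix = D["u_ix"][i] < self.pathway.p_investigation[acu]
        needs_rx = D["u_rx"][i] < self.pathway.p_treatment[acu]
        second = D["u_cycle"][i] < self.pathway.p_second_cycle and (needs_ix or needs_rx)
        plan = []
        if not skip_first_ix and not skip_first_rx:
            plan.append((needs_ix, needs_rx, "t_ix1", "t_rx1"))
        elif not skip_first_rx:
            plan.append((False, needs_rx, "t_ix1", "t_rx1"))
        if second:
            plan.append((needs_ix, needs_rx, "t_ix2", "t_rx2"))
        fs = self.fac[self.ed_id]
        doc = fs.resources["doctors"]
        for do_ix, do_rx, kix, krx in plan:
            if do_ix:
                dur = D[kix][i]
                p.stage = "investigation"
                p.stage_end = self.env.now + dur
                self._log(p, "investigation_start")
                yield Timeout(dur)
                self._log(p, "investigation_end")
            if do_rx:
                yield Request(doc, priority=(p.acuity, p.arrival_time))
                p.held.append(doc)
                dur = D[krx][i]
                p.stage = "treatment"
                p.stage_end = self.env.now + dur
                self._log(p, "treatment_start")
                yield Timeout(dur)
                doc.release()
                p.held.remove(doc)
                self._log(p, "treatment_end")
        yield from self._disposition(p, D)

    def _disposition(self, p: _Patient, D):
        i = p.idx
        cdf = self._disp_cdf[p.acuity - 1]
        u = D["u_disp"][i]
        kind = "discharge" if u < cdf[0] else ("admit" if u < cdf[1] else "cdu")
        fs = self.fac[self.ed_id]
        if kind == "discharge":
            self._depart(p, "discharge")
        elif kind == "admit":
            dur = D["t_boarding"][i]
            p.stage = "boarding"
            p.stage_end = self.env.now + dur
            p.rec["boarding_start"] = self.env.now
            self._log(p, "boarding_start")
            if not self.pathway.boarding_holds_cubicle:
                self._release_held(p)
            yield Timeout(dur)
            self._depart(p, "admit")
        else:
            p.rec["cdu_entry"] = self.env.now
            self._log(p, "cdu_entry")
            self._release_held(p)  # patient moves from cubicle to the CDU
            dur = D["t_cdu"][i]
            p.stage = "cdu"
            p.stage_end = self.env.now + dur
            yield Timeout(dur)
            self._depart(p, "cdu")

    def _release_held(self, p: _Patient) -> None:
        for res in p.held:
            res.release()
        p.held.clear()

    def _depart(self, p: _Patient, disposition: str) -> None:
        self._release_held(p)
        fs = self.fac[p.facility_id]
        fs.in_system.pop(p.pid, None)
        fs.waiting.pop(p.pid, None)
        p.rec["disposition"] = disposition
        p.rec["disposition_time"] = self.env.now
        self._log(p, "depart")
        self.records.append(p.rec)

    # -- MTC pathway ---------------------------------------------------
    def _mtc_process(self, p: _Patient, D, skip_entry=False):
        fs = self.fac[p.facility_id]
        if not skip_entry:
            fs.in_system[p.pid] = p
            fs.waiting[p.pid] = p.arrival_time
            self._log(p, "arrival")
        cli = fs.resources["clinicians"]
        yield Request(cli, priority=p.arrival_time)
        p.held.append(cli)
        del fs.waiting[p.pid]
        dur = D["t_mtc"][p.idx]
        p.stage = "mtc_service"
        p.stage_end = self.env.now + dur
        p.rec["assessment_start"] = self.env.now
        self._log(p, "treatment_start")
        yield Timeout(dur)
        self._log(p, "treatment_end")
        self._depart(p, "discharge")

    # -- init continuation --------------------------------------------
    def _init_continuation(self, p: _Patient, ip: InitPatient):
        """Finish the in-progress activity, then continue down the pathway.

        Carried-over and synthesised entities occupy resources
        unconditionally (the physical department can exceed nominal
        capacity); fresh requests queue until occupancy drops.
        """
        D = self.DI
        fs = self.fac[p.facility_id]
        remaining = float(ip.remaining or 0.0)
        if ip.stage == "mtc_service":
            cli = fs.resources["clinicians"]
            cli.occupy()
            p.held.append(cli)
            yield Timeout(remaining)
            self._depart(p, "discharge")
            return
        cub = fs.resources["cubicles"]
        doc = fs.resources["doctors"]
        if ip.stage in ("assessment", "investigation", "treatment") or (
                ip.stage == "boarding" and self.pathway.boarding_holds_cubicle):
            cub.occupy()
            p.held.append(cub)
        if ip.stage in ("assessment", "treatment"):
            doc.occupy()
            p.held.append(doc)
        p.stage = ip.stage
        p.stage_end = remaining
        yield Timeout(remaining)
        if ip.stage == "assessment":
            doc.release()
            p.held.remove(doc)
            p.rec["assessment_end"] = self.env.now
            yield from self._cycles_then_disposition(p, D)
        elif ip.stage == "investigation":
            yield from self._cycles_then_disposition(p, D, skip_first_ix=True)
        elif ip.stage == "treatment":
            doc.release()
            p.held.remove(doc)
            yield from self._cycles_then_disposition(p, D, skip_first_ix=True, skip_first_rx=True)
        elif ip.stage == "boarding":
            self._depart(p, "admit")
        elif ip.stage == "cdu":
            self._depart(p, "cdu")

    # -- run -----------------------------------------------------------
    def run(self) -> SimulationResult:
        self._setup()
        self.env.run(until=self.run_minutes)

        final_state = None
        if self.capture_state:
            final_state = {}
            for fid, fs in self.fac.items():
                waiting = [(p.pid, p.arrival_time, p.acuity, p.mode)
                           for p in fs.in_system.values() if p.pid in fs.waiting]
                in_service = [
                    (p.pid, p.acuity, p.mode, p.stage,
                     max((p.stage_end or self.run_minutes) - self.run_minutes, 0.0))
                    for p in fs.in_system.values() if p.pid not in fs.waiting
                ]
                waiting.sort(key=lambda x: x[1])
                in_service.sort(key=lambda x: x[0])
                final_state[fid] = {"waiting": waiting, "in_service": in_service}

        series = {
            fid: pd.DataFrame(rows, columns=["time", "census", "waiting", "max_wait"])
            for fid, rows in self.series_rows.items()
        }
        # patients still in the department at the end are censored
        for fs in self.fac.values():
            for p in fs.in_system.values():
                self.records.append(p.rec)
        patients = pd.DataFrame(self.records, columns=PATIENT_COLUMNS) if self.records \
            else pd.DataFrame(columns=PATIENT_COLUMNS)
        events = pd.DataFrame(self.events, columns=["patient_id", "event", "timestamp", "facility_id"])

        kpis = compute_kpis(patients)
        kpis["utilisation"] = {
            f"{fid}.{name}": res.utilisation(self.run_minutes)
            for fid, fs in self.fac.items() for name, res in fs.resources.items()
        }
        ed_series = series[self.ed_id]
        kpis["mean_ed_census"] = float(ed_series["census"].mean())
        kpis["mean_ed_waiting"] = float(ed_series["waiting"].mean())

        return SimulationResult(
            scenario=self.scenario.name, seed=self.seed, start=self.start,
            run_minutes=self.run_minutes, record_interval_minutes=self.record_interval,
            facility_series=series, patients=patients, events=events, kpis=kpis,
            init_counts=self.init_counts, final_state=final_state,
        )


def run_replication(
    network: NetworkSpec,
    arrivals: Sequence[ArrivalRecord],
    pathway: PathwaySpec,
    scenario: Optional[Scenario] = None,
    run_minutes: float = 24 * 60.0,
    seed: int = 0,
    init: Optional[InitState] = None,
    record_interval_minutes: int = 30,
    start: datetime = DEFAULT_START,
    capture_state: bool = False,
) -> SimulationResult:
    """Execute one seeded replication of the network model.

    ``arrivals`` is a sorted event log (e.g. from
    :func:`urgentsim.feed.sample_nhpp_arrivals`); ``seed`` drives all
    duration/branch draws and is independent of the arrival stream so
    scenarios can share arrivals (common random numbers).
    """
    if run_minutes <= 0:
        raise ValidationError(f"run_minutes must be positive, got {run_minutes}")
    ts = [a.t_minutes for a in arrivals]
    if any(a > b for a, b in zip(ts, ts[1:])):
        raise ValidationError("arrivals must be sorted by time")
    sim = _Sim(network, arrivals, pathway, scenario or BASELINE, run_minutes, seed,
               start, record_interval_minutes, init, capture_state)
    return sim.run()


# ---------------------------------------------------------------------------
# KPIs
# ---------------------------------------------------------------------------

def compute_kpis(patients: pd.DataFrame, four_hour_limit: float = 240.0) -> Dict:
    """Patient-level KPIs with the CDU clock-stop rule.

    Time in ED is ``disposition_time - arrival_time`` except for CDU
    patients, whose clock stops at CDU entry.  Only non-init entities
    with a complete timestamp chain enter the averages; entities still
    in the system (no disposition) are excluded and counted as censored.
    """
    if len(patients) == 0:
        return {"n_completed": 0, "n_censored": 0, "n_redirected": 0,
                "four_hour_frac": float("nan"), "mean_time_in_ed": float("nan"),
                "median_time_in_ed": float("nan"), "mean_time_by_acuity": {},
                "median_time_by_acuity": {}, "mean_wait_assessment": float("nan")}
    df = patients
    censored = int(df["disposition"].isna().sum())
    ed = df[(~df["is_init"]) & df["disposition"].isin(["discharge", "admit", "cdu"])
            & (~df["redirected"].astype(bool))].copy()
    n_redirected = int(((df["disposition"] == "redirected")).sum())
    if len(ed):
        clock_end = ed["disposition_time"].where(ed["disposition"] != "cdu", ed["cdu_entry"])
        ed["clock_time"] = clock_end - ed["arrival_time"]
        four_hour = float((ed["clock_time"] <= four_hour_limit).mean())
        mean_t = float(ed["clock_time"].mean())
        median_t = float(ed["clock_time"].median())
        by_acuity_mean = {int(k): float(v) for k, v in ed.groupby("acuity")["clock_time"].mean().items()}
        by_acuity_median = {int(k): float(v) for k, v in ed.groupby("acuity")["clock_time"].median().items()}
        wait = (ed["assessment_start"] - ed["arrival_time"]).dropna()
        mean_wait = float(wait.mean()) if len(wait) else float("nan")
    else:
        four_hour = mean_t = median_t = mean_wait = float("nan")
        by_acuity_mean = {}
        by_acuity_median = {}
    return {
        "n_completed": int(len(ed)),
        "n_censored": censored,
        "n_redirected": n_redirected,
        "four_hour_frac": four_hour,
        "mean_time_in_ed": mean_t,
        "median_time_in_ed": median_t,
        "mean_time_by_acuity": by_acuity_mean,
        "median_time_by_acuity": by_acuity_median,
        "mean_wait_assessment": mean_wait,
    }


# ---------------------------------------------------------------------------
# Warm-up and real-time alignment
# ---------------------------------------------------------------------------

def _stage_weights(pathway: PathwaySpec, profile: ArrivalProfile) -> Dict[str, float]:
    """Expected occupancy weight per ED service stage (Little's law shape)."""
    mix = (np.asarray(profile.acuity_mix_ambulance) * profile.ambulance_fraction
           + np.asarray(profile.acuity_mix_walkin) * (1.0 - profile.ambulance_fraction))
    p_ix = float(mix @ np.asarray(pathway.p_investigation))
    p_rx = float(mix @ np.asarray(pathway.p_treatment))
    disp = np.asarray(pathway.disposition_probs)
    p_admit = float(mix @ disp[:, 1])
    p_cdu = float(mix @ disp[:, 2])
    cyc = 1.0 + pathway.p_second_cycle
    st = pathway.service_times
    w = {
        "assessment": st["assessment"].mean,
        "investigation": p_ix * st["investigation"].mean * cyc,
        "treatment": p_rx * st["treatment"].mean * cyc,
        "boarding": p_admit * st["boarding"].mean,
        "cdu": p_cdu * st["cdu_stay"].mean,
    }
    total = sum(w.values())
    if total <= 0:
        return {"assessment": 1.0}
    return {k: v / total for k, v in w.items()}


def _sample_stage_duration(pathway: PathwaySpec, stage: str, u: float) -> float:
    key = {"assessment": "assessment", "investigation": "investigation",
           "treatment": "treatment", "boarding": "boarding", "cdu": "cdu_stay",
           "mtc_service": "mtc_treatment"}[stage]
    return float(durations_from_uniforms(pathway.service_times[key], np.array([u]))[0])


def warmup_then_align(
    network: NetworkSpec,
    pathway: PathwaySpec,
    profile: ArrivalProfile,
    warmup_hours: float,
    targets: Dict[str, RealTimeSnapshot],
    seed: int = 0,
    start: datetime = DEFAULT_START,
) -> InitState:
    """Warm the model up from empty, then align its state to live snapshots.

    After the warm-up run, for each facility with a target snapshot the
    frozen state is adjusted deterministically: waiting entities are
    dropped newest-first or synthesised until the waiting count matches;
    the oldest waiting entity's arrival is set to ``now -
    max_wait_minutes`` and every other waiting arrival is kept (or
    redrawn) inside that window; in-service entities are dropped or
    synthesised (stage drawn proportional to expected stage occupancy,
    remaining time = U * a fresh duration draw) until the census
    matches.  Measuring the returned state reproduces each target
    snapshot exactly.  Facilities without a target keep their warm-up
    state unchanged.
    """
    if warmup_hours < 0:
        raise ValidationError("warmup_hours must be >= 0")
    for fid, snap in targets.items():
        if fid not in {f.facility_id for f in network.facilities}:
            raise ValidationError(f"target for unknown facility {fid!r}")
        if snap.waiting > snap.census:
            raise ValidationError(f"target for {fid}: waiting > census")

    state: Dict[str, Dict] = {f.facility_id: {"waiting": [], "in_service": []}
                              for f in network.facilities}
    if warmup_hours > 0:
        w_min = warmup_hours * 60.0
        days = max(1, math.ceil(warmup_hours / 24.0))
        warm_arrivals = sample_nhpp_arrivals(
            profile, start - timedelta(minutes=w_min), days,
            seed=np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 21]),
            facility_id=network.ed.facility_id)
        res = run_replication(network, warm_arrivals, pathway, BASELINE,
                              run_minutes=w_min, seed=seed,
                              start=start - timedelta(minutes=w_min),
                              capture_state=True)
        for fid, fstate in res.final_state.items():
            state[fid] = {
                "waiting": [(pid, at - w_min, acu, mode) for pid, at, acu, mode in fstate["waiting"]],
                "in_service": fstate["in_service"],
            }

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 22]))
    weights = _stage_weights(pathway, profile)
    stage_names = sorted(weights)
    stage_p = np.array([weights[s] for s in stage_names])
    stage_p = stage_p / stage_p.sum()
    acu_mix = np.asarray(profile.acuity_mix_walkin)

    patients: List[InitPatient] = []
    counter = 0
    for fac in network.facilities:
        fid = fac.facility_id
        fstate = state[fid]
        if fid not in targets:
            patients.extend(_carry_over(fid, fstate))
            continue
        snap = targets[fid]
        mw = float(snap.max_wait_minutes)

        # waiting entities: keep oldest, drop newest, synthesise as needed
        # carried ids are namespaced so they can never collide with the
        # patient ids of the run the state is injected into
        waiting = sorted(fstate["waiting"], key=lambda x: x[1])[: snap.waiting]
        wlist: List[InitPatient] = []
        for pid, offset, acu, mode in waiting:
            wlist.append(InitPatient(f"C_{pid}", fid, int(acu), mode, float(offset), "waiting"))
        while len(wlist) < snap.waiting:
            acu = int(rng.choice(np.arange(1, 6), p=acu_mix))
            if fac.kind == "MTC":
                acu = max(acu, 4)
            wlist.append(InitPatient(f"W{fid}_{counter:04d}", fid, acu, "walkin",
                                     float(-rng.uniform(0.0, mw)) if mw > 0 else 0.0, "waiting"))
            counter += 1
        if wlist:
            # clamp every waiting arrival into (-max_wait, 0]; pin the oldest
            fixed: List[InitPatient] = []
            for k, ip in enumerate(sorted(wlist, key=lambda x: x.arrival_offset)):
                if k == 0:
                    off = -mw
                else:
                    off = ip.arrival_offset
                    if not (-mw < off <= 0.0):
                        off = float(-rng.uniform(0.0, mw)) if mw > 0 else 0.0
                fixed.append(InitPatient(ip.patient_id, fid, ip.acuity, ip.mode, off, "waiting"))
            wlist = fixed

        # in-service entities up to census - waiting
        n_service = snap.census - snap.waiting
        service = fstate["in_service"][:n_service]
        slist: List[InitPatient] = []
        for pid, acu, mode, stage, remaining in service:
            slist.append(InitPatient(f"C_{pid}", fid, int(acu), mode, -mw - 1.0, stage,
                                     float(remaining)))
        while len(slist) < n_service:
            acu = int(rng.choice(np.arange(1, 6), p=acu_mix))
            if fac.kind == "MTC":
                acu = max(acu, 4)
                stage = "mtc_service"
            else:
                stage = stage_names[int(rng.choice(len(stage_names), p=stage_p))]
            remaining = float(rng.random()) * _sample_stage_duration(pathway, stage, float(rng.random()))
            slist.append(InitPatient(f"S{fid}_{counter:04d}", fid, acu, "walkin",
                                     -mw - 1.0, stage, remaining))
            counter += 1
        patients.extend(wlist)
        patients.extend(slist)

    return InitState(patients=tuple(patients))


def _carry_over(fid: str, fstate: Dict) -> List[InitPatient]:
    out = [InitPatient(f"C_{pid}", fid, int(acu), mode, float(min(off, 0.0)), "waiting")
           for pid, off, acu, mode in fstate["waiting"]]
    out += [InitPatient(f"C_{pid}", fid, int(acu), mode, 0.0, stage, float(rem))
            for pid, acu, mode, stage, rem in fstate["in_service"]]
    return out


# ---------------------------------------------------------------------------
# Scenario batches with common random numbers
# ---------------------------------------------------------------------------

#: scalar KPIs aggregated across replications
SCALAR_KPIS = [
    "mean_ed_census", "mean_ed_waiting", "four_hour_frac", "mean_time_in_ed",
    "median_time_in_ed", "mean_wait_assessment", "n_completed", "n_redirected",
    "n_censored", "mean_ed_census_recovery",
]


@dataclass
class ScenarioSummary:
    name: str
    per_rep: pd.DataFrame  # one row per replication, SCALAR_KPIS columns
    kpi_mean: Dict[str, float]
    kpi_ci: Dict[str, Tuple[float, float]]
    degenerate_ci: bool
    mean_census_trajectory: pd.DataFrame  # time, census (ED, mean over reps)


def run_scenarios(
    network: NetworkSpec,
    profile: ArrivalProfile,
    pathway: PathwaySpec,
    scenarios: Sequence[Scenario],
    replications: int,
    base_seed: int,
    run_minutes: float = 8 * 60.0,
    init: Optional[InitState] = None,
    start: datetime = DEFAULT_START,
    record_interval_minutes: int = 30,
    recovery_window_minutes: Optional[float] = None,
    ci_level: float = 0.95,
) -> Dict[str, ScenarioSummary]:
    """Run each scenario against common random numbers and aggregate.

    Replication ``r`` draws one arrival stream and one set of
    per-patient attribute draws, reused by every scenario, so paired
    scenario contrasts are variance-reduced.  KPI means carry
    t-distribution confidence intervals across replications (degenerate,
    flagged, when ``replications == 1``).
    """
    if replications < 1:
        raise ValidationError("replications must be >= 1")
    recovery = recovery_window_minutes if recovery_window_minutes is not None else run_minutes
    days = max(1, math.ceil(run_minutes / (24 * 60.0)))
    ed_id = network.ed.facility_id

    out: Dict[str, ScenarioSummary] = {}
    arrivals_per_rep = []
    seeds = []
    for r in range(replications):
        ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, r, 0])
        arrivals_per_rep.append(sample_nhpp_arrivals(profile, start, days, seed=ss,
                                                     facility_id=ed_id))
        seeds.append(int(np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, r, 1])
                         .generate_state(1)[0] & 0x7FFFFFFF))

    for sc in scenarios:
        rows = []
        trajectories = []
        for r in range(replications):
            res = run_replication(network, arrivals_per_rep[r], pathway, sc,
                                  run_minutes=run_minutes, seed=seeds[r], init=init,
                                  record_interval_minutes=record_interval_minutes,
                                  start=start)
            ed_series = res.facility_series[ed_id]
            in_window = ed_series[ed_series["time"] <= recovery]
            row = {k: res.kpis.get(k, float("nan")) for k in SCALAR_KPIS if k != "mean_ed_census_recovery"}
            row["mean_ed_census_recovery"] = float(in_window["census"].mean())
            rows.append(row)
            trajectories.append(ed_series.set_index("time")["census"])
        per_rep = pd.DataFrame(rows)
        kpi_mean = {k: float(per_rep[k].mean()) for k in per_rep.columns}
        kpi_ci = {}
        degenerate = replications < 2
        for k in per_rep.columns:
            vals = per_rep[k].astype(float)
            m = float(vals.mean())
            if degenerate or vals.std(ddof=1) == 0 or math.isnan(vals.std(ddof=1)):
                kpi_ci[k] = (m, m)
            else:
                half = float(stats.t.ppf(0.5 + ci_level / 2, len(vals) - 1)
                             * vals.std(ddof=1) / math.sqrt(len(vals)))
                kpi_ci[k] = (m - half, m + half)
        traj = pd.concat(trajectories, axis=1).mean(axis=1).rename("census").reset_index()
        out[sc.name] = ScenarioSummary(
            name=sc.name, per_rep=per_rep, kpi_mean=kpi_mean, kpi_ci=kpi_ci,
            degenerate_ci=degenerate, mean_census_trajectory=traj,
        )
    return out
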