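"""The symbiotic update loop and the synthetic end-to-end validation.

Every update interval (default 30 minutes) the loop ingests a snapshot
batch from the live feed, refreshes the census forecast over the 4-hour
horizon, tests it against the hour-of-day crowding thresholds, and — on
a trigger — aligns the simulation to the latest snapshots, runs the
scenario set under common random numbers, and emits a ranked
recommendation.  The loop runs in virtual time against a replayed
stream, which makes it deterministic and testable; a wall-clock wrapper
would simply sleep between batches.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import FullConfig, Scenario, ValidationError
from .des import (
    BASELINE,
    InitState,
    ScenarioSummary,
    run_replication,
    run_scenarios,
    warmup_then_align,
)
from .feed import CensusSeries, RealTimeSnapshot, replay_stream, sample_nhpp_arrivals
from .forecast import ForecastResult, fit_forecast
from .trigger import TriggerEvent, TriggerProfile, detect, estimate_profile

logger = logging.getLogger(__name__)


@dataclass
class Recommendation:
    tick_time: datetime
    ranking: List[str]  # scenario names, best first
    chosen: str
    kpi_table: Dict[str, Dict[str, float]]  # scenario -> kpi -> mean
    deltas_vs_baseline: Dict[str, Dict[str, Tuple[float, float, float]]]
    # scenario -> kpi -> (mean delta, ci_lo, ci_hi); paired over replications


@dataclass
class LoopTick:
    tick_index: int
    tick_time: datetime
    snapshots: List[RealTimeSnapshot]
    skipped: bool = False
    forecast: Optional[ForecastResult] = None
    trigger_event: Optional[TriggerEvent] = None
    scenario_results: Optional[Dict[str, ScenarioSummary]] = None
    recommendation: Optional[Recommendation] = None

    def __post_init__(self):
        if (self.trigger_event is None) != (self.scenario_results is None):
            raise ValidationError("scenario results must be present iff a trigger event is")


@dataclass
class LoopState:
    """Persistable controller state; resuming from it reproduces the run."""

    history: CensusSeries
    profile: TriggerProfile
    next_tick: int = 0
    cooldown_until: Optional[datetime] = None


RANK_KPI = "mean_ed_census_recovery"
TIE_KPI = "four_hour_frac"


def run_loop(
    config: FullConfig,
    history: CensusSeries,
    stream: Union[Sequence[RealTimeSnapshot], Iterable[List[RealTimeSnapshot]]],
    scenarios: Optional[Sequence[Scenario]] = None,
    master_seed: Optional[int] = None,
    out_dir: Optional[Path] = None,
    state: Optional[LoopState] = None,
    max_ticks: Optional[int] = None,
) -> Tuple[List[LoopTick], LoopState]:
    """Drive the update loop over a replayed snapshot stream.

    Per tick: append the ED snapshot to the census history, refit the
    forecast, test the trigger, and on an exceedance align the model to
    the batch's snapshots and run all scenarios (baseline always
    included) with common random numbers.  After a recommendation the
    trigger is suppressed for one recovery window (cooldown).  A stream
    gap wider than the configured tolerance skips the tick with a
    warning (history is padded with the last value to stay on-grid).
    Fully deterministic under ``master_seed``.
    """
    exp = config.experiment
    seed = exp.seed if master_seed is None else master_seed
    scenarios = list(scenarios if scenarios is not None else config.scenarios)
    if not any(s.redirect_fraction == 0 for s in scenarios):
        scenarios.insert(0, BASELINE)

    if state is None:
        history = CensusSeries(history.facility_id, history.start,
                               history.interval_minutes, np.array(history.values))
        profile = estimate_profile(history, exp.threshold_quantile)
        state = LoopState(history=history, profile=profile)
    history = state.history
    ed_id = config.network.ed.facility_id

    if isinstance(stream, Sequence) and (not stream or isinstance(stream[0], RealTimeSnapshot)):
        batches = replay_stream(stream)
    else:
        batches = stream
    interval = timedelta(minutes=history.interval_minutes)

    ticks: List[LoopTick] = []
    for batch in batches:
        if max_ticks is not None and len(ticks) >= max_ticks:
            break
        k = state.next_tick
        state.next_tick += 1
        tick_time = batch[0].timestamp
        ed_snap = next((s for s in batch if s.facility_id == ed_id), None)
        if ed_snap is None:
            logger.warning("tick %d: no ED snapshot in batch; skipped", k)
            ticks.append(LoopTick(k, tick_time, list(batch), skipped=True))
            continue

        expected = history.start + len(history) * interval
        gap = (tick_time - expected) / interval
        if gap > 0:
            gap_minutes = gap * history.interval_minutes
            pad = int(round(gap))
            last = int(history.values[-1])
            for _ in range(pad):
                history.extend(last)
            if gap_minutes > exp.stream_gap_tolerance_minutes:
                logger.warning("tick %d: stream gap of %.0f min exceeds tolerance; tick skipped",
                               k, gap_minutes)
                history.extend(ed_snap.census)
                ticks.append(LoopTick(k, tick_time, list(batch), skipped=True))
                continue
        history.extend(ed_snap.census)

        try:
            forecast = fit_forecast(history, horizon_steps=exp.horizon_steps,
                                    method=exp.forecast_method, level=exp.interval_level)
        except ValidationError as exc:
            logger.warning("tick %d: forecast unavailable (%s); tick skipped", k, exc)
            ticks.append(LoopTick(k, tick_time, list(batch), skipped=True))
            continue

        in_cooldown = state.cooldown_until is not None and tick_time < state.cooldown_until
        event = None if in_cooldown else detect(forecast, state.profile)

        scenario_results = None
        recommendation = None
        if event is not None:
            targets = {s.facility_id: s for s in batch}
            tick_seed = int(np.random.SeedSequence([seed & 0x7FFFFFFF, k]).generate_state(1)[0] & 0x7FFFFFFF)
            init = warmup_then_align(config.network, config.pathway, config.arrivals,
                                     exp.warmup_hours, targets, seed=tick_seed,
                                     start=tick_time)
            scenario_results = run_scenarios(
                config.network, config.arrivals, config.pathway, scenarios,
                replications=exp.replications, base_seed=tick_seed,
                run_minutes=exp.recovery_window_minutes, init=init, start=tick_time,
                record_interval_minutes=exp.update_interval_minutes,
                recovery_window_minutes=exp.recovery_window_minutes,
                ci_level=exp.interval_level)
            recommendation = make_recommendation(tick_time, scenario_results,
                                                 ci_level=exp.interval_level)
            state.cooldown_until = tick_time + timedelta(minutes=exp.recovery_window_minutes)

        tick = LoopTick(k, tick_time, list(batch), skipped=False, forecast=forecast,
                        trigger_event=event, scenario_results=scenario_results,
                        recommendation=recommendation)
        ticks.append(tick)
        if out_dir is not None and recommendation is not None:
            _write_recommendation(Path(out_dir), k, recommendation)

    if out_dir is not None:
        _write_ticks(Path(out_dir), ticks)
    return ticks, state


def make_recommendation(tick_time: datetime,
                        results: Dict[str, ScenarioSummary],
                        ci_level: float = 0.95,
                        baseline_name: str = "baseline") -> Recommendation:
    """Rank scenarios: lowest mean ED census over the recovery window wins.

    Ties (within 1e-9) break on higher 4-hour performance.  Deltas
    against baseline are paired over common-random-number replications,
    with t-distribution confidence intervals.
    """
    from scipy import stats

    if baseline_name not in results:
        raise ValidationError(f"baseline scenario {baseline_name!r} missing from results")
    ranking = sorted(
        results,
        key=lambda n: (round(results[n].kpi_mean[RANK_KPI], 9),
                       -results[n].kpi_mean.get(TIE_KPI, 0.0)),
    )
    base = results[baseline_name].per_rep
    deltas: Dict[str, Dict[str, Tuple[float, float, float]]] = {}
    for name, summary in results.items():
        if name == baseline_name:
            continue
        d: Dict[str, Tuple[float, float, float]] = {}
        for kpi in summary.per_rep.columns:
            diff = (summary.per_rep[kpi] - base[kpi]).astype(float).dropna()
            if len(diff) == 0:
                continue
            m = float(diff.mean())
            if len(diff) < 2 or diff.std(ddof=1) == 0:
                d[kpi] = (m, m, m)
            else:
                half = float(stats.t.ppf(0.5 + ci_level / 2, len(diff) - 1)
                             * diff.std(ddof=1) / math.sqrt(len(diff)))
                d[kpi] = (m, m - half, m + half)
        deltas[name] = d
    return Recommendation(
        tick_time=tick_time, ranking=ranking, chosen=ranking[0],
        kpi_table={n: dict(s.kpi_mean) for n, s in results.items()},
        deltas_vs_baseline=deltas,
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def _json_default(obj):
    if isinstance(obj, datetime):
        return obj.isoformat()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialise {type(obj)}")


def tick_to_dict(tick: LoopTick) -> dict:
    d = {
        "tick_index": tick.tick_index,
        "tick_time": tick.tick_time.isoformat(),
        "skipped": tick.skipped,
        "snapshots": [
            {"timestamp": s.timestamp.isoformat(), "facility_id": s.facility_id,
             "census": s.census, "waiting": s.waiting,
             "max_wait_minutes": s.max_wait_minutes}
            for s in tick.snapshots
        ],
        "forecast": None,
        "trigger": None,
        "recommendation": None,
    }
    if tick.forecast is not None:
        f = tick.forecast
        d["forecast"] = {
            "issued_at": f.issued_at.isoformat(),
            "timestamps": [t.isoformat() for t in f.timestamps],
            "point": [float(x) for x in f.point],
            "lower": [float(x) for x in f.lower],
            "upper": [float(x) for x in f.upper],
            "level": f.level, "model_tag": f.model_tag,
        }
    if tick.trigger_event is not None:
        e = tick.trigger_event
        d["trigger"] = {
            "detected_at": e.detected_at.isoformat(),
            "first_breach_step": e.first_breach_step,
            "breach_time": e.breach_time.isoformat(),
            "forecast_value": e.forecast_value,
            "threshold_value": e.threshold_value,
        }
    if tick.recommendation is not None:
        r = tick.recommendation
        d["recommendation"] = {
            "tick_time": r.tick_time.isoformat(), "ranking": r.ranking,
            "chosen": r.chosen, "kpi_table": r.kpi_table,
            "deltas_vs_baseline": r.deltas_vs_baseline,
        }
    return d


def _write_ticks(out_dir: Path, ticks: List[LoopTick]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "ticks.jsonl", "w", encoding="utf-8") as fh:
        for tick in ticks:
            fh.write(json.dumps(tick_to_dict(tick), sort_keys=True, default=_json_default))
            fh.write("\n")


def _write_recommendation(out_dir: Path, tick_index: int, rec: Recommendation) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "tick_time": rec.tick_time.isoformat(), "ranking": rec.ranking,
        "chosen": rec.chosen, "kpi_table": rec.kpi_table,
        "deltas_vs_baseline": rec.deltas_vs_baseline,
    }
    with open(out_dir / f"recommendation_{tick_index:04d}.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2, default=_json_default)


# ---------------------------------------------------------------------------
# Synthetic end-to-end validation
# ---------------------------------------------------------------------------

def end_to_end_validation(
    network,
    profile,
    pathway,
    seed: int = 0,
    days: int = 7,
    replications: int = 30,
    refit_rate_multiplier: float = 1.0,
    warmup_days: int = 1,
    start: datetime = datetime(2025, 1, 6),
) -> dict:
    """Validate the model against a synthetic ground truth.

    Generates arrivals from a known profile and runs the model once to
    produce a "historical" hour-of-day mean census/waiting profile (the
    stand-in for real feed data).  The model is then refit from the
    profile alone (optionally with deliberately perturbed rates) and run
    for ``replications`` independent streams; the report gives the mean
    absolute deviation of the replicated trajectories from ground truth,
    the 95% replication band coverage per hour of day, and a sign-based
    systematic-bias flag.  The first ``warmup_days`` are excluded from
    all hourly means.
    """
    ed_id = network.ed.facility_id
    run_minutes = days * 24 * 60.0

    def hourly_means(res) -> Tuple[np.ndarray, np.ndarray]:
        frame = res.facility_series[ed_id]
        sub = frame[frame["time"] >= warmup_days * 24 * 60.0]
        hours = ((sub["time"] // 60) % 24).astype(int)
        census = sub.groupby(hours)["census"].mean().reindex(range(24)).to_numpy(dtype=float)
        waiting = sub.groupby(hours)["waiting"].mean().reindex(range(24)).to_numpy(dtype=float)
        return census, waiting

    truth_arr = sample_nhpp_arrivals(profile, start, days,
                                     seed=np.random.SeedSequence([seed & 0x7FFFFFFF, 0]),
                                     facility_id=ed_id)
    truth = run_replication(network, truth_arr, pathway, run_minutes=run_minutes,
                            seed=int(np.random.SeedSequence([seed & 0x7FFFFFFF, 1])
                                     .generate_state(1)[0] & 0x7FFFFFFF),
                            start=start)
    truth_census, truth_waiting = hourly_means(truth)

    rep_census = np.zeros((replications, 24))
    rep_waiting = np.zeros((replications, 24))
    for r in range(replications):
        arr = sample_nhpp_arrivals(profile, start, days,
                                   seed=np.random.SeedSequence([seed & 0x7FFFFFFF, 100 + r]),
                                   facility_id=ed_id,
                                   rate_multiplier=refit_rate_multiplier)
        res = run_replication(network, arr, pathway, run_minutes=run_minutes,
                              seed=int(np.random.SeedSequence([seed & 0x7FFFFFFF, 1000 + r])
                                       .generate_state(1)[0] & 0x7FFFFFFF),
                              start=start)
        rep_census[r], rep_waiting[r] = hourly_means(res)

    # 95% prediction band for a new replication: the ground-truth run is one
    # more draw of the same statistic, so a t prediction interval is the
    # right yardstick (a plain percentile band of R runs under-covers).
    from scipy import stats as _st

    m = rep_census.mean(axis=0)
    s = rep_census.std(axis=0, ddof=1)
    half = _st.t.ppf(0.975, replications - 1) * s * math.sqrt(1.0 + 1.0 / replications)
    lo = m - half
    hi = m + half
    covered = (truth_census >= lo) & (truth_census <= hi)
    dev = rep_census.mean(axis=0) - truth_census
    dev_wait = rep_waiting.mean(axis=0) - truth_waiting
    n_pos = int((dev > 0).sum())
    systematic = "positive" if n_pos >= 20 else ("negative" if n_pos <= 4 else "none")

    return {
        "hours": list(range(24)),
        "truth_census": truth_census.tolist(),
        "truth_waiting": truth_waiting.tolist(),
        "rep_mean_census": rep_census.mean(axis=0).tolist(),
        "rep_mean_waiting": rep_waiting.mean(axis=0).tolist(),
        "band_low": lo.tolist(),
        "band_high": hi.tolist(),
        "coverage": float(covered.mean()),
        "mad_census": float(np.abs(dev).mean()),
        "mad_waiting": float(np.abs(dev_wait).mean()),
        "mean_bias_census": float(dev.mean()),
        "hours_positive_bias": n_pos,
        "systematic_bias": systematic,
        "replications": replications,
        "days": days,
        "refit_rate_multiplier": refit_rate_multiplier,
    }
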