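"""Synthetic real-time data feed for the urgent-care network.

The live platform that supplied census, waiting-count and maximum-wait
snapshots in the original deployment is not publicly available, so this
module generates statistically controlled stand-ins with known ground
truth: event-level arrival logs from a non-homogeneous Poisson process,
historical 30-minute census series with daily/weekly seasonality, and a
replayable snapshot stream that emulates a live feed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Iterator, List, Optional, Sequence

import numpy as np

from .config import ArrivalProfile, ValidationError

logger = logging.getLogger(__name__)

#: Default stream/series cadence in minutes, matching the update loop.
DEFAULT_INTERVAL = 30


@dataclass(frozen=True)
class ArrivalRecord:
    """One patient arrival: when, where, how urgent, and by what mode."""

    timestamp: datetime
    facility_id: str
    patient_id: str
    acuity: int
    mode: str  # "walkin" | "ambulance"
    t_minutes: float  # offset from the generation start, simulation clock

    def __post_init__(self):
        if self.acuity not in (1, 2, 3, 4, 5):
            raise ValidationError(f"acuity must be 1..5, got {self.acuity}")
        if self.mode not in ("walkin", "ambulance"):
            raise ValidationError(f"mode must be walkin|ambulance, got {self.mode!r}")


@dataclass(frozen=True)
class RealTimeSnapshot:
    """One facility's live state: census, waiting count, maximum wait."""

    timestamp: datetime
    facility_id: str
    census: int
    waiting: int
    max_wait_minutes: float

    def __post_init__(self):
        if self.census < 0 or self.waiting < 0 or self.max_wait_minutes < 0:
            raise ValidationError("snapshot fields must be nonnegative")
        if self.waiting > self.census:
            raise ValidationError(
                f"waiting ({self.waiting}) cannot exceed census ({self.census})"
            )
        if (self.waiting == 0) != (self.max_wait_minutes == 0):
            raise ValidationError("max_wait_minutes must be 0 exactly when waiting is 0")


@dataclass
class CensusSeries:
    """Equally spaced patients-in-department counts for one facility."""

    facility_id: str
    start: datetime
    interval_minutes: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.interval_minutes <= 0:
            raise ValidationError("interval_minutes must be positive")
        if np.any(self.values < 0):
            raise ValidationError("census values must be nonnegative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def slots_per_day(self) -> int:
        return 24 * 60 // self.interval_minutes

    def timestamps(self) -> List[datetime]:
        step = timedelta(minutes=self.interval_minutes)
        return [self.start + i * step for i in range(len(self.values))]

    def extend(self, value: int) -> None:
        self.values = np.append(self.values, int(value))

    def tail(self, n: int) -> "CensusSeries":
        n = min(n, len(self.values))
        start = self.start + timedelta(minutes=(len(self.values) - n) * self.interval_minutes)
        return CensusSeries(self.facility_id, start, self.interval_minutes, self.values[-n:])


# ---------------------------------------------------------------------------
# Arrival process
# ---------------------------------------------------------------------------

def sample_nhpp_arrivals(
    profile: ArrivalProfile,
    start: datetime,
    days: int,
    seed,
    facility_id: str = "ED1",
    rate_multiplier: float = 1.0,
) -> List[ArrivalRecord]:
    """Sample arrivals from a non-homogeneous Poisson process by thinning.

    The rate is piecewise constant: ``lambda(t) = hourly_rates[hour(t)] *
    dow_factors[weekday(t)] * rate_multiplier``.  Candidate points are
    drawn at the maximal rate and accepted with probability
    ``lambda(t)/lambda_max``, which is exact for this rate structure.
    Acuity and arrival mode are then drawn from the profile mixes;
    ambulance arrivals occur only at the ED.  Reproducible given seed.
    """
    if days < 1:
        raise ValidationError(f"days must be >= 1, got {days}")
    rng = np.random.default_rng(seed)
    lam_max = profile.max_rate * rate_multiplier / 60.0  # per minute
    horizon = days * 24 * 60.0
    if lam_max <= 0:
        return []

    # candidate homogeneous process at lam_max
    n_expect = lam_max * horizon
    times: List[float] = []
    t = 0.0
    chunk = max(64, int(n_expect * 1.1))
    while t < horizon:
        gaps = rng.exponential(1.0 / lam_max, size=chunk)
        us = rng.random(size=chunk)
        for g, u in zip(gaps, us):
            t += g
            if t >= horizon:
                break
            ts = start + timedelta(minutes=t)
            lam_t = profile.rate_at(ts.hour, ts.weekday()) * rate_multiplier / 60.0
            if u < lam_t / lam_max:
                times.append(t)
        chunk = 4096

    n = len(times)
    is_amb = rng.random(n) < profile.ambulance_fraction
    acu_w = rng.choice(np.arange(1, 6), size=n, p=profile.acuity_mix_walkin)
    acu_a = rng.choice(np.arange(1, 6), size=n, p=profile.acuity_mix_ambulance)
    records = []
    for i, tm in enumerate(times):
        mode = "ambulance" if is_amb[i] else "walkin"
        acuity = int(acu_a[i] if is_amb[i] else acu_w[i])
        records.append(
            ArrivalRecord(
                timestamp=start + timedelta(minutes=tm),
                facility_id=facility_id,
                patient_id=f"P{i:06d}",
                acuity=acuity,
                mode=mode,
                t_minutes=tm,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Historical census generator
# ---------------------------------------------------------------------------

#: Additive day-of-week shape (Mon..Sun), zero-mean, scaled by dow_amplitude.
DOW_SHAPE = np.array([1.0, 0.2, -0.4, -0.6, -0.4, 0.0, 0.2])
DOW_SHAPE = DOW_SHAPE - DOW_SHAPE.mean()


def daily_shape(slot_frac: np.ndarray) -> np.ndarray:
    """Smooth daily census shape on [0,1): trough ~05:00, peak ~17:00."""
    return np.sin(2.0 * np.pi * (slot_frac - 11.0 / 24.0))


def synth_census_series(
    days: int,
    interval_minutes: int = DEFAULT_INTERVAL,
    base: float = 20.0,
    amplitude: float = 10.0,
    dow_amplitude: float = 2.0,
    noise_scale: float = 2.0,
    ar_coeff: float = 0.7,
    seed=0,
    start: Optional[datetime] = None,
    facility_id: str = "ED1",
) -> CensusSeries:
    """Generate a seasonal census series with AR(1) noise.

    ``values[i] = round(max(0, base + amplitude * s(slot-of-day)
    + dow_amplitude * d(weekday) + x_i))`` where ``s`` is a sinusoid
    peaking in the late afternoon, ``d`` is a fixed zero-mean weekday
    shape (Monday-heavy) and ``x`` is AR(1):
    ``x_i = ar_coeff * x_{i-1} + eps_i``, ``eps ~ N(0, noise_scale^2)``.
    """
    if days < 1:
        raise ValidationError(f"days must be >= 1, got {days}")
    if noise_scale < 0:
        raise ValidationError(f"noise_scale must be nonnegative, got {noise_scale}")
    if not (base >= amplitude >= 0):
        raise ValidationError(f"need base >= amplitude >= 0, got base={base}, amplitude={amplitude}")
    if start is None:
        start = datetime(2025, 1, 6)  # a Monday
    rng = np.random.default_rng(seed)
    spd = 24 * 60 // interval_minutes
    n = days * spd
    idx = np.arange(n)
    slot_frac = (idx % spd) / spd
    weekday = ((idx // spd) + start.weekday()) % 7
    signal = base + amplitude * daily_shape(slot_frac) + dow_amplitude * DOW_SHAPE[weekday]
    noise = np.zeros(n)
    if noise_scale > 0:
        eps = rng.normal(0.0, noise_scale, size=n)
        x = 0.0
        for i in range(n):
            x = ar_coeff * x + eps[i]
            noise[i] = x
    values = np.round(np.maximum(0.0, signal + noise)).astype(int)
    return CensusSeries(facility_id, start, interval_minutes, values)


# ---------------------------------------------------------------------------
# Snapshots
# ---------------------------------------------------------------------------

def snapshots_from_simulation(result, interval_minutes: int = DEFAULT_INTERVAL) -> List[RealTimeSnapshot]:
    """Read one snapshot per facility per interval boundary from a run.

    ``result`` is a :class:`urgentsim.des.SimulationResult` whose state
    trajectories were recorded at (a divisor of) the requested cadence.
    """
    snaps: List[RealTimeSnapshot] = []
    for fid, frame in result.facility_series.items():
        rec_interval = result.record_interval_minutes
        if interval_minutes % rec_interval != 0:
            raise ValidationError(
                f"requested cadence {interval_minutes} is not a multiple of the "
                f"recorded cadence {rec_interval}"
            )
        stride = interval_minutes // rec_interval
        sub = frame.iloc[::stride]
        for _, row in sub.iterrows():
            snaps.append(
                RealTimeSnapshot(
                    timestamp=result.start + timedelta(minutes=float(row["time"])),
                    facility_id=fid,
                    census=int(row["census"]),
                    waiting=int(row["waiting"]),
                    max_wait_minutes=float(row["max_wait"]),
                )
            )
    snaps.sort(key=lambda s: (s.timestamp, s.facility_id))
    return snaps


def replay_stream(
    snapshots: Sequence[RealTimeSnapshot],
    from_ts: Optional[datetime] = None,
) -> Iterator[List[RealTimeSnapshot]]:
    """Yield snapshot batches in timestamp order, one batch per instant.

    Emulates a live feed: each yielded batch holds every facility's
    snapshot for one update instant.  Input must be sorted by timestamp.
    """
    ts = [s.timestamp for s in snapshots]
    if any(a > b for a, b in zip(ts, ts[1:])):
        raise ValidationError("snapshots must be sorted by timestamp")
    batch: List[RealTimeSnapshot] = []
    for s in snapshots:
        if from_ts is not None and s.timestamp < from_ts:
            continue
        if batch and s.timestamp != batch[-1].timestamp:
            yield batch
            batch = []
        batch.append(s)
    if batch:
        yield batch


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

CENSUS_COLUMNS = ["timestamp", "facility_id", "census", "waiting", "max_wait_minutes"]
ARRIVAL_COLUMNS = ["timestamp", "facility_id", "patient_id", "acuity", "mode"]
_TS_FMT = "%Y-%m-%dT%H:%M:%S"


def write_census_csv(series: CensusSeries, path) -> None:
    """Write a census series in the documented 5-column snapshot schema.

    Waiting and max-wait columns are left blank when the series carries
    census only; :func:`read_census_csv` round-trips it bit-exactly.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CENSUS_COLUMNS)
        for ts, v in zip(series.timestamps(), series.values):
            w.writerow([ts.strftime(_TS_FMT), series.facility_id, int(v), "", ""])


def write_snapshots_csv(snapshots: Iterable[RealTimeSnapshot], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CENSUS_COLUMNS)
        for s in snapshots:
            w.writerow(
                [s.timestamp.strftime(_TS_FMT), s.facility_id, s.census, s.waiting,
                 format(s.max_wait_minutes, "g")]
            )


def read_snapshots_csv(path) -> List[RealTimeSnapshot]:
    rows = _read_rows(path)
    snaps = []
    for row in rows:
        snaps.append(
            RealTimeSnapshot(
                timestamp=datetime.strptime(row["timestamp"], _TS_FMT),
                facility_id=row["facility_id"],
                census=int(row["census"]),
                waiting=int(row["waiting"] or 0),
                max_wait_minutes=float(row["max_wait_minutes"] or 0.0),
            )
        )
    return snaps


def read_census_csv(path, facility_id: Optional[str] = None) -> CensusSeries:
    """Read a census series; interpolate single gaps, reject longer runs.

    A missing slot (absent timestamp or blank census) is filled by linear
    interpolation when isolated (runs of at most 2 slots), with a logged
    warning; longer runs raise, since forecasting needs a complete
    series.
    """
    rows = _read_rows(path)
    if facility_id is not None:
        rows = [r for r in rows if r["facility_id"] == facility_id]
    if not rows:
        raise ValidationError(f"no census rows found in {path}"
                              + (f" for facility {facility_id!r}" if facility_id else ""))
    fid = rows[0]["facility_id"]
    if any(r["facility_id"] != fid for r in rows):
        raise ValidationError("multiple facilities in file; pass facility_id to select one")
    parsed = []
    for r in rows:
        ts = datetime.strptime(r["timestamp"], _TS_FMT)
        val = r["census"].strip()
        parsed.append((ts, int(val) if val else None))
    parsed.sort(key=lambda x: x[0])
    if len(parsed) < 2:
        raise ValidationError("census series needs at least 2 rows")
    interval = int((parsed[1][0] - parsed[0][0]).total_seconds() // 60)
    if interval <= 0:
        raise ValidationError("duplicate or non-increasing timestamps")
    start, end = parsed[0][0], parsed[-1][0]
    n = int((end - start).total_seconds() // 60) // interval + 1
    grid: List[Optional[float]] = [None] * n
    for ts, val in parsed:
        off = (ts - start).total_seconds() / 60.0
        slot = off / interval
        if abs(slot - round(slot)) > 1e-9:
            raise ValidationError(f"timestamp {ts} is off the {interval}-minute grid")
        grid[int(round(slot))] = val
    values = _fill_gaps(grid, path)
    return CensusSeries(fid, start, interval, np.asarray(values))


def _fill_gaps(grid: List[Optional[float]], path) -> List[int]:
    if grid[0] is None or grid[-1] is None:
        raise ValidationError("census series cannot start or end with a gap")
    values: List[int] = []
    i = 0
    n = len(grid)
    while i < n:
        if grid[i] is not None:
            values.append(int(grid[i]))
            i += 1
            continue
        j = i
        while grid[j] is None:
            j += 1
        run = j - i
        if run > 2:
            raise ValidationError(f"gap of {run} consecutive slots in {path}; cleaning handles runs <= 2")
        logger.warning("census gap of %d slot(s) at index %d in %s: linear interpolation", run, i, path)
        lo, hi = float(values[-1]), float(grid[j])
        for k in range(1, run + 1):
            values.append(int(round(lo + (hi - lo) * k / (run + 1))))
        i = j
    return values


def _read_rows(path) -> List[dict]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, expected header {CENSUS_COLUMNS}")
        missing = {"timestamp", "facility_id", "census"} - set(reader.fieldnames)
        if missing:
            raise ValidationError(f"{path}: malformed header, missing column(s) {sorted(missing)}")
        return list(reader)


def write_arrivals_csv(arrivals: Iterable[ArrivalRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ARRIVAL_COLUMNS)
        for a in arrivals:
            w.writerow([a.timestamp.strftime(_TS_FMT), a.facility_id, a.patient_id, a.acuity, a.mode])


def read_arrivals_csv(path, start: Optional[datetime] = None) -> List[ArrivalRecord]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(ARRIVAL_COLUMNS) - set(reader.fieldnames):
            raise ValidationError(f"{path}: malformed header, expected {ARRIVAL_COLUMNS}")
        rows = list(reader)
    records = []
    for r in rows:
        ts = datetime.strptime(r["timestamp"], _TS_FMT)
        if start is None:
            start = ts
        records.append(
            ArrivalRecord(
                timestamp=ts,
                facility_id=r["facility_id"],
                patient_id=r["patient_id"],
                acuity=int(r["acuity"]),
                mode=r["mode"],
                t_minutes=(ts - start).total_seconds() / 60.0,
            )
        )
    return records
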