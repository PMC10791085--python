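"""Domain types, invariants, and configuration loading for the urgent-care network.

The network is one emergency department (ED) modelled in detail plus a
small number of minor treatment centres (MTCs) that can absorb
redirected low-acuity walk-ins (triage categories 4-5).  None of the
default numbers below come from a published dataset: the real service
parameters of the case-study system were never released, so the
defaults are documented synthetic placeholders chosen to give a
plausible mid-size ED.  Every one of them can be overridden from the
YAML config file (see README for the key-by-key schema).
"""

from __future__ import annotations

import math
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

ACUITIES = (1, 2, 3, 4, 5)

DispositionKind = Literal["discharge", "admit", "cdu"]


class ValidationError(ValueError):
    """Raised when a configuration or domain invariant is violated."""


class ServiceTime(BaseModel):
    """Duration distribution for one activity, parameterised by mean (minutes).

    ``lognormal`` uses (mean, cv); ``exponential`` uses mean; ``fixed`` is
    degenerate at the mean.  All three yield nonnegative durations.
    """

    model_config = ConfigDict(frozen=True)

    dist: Literal["lognormal", "exponential", "fixed"] = "lognormal"
    mean: float = Field(ge=0.0)
    cv: float = Field(default=0.5, ge=0.0)


class FacilitySpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    facility_id: str = Field(min_length=1, max_length=32)
    kind: Literal["ED", "MTC"]
    servers: Dict[str, int]
    hours: Tuple[float, float] = (0.0, 24.0)  # open interval, hour-of-day
    accepts_categories: frozenset = frozenset(ACUITIES)

    @field_validator("servers")
    @classmethod
    def _servers_positive(cls, v: Dict[str, int]) -> Dict[str, int]:
        for name, count in v.items():
            if count < 1:
                raise ValueError(f"server count for {name!r} must be >= 1, got {count}")
        return v

    @field_validator("accepts_categories", mode="before")
    @classmethod
    def _coerce_set(cls, v):
        return frozenset(int(x) for x in v)

    @model_validator(mode="after")
    def _check_kind(self) -> "FacilitySpec":
        if not self.accepts_categories <= set(ACUITIES):
            raise ValueError(f"accepts_categories must be within {set(ACUITIES)}")
        if self.kind == "MTC" and not self.accepts_categories <= {4, 5}:
            raise ValueError(
                f"MTC {self.facility_id!r}: accepts_categories must be a subset of "
                f"{{4, 5}}, got {sorted(self.accepts_categories)}"
            )
        if self.kind == "ED":
            missing = {"triage_nurses", "doctors", "cubicles"} - set(self.servers)
            if missing:
                raise ValueError(f"ED requires servers {sorted(missing)}")
        if self.kind == "MTC" and "clinicians" not in self.servers:
            raise ValueError(f"MTC {self.facility_id!r} requires a 'clinicians' server pool")
        lo, hi = self.hours
        if not (0 <= lo < hi <= 24):
            raise ValueError(f"hours must satisfy 0 <= open < close <= 24, got {self.hours}")
        return self

    def is_open(self, hour_of_day: float) -> bool:
        lo, hi = self.hours
        return lo <= hour_of_day % 24.0 < hi


class NetworkSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    facilities: List[FacilitySpec]
    travel_delay_minutes: float = Field(default=20.0, ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "NetworkSpec":
        ids = [f.facility_id for f in self.facilities]
        if len(set(ids)) != len(ids):
            raise ValueError(f"facility_ids must be unique, got {ids}")
        n_ed = sum(1 for f in self.facilities if f.kind == "ED")
        if n_ed != 1:
            raise ValueError(f"network must contain exactly one ED, got {n_ed}")
        return self

    @property
    def ed(self) -> FacilitySpec:
        return next(f for f in self.facilities if f.kind == "ED")

    @property
    def mtcs(self) -> List[FacilitySpec]:
        return [f for f in self.facilities if f.kind == "MTC"]

    def facility(self, facility_id: str) -> FacilitySpec:
        for f in self.facilities:
            if f.facility_id == facility_id:
                return f
        raise KeyError(facility_id)


def _check_prob_vector(name: str, v: Sequence[float], length: int) -> List[float]:
    vals = [float(x) for x in v]
    if len(vals) != length:
        raise ValueError(f"{name} must have {length} entries, got {len(vals)}")
    if any(x < 0 or x > 1 for x in vals):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if abs(sum(vals) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 +/- 1e-9, got {sum(vals)!r}")
    return vals


class ArrivalProfile(BaseModel):
    """Non-homogeneous walk-in/ambulance arrival process for the ED.

    Rate at time t is ``hourly_rates[hour(t)] * dow_factors[weekday(t)]``
    (week starts Monday).  Acuity is drawn from mode-specific mixes over
    triage categories 1 (most urgent) to 5.
    """

    model_config = ConfigDict(frozen=True)

    hourly_rates: List[float]
    dow_factors: List[float] = Field(default_factory=lambda: [1.0] * 7)
    ambulance_fraction: float = Field(default=0.25, ge=0.0, le=1.0)
    acuity_mix_walkin: List[float]
    acuity_mix_ambulance: List[float]

    @field_validator("hourly_rates")
    @classmethod
    def _rates(cls, v: List[float]) -> List[float]:
        if len(v) != 24:
            raise ValueError(f"hourly_rates must have 24 entries, got {len(v)}")
        if any((not math.isfinite(x)) or x < 0 for x in v):
            raise ValueError("hourly_rates must be finite and nonnegative")
        return [float(x) for x in v]

    @field_validator("dow_factors")
    @classmethod
    def _dow(cls, v: List[float]) -> List[float]:
        if len(v) != 7:
            raise ValueError(f"dow_factors must have 7 entries, got {len(v)}")
        if any((not math.isfinite(x)) or x <= 0 for x in v):
            raise ValueError("dow_factors must be finite and positive")
        return [float(x) for x in v]

    @field_validator("acuity_mix_walkin")
    @classmethod
    def _mix_w(cls, v):
        return _check_prob_vector("acuity_mix_walkin", v, 5)

    @field_validator("acuity_mix_ambulance")
    @classmethod
    def _mix_a(cls, v):
        return _check_prob_vector("acuity_mix_ambulance", v, 5)

    def rate_at(self, hour_of_day: int, weekday: int) -> float:
        return self.hourly_rates[hour_of_day] * self.dow_factors[weekday]

    @property
    def max_rate(self) -> float:
        return max(self.hourly_rates) * max(self.dow_factors)


class PathwaySpec(BaseModel):
    """Branch probabilities and activity durations of the ED pathway.

    The pathway is: triage -> assessment -> optional investigation (Ix)
    -> optional treatment (Rx) -> optional one extra Ix/Rx cycle ->
    disposition in {discharge, admit, cdu}.  Admitted patients incur a
    downstream boarding delay (awaiting a ward bed) which by default
    keeps their cubicle occupied (exit block); entry to the clinical
    decision unit (CDU) stops the waiting-time clock.
    """

    model_config = ConfigDict(frozen=True)

    p_investigation: List[float]  # indexed by acuity-1
    p_treatment: List[float]
    p_second_cycle: float = Field(default=0.15, ge=0.0, le=1.0)
    disposition_probs: List[List[float]]  # rows by acuity: [discharge, admit, cdu]
    service_times: Dict[str, ServiceTime]
    boarding_holds_cubicle: bool = True

    _REQUIRED_ACTIVITIES = (
        "triage",
        "assessment",
        "investigation",
        "treatment",
        "cdu_stay",
        "boarding",
        "mtc_treatment",
    )

    @field_validator("p_investigation", "p_treatment")
    @classmethod
    def _probs5(cls, v):
        vals = [float(x) for x in v]
        if len(vals) != 5 or any(x < 0 or x > 1 for x in vals):
            raise ValueError("per-acuity probabilities must be 5 values in [0, 1]")
        return vals

    @field_validator("disposition_probs")
    @classmethod
    def _disp(cls, v):
        if len(v) != 5:
            raise ValueError(f"disposition_probs must have 5 rows, got {len(v)}")
        return [_check_prob_vector(f"disposition_probs[{i}]", row, 3) for i, row in enumerate(v)]

    @model_validator(mode="after")
    def _activities(self) -> "PathwaySpec":
        missing = set(self._REQUIRED_ACTIVITIES) - set(self.service_times)
        if missing:
            raise ValueError(f"service_times missing activities {sorted(missing)}")
        return self


class Scenario(BaseModel):
    """A demand-redirection policy to evaluate against baseline.

    Eligible patients (default: triage category 4/5 walk-ins) are, with
    probability ``redirect_fraction``, sent at arrival to an MTC chosen
    by routing weight, incurring the network travel delay.
    """

    model_config = ConfigDict(frozen=True)

    name: str = Field(min_length=1)
    redirect_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    eligible_categories: frozenset = frozenset({4, 5})
    eligible_modes: frozenset = frozenset({"walkin"})
    targets: Dict[str, float] = Field(default_factory=dict)

    @field_validator("eligible_categories", mode="before")
    @classmethod
    def _cats(cls, v):
        return frozenset(int(x) for x in v)

    @field_validator("eligible_modes", mode="before")
    @classmethod
    def _modes(cls, v):
        modes = frozenset(str(x) for x in v)
        if not modes <= {"walkin", "ambulance"}:
            raise ValueError(f"eligible_modes must be within {{walkin, ambulance}}, got {sorted(modes)}")
        return modes

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        if self.targets:
            total = sum(self.targets.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"scenario {self.name!r}: target weights must sum to 1, got {total!r}")
            if any(w < 0 for w in self.targets.values()):
                raise ValueError(f"scenario {self.name!r}: target weights must be nonnegative")
        if self.redirect_fraction > 0 and not self.targets:
            raise ValueError(f"scenario {self.name!r}: redirect_fraction > 0 requires targets")
        return self


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    update_interval_minutes: int = Field(default=30, gt=0)
    forecast_horizon_minutes: int = Field(default=240, gt=0)
    warmup_hours: float = Field(default=24.0, ge=0.0)
    replications: int = Field(default=50, ge=1)
    seed: int = 0
    threshold_quantile: float = Field(default=0.85, gt=0.0, lt=1.0)
    recovery_window_minutes: float = Field(default=480.0, gt=0.0)
    forecast_method: Literal["seasonal_naive", "sarima"] = "seasonal_naive"
    interval_level: float = Field(default=0.95, gt=0.0, lt=1.0)
    stream_gap_tolerance_minutes: float = Field(default=90.0, gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "ExperimentConfig":
        if self.forecast_horizon_minutes % self.update_interval_minutes != 0:
            raise ValueError(
                "forecast_horizon_minutes must be a multiple of update_interval_minutes "
                f"({self.forecast_horizon_minutes} % {self.update_interval_minutes} != 0)"
            )
        return self

    @property
    def horizon_steps(self) -> int:
        return self.forecast_horizon_minutes // self.update_interval_minutes


class FullConfig(BaseModel):
    """Bundle returned by :func:`load_config`; records defaulted fields."""

    model_config = ConfigDict(frozen=True)

    experiment: ExperimentConfig
    network: NetworkSpec
    arrivals: ArrivalProfile
    pathway: PathwaySpec
    scenarios: List[Scenario] = Field(default_factory=list)
    defaulted_fields: List[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "FullConfig":
        known = {f.facility_id for f in self.network.facilities}
        mtc_ids = {f.facility_id for f in self.network.mtcs}
        for sc in self.scenarios:
            bad = set(sc.targets) - mtc_ids
            if bad:
                raise ValueError(f"scenario {sc.name!r}: targets reference non-MTC facilities {sorted(bad)}")
            if sc.redirect_fraction > 0 and not mtc_ids & known:
                raise ValueError("redirection scenarios require at least one MTC in the network")
        return self


# ---------------------------------------------------------------------------
# Defaults.  All values are synthetic and documented; the source system's
# real parameters were never published.
# ---------------------------------------------------------------------------

def default_network() -> NetworkSpec:
    """One 24-hour ED plus three daytime minor treatment centres."""
    return NetworkSpec(
        facilities=[
            FacilitySpec(
                facility_id="ED1",
                kind="ED",
                servers={"triage_nurses": 3, "doctors": 8, "cubicles": 20},
                hours=(0.0, 24.0),
                accepts_categories=frozenset(ACUITIES),
            ),
            FacilitySpec(
                facility_id="MTC1",
                kind="MTC",
                servers={"clinicians": 2},
                hours=(8.0, 20.0),
                accepts_categories=frozenset({4, 5}),
            ),
            FacilitySpec(
                facility_id="MTC2",
                kind="MTC",
                servers={"clinicians": 2},
                hours=(8.0, 20.0),
                accepts_categories=frozenset({4, 5}),
            ),
            FacilitySpec(
                facility_id="MTC3",
                kind="MTC",
                servers={"clinicians": 1},
                hours=(8.0, 20.0),
                accepts_categories=frozenset({4, 5}),
            ),
        ],
        travel_delay_minutes=20.0,
    )


def default_arrival_profile() -> ArrivalProfile:
    """Synthetic mid-size ED demand: ~170 arrivals/day, afternoon peak.

    Walk-ins skew low acuity (categories 3-5), ambulances high (1-3).
    """
    return ArrivalProfile(
        hourly_rates=[
            3.0, 2.5, 2.0, 2.0, 2.0, 2.5,   # 00-05
            4.0, 6.0, 8.0, 10.0, 11.0, 11.0,  # 06-11
            10.5, 10.0, 10.0, 10.0, 10.0, 10.5,  # 12-17
            10.0, 9.0, 8.0, 6.5, 5.0, 4.0,  # 18-23
        ],
        dow_factors=[1.15, 1.00, 0.95, 0.95, 0.95, 1.00, 1.00],
        ambulance_fraction=0.25,
        acuity_mix_walkin=[0.02, 0.08, 0.30, 0.40, 0.20],
        acuity_mix_ambulance=[0.10, 0.30, 0.40, 0.15, 0.05],
    )


def default_pathway() -> PathwaySpec:
    """Synthetic pathway parameters (lognormal activities, exponential boarding)."""
    return PathwaySpec(
        p_investigation=[0.90, 0.80, 0.60, 0.35, 0.15],
        p_treatment=[0.90, 0.80, 0.70, 0.50, 0.30],
        p_second_cycle=0.15,
        disposition_probs=[
            [0.10, 0.80, 0.10],
            [0.30, 0.60, 0.10],
            [0.55, 0.35, 0.10],
            [0.85, 0.10, 0.05],
            [0.95, 0.03, 0.02],
        ],
        service_times={
            "triage": ServiceTime(dist="lognormal", mean=5.0, cv=0.40),
            "assessment": ServiceTime(dist="lognormal", mean=25.0, cv=0.60),
            "investigation": ServiceTime(dist="lognormal", mean=40.0, cv=0.50),
            "treatment": ServiceTime(dist="lognormal", mean=20.0, cv=0.60),
            "cdu_stay": ServiceTime(dist="lognormal", mean=180.0, cv=0.40),
            "boarding": ServiceTime(dist="exponential", mean=60.0),
            "mtc_treatment": ServiceTime(dist="lognormal", mean=30.0, cv=0.50),
        },
        boarding_holds_cubicle=True,
    )


def default_scenarios() -> List[Scenario]:
    targets = {"MTC1": 0.4, "MTC2": 0.4, "MTC3": 0.2}
    return [
        Scenario(name="baseline", redirect_fraction=0.0),
        Scenario(name="redirect25", redirect_fraction=0.25, targets=targets),
        Scenario(name="redirect50", redirect_fraction=0.50, targets=targets),
    ]


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

_SECTION_BUILDERS = {
    "experiment": (ExperimentConfig, lambda: ExperimentConfig()),
    "network": (NetworkSpec, default_network),
    "arrivals": (ArrivalProfile, default_arrival_profile),
    "pathway": (PathwaySpec, default_pathway),
}


def _build_section(name: str, raw: Optional[dict], defaulted: List[str]):
    model, default_fn = _SECTION_BUILDERS[name]
    if raw is None:
        defaulted.append(name)
        return default_fn()
    if not isinstance(raw, dict):
        raise ValidationError(f"config section {name!r} must be a mapping")
    base = default_fn().model_dump()
    for key in base:
        if key not in raw:
            defaulted.append(f"{name}.{key}")
    if name == "pathway" and "service_times" in raw:
        # per-activity override on top of defaults
        merged = dict(base["service_times"])
        merged.update(raw["service_times"])
        raw = {**raw, "service_times": merged}
    base.update(raw)
    try:
        return model(**base)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"config section {name!r}: {exc}") from exc


def load_config(path) -> FullConfig:
    """Load and validate a YAML config; defaults fill omitted fields.

    The returned :class:`FullConfig` lists every defaulted field in
    ``defaulted_fields`` so a run is self-describing.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise
    except yaml.YAMLError as exc:
        raise ValidationError(f"cannot parse config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    unknown = set(raw) - set(_SECTION_BUILDERS) - {"scenarios"}
    if unknown:
        raise ValidationError(f"unknown config sections: {sorted(unknown)}")

    defaulted: List[str] = []
    sections = {name: _build_section(name, raw.get(name), defaulted) for name in _SECTION_BUILDERS}
    if "scenarios" in raw and raw["scenarios"] is not None:
        try:
            scenarios = [Scenario(**s) for s in raw["scenarios"]]
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"config section 'scenarios': {exc}") from exc
    else:
        defaulted.append("scenarios")
        scenarios = default_scenarios()
    try:
        return FullConfig(
            experiment=sections["experiment"],
            network=sections["network"],
            arrivals=sections["arrivals"],
            pathway=sections["pathway"],
            scenarios=scenarios,
            defaulted_fields=sorted(defaulted),
        )
    except (ValueError, TypeError) as exc:
        raise ValidationError(str(exc)) from exc


def dump_config(config: FullConfig, path) -> None:
    """Serialise a config so that :func:`load_config` round-trips it."""
    payload = {
        "experiment": config.experiment.model_dump(),
        "network": _jsonify(config.network.model_dump()),
        "arrivals": config.arrivals.model_dump(),
        "pathway": config.pathway.model_dump(),
        "scenarios": [_jsonify(s.model_dump()) for s in config.scenarios],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def _jsonify(obj):
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonify(v) for v in obj]
    return obj
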