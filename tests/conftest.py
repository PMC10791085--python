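from datetime import datetime

import numpy as np
import pytest

import urgentsim as u

MONDAY = datetime(2025, 1, 6)


@pytest.fixture(scope="session")
def network():
    return u.default_network()


@pytest.fixture(scope="session")
def profile():
    return u.default_arrival_profile()


@pytest.fixture(scope="session")
def pathway():
    return u.default_pathway()


def constant_profile(rate_per_hour: float, ambulance_fraction: float = 0.25) -> u.ArrivalProfile:
    """Flat arrival profile: same rate every hour, every day."""
    return u.ArrivalProfile(
        hourly_rates=[rate_per_hour] * 24,
        dow_factors=[1.0] * 7,
        ambulance_fraction=ambulance_fraction,
        acuity_mix_walkin=[0.02, 0.08, 0.30, 0.40, 0.20],
        acuity_mix_ambulance=[0.10, 0.30, 0.40, 0.15, 0.05],
    )


def mmc_setup(c: int, utilisation: float = 0.75, mean_service: float = 10.0):
    """Degenerate M/M/c configuration: the ED reduces to a multi-server queue.

    Zero-length triage, exponential assessment, no investigations or
    treatments, every disposition an immediate discharge, and a cubicle
    pool too large to ever bind, so the doctors are the only queue.
    """
    lam_per_hour = utilisation * c * 60.0 / mean_service
    network = u.NetworkSpec(
        facilities=[
            u.FacilitySpec(facility_id="ED1", kind="ED",
                           servers={"triage_nurses": 1, "doctors": c, "cubicles": 100000}),
        ],
        travel_delay_minutes=0.0,
    )
    pathway = u.PathwaySpec(
        p_investigation=[0.0] * 5,
        p_treatment=[0.0] * 5,
        p_second_cycle=0.0,
        disposition_probs=[[1.0, 0.0, 0.0]] * 5,
        service_times={
            "triage": u.ServiceTime(dist="fixed", mean=0.0),
            "assessment": u.ServiceTime(dist="exponential", mean=mean_service),
            "investigation": u.ServiceTime(dist="fixed", mean=0.0),
            "treatment": u.ServiceTime(dist="fixed", mean=0.0),
            "cdu_stay": u.ServiceTime(dist="fixed", mean=0.0),
            "boarding": u.ServiceTime(dist="fixed", mean=0.0),
            "mtc_treatment": u.ServiceTime(dist="fixed", mean=0.0),
        },
    )
    return network, constant_profile(lam_per_hour, ambulance_fraction=0.0), pathway


def erlang_c_wq(c: int, lam: float, mu: float) -> float:
    """Independent closed-form mean queue wait for M/M/c (Erlang C).

    ``Wq = C(c, a) / (c * mu - lam)`` with ``a = lam / mu`` and ``C`` the
    Erlang-C delay probability, computed by the stable recursion for the
    Erlang-B blocking probability ``B``: ``C = B / (1 - rho * (1 - B))``.
    """
    a = lam / mu
    rho = a / c
    if rho >= 1:
        raise ValueError("unstable queue")
    b = 1.0
    for k in range(1, c + 1):
        b = a * b / (k + a * b)
    c_prob = b / (1.0 - rho * (1.0 - b))
    return c_prob / (c * mu - lam)


def check_conservation(result: "u.SimulationResult") -> None:
    """Exact flow balance at every recorded boundary, per facility.

    census(t) == initial occupants + arrivals strictly before t minus
    departures strictly before t (boundary recorders fire before any
    event scheduled at the same instant).
    """
    ev = result.events
    for fid, frame in result.facility_series.items():
        arr = ev[(ev["facility_id"] == fid) & (ev["event"] == "arrival")]["timestamp"].to_numpy()
        dep = ev[(ev["facility_id"] == fid) & (ev["event"] == "depart")]["timestamp"].to_numpy()
        init = result.init_counts.get(fid, 0)
        for _, row in frame.iterrows():
            t = row["time"]
            expected = init + int((arr < t).sum()) - int((dep < t).sum())
            assert expected == int(row["census"]), (
                f"{fid} at t={t}: census {int(row['census'])} != flow balance {expected}")
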