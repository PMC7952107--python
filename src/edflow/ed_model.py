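"""Discrete-event engine for the low-acuity ED pathway.

Each simulated patient flows: arrival -> nurse screening -> vital signs
(one nurse hold spans both triage steps) -> queue for a room -> transfer to
room -> queue for a provider -> evaluation (resident path: resident
evaluation then attending/resident review; otherwise attending evaluation)
-> if tested: testing & treatment delay, then attending reassessment ->
nurse discharge process -> disposition -> bed cleaning -> room released.

Rooms are held from room entry until bed cleaning completes; nurses serve
screening, vitals and discharge; providers serve all evaluation and
reassessment steps.  Untested patients skip testing and reassessment.  All
queues are FIFO with no priority between ESI 4 and ESI 5 (a single
low-acuity track).

Two outcome timestamps matter downstream: ``wait`` is arrival to the start
of clinician evaluation, and ``los`` is arrival to disposition (the end of
the discharge process); bed cleaning happens after disposition and never
extends a patient's LOS.

The engine is a minimal event-scheduling kernel: patient processes are
generators yielding (verb, argument) commands onto a single event heap.
Per-patient service durations and the testing Bernoulli draw are all drawn
up-front from independent named streams, so two runs that share a seed are
bitwise identical and two scenarios that share streams are synchronised
patient-by-patient (common random numbers).
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import (
    ArrivalProfile,
    ServiceDistributionSpec,
    build_sampler,
    nhpp_arrivals,
)

__all__ = [
    "ResourceConfig",
    "PathwayConfig",
    "VisitLog",
    "run_replication",
    "utilization",
    "write_visit_log",
    "read_visit_log",
    "LOG_COLUMNS",
]

PROCESS_NAMES = (
    "nurse_screening",
    "vitals",
    "transfer_to_room",
    "attending_eval",
    "resident_eval",
    "attending_resident_review",
    "attending_reassessment",
    "testing_treatment_esi4",
    "testing_treatment_esi5",
    "nurse_discharge",
    "bed_cleaning",
)

LOG_COLUMNS = [
    "patient_id",
    "esi",
    "arrival",
    "screening_start",
    "screening_end",
    "vitals_end",
    "room_entry",
    "provider_start",
    "tested",
    "disposition",
    "los",
    "wait",
]


@dataclass(frozen=True)
class ResourceConfig:
    """Counts of the contended resources, plus the resident routing share."""

    n_rooms: int
    n_nurses: int
    n_providers: int
    n_residents: int = 0
    resident_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rooms < 1 or self.n_nurses < 1 or self.n_providers < 1:
            raise ValueError("rooms, nurses and providers must each be >= 1")
        if self.n_residents < 0:
            raise ValueError("n_residents must be >= 0")
        if not 0.0 <= self.resident_fraction <= 1.0:
            raise ValueError("resident_fraction must lie in [0, 1]")
        if self.n_residents == 0 and self.resident_fraction > 0:
            raise ValueError("resident_fraction must be 0 when there are no residents")


@dataclass(frozen=True)
class PathwayConfig:
    """One duration spec per pathway process plus per-ESI testing shares."""

    specs: dict  # name -> ServiceDistributionSpec, one per PROCESS_NAMES
    p_test_esi4: float
    p_test_esi5: float

    def __post_init__(self) -> None:
        missing = [n for n in PROCESS_NAMES if n not in self.specs]
        if missing:
            raise ValueError(f"pathway specs missing: {missing}")
        for p in (self.p_test_esi4, self.p_test_esi5):
            if not 0.0 <= p <= 1.0:
                raise ValueError("testing proportions must lie in [0, 1]")

    def with_rates(self, p_test_esi4: float, p_test_esi5: float) -> "PathwayConfig":
        return PathwayConfig(self.specs, p_test_esi4, p_test_esi5)


@dataclass
class VisitLog:
    """One replication's visit records plus engine-side resource accounting."""

    records: pd.DataFrame
    busy_minutes: dict = field(default_factory=dict)
    horizon_days: float = 0.0


class _Resource:
    __slots__ = ("free", "queue", "busy")

    def __init__(self, capacity: int):
        self.free = capacity
        self.queue: deque = deque()
        self.busy = 0.0  # accumulated service minutes


class _Kernel:
    """Event-scheduling core: a heap of (time, seq, generator)."""

    def __init__(self) -> None:
        self.heap: list = []
        self.now = 0.0
        self._seq = 0

    def schedule(self, time: float, gen) -> None:
        self._seq += 1
        heapq.heappush(self.heap, (time, self._seq, gen))

    def run(self) -> None:
        while self.heap:
            self.now, _, gen = heapq.heappop(self.heap)
            self._advance(gen)

    def _advance(self, gen) -> None:
        while True:
            try:
                verb, arg = next(gen)
            except StopIteration:
                return
            if verb == "delay":
                self.schedule(self.now + arg, gen)
                return
            if verb == "request":
                if arg.free > 0:
                    arg.free -= 1
                    continue  # granted immediately
                arg.queue.append(gen)
                return
            if verb == "release":
                if arg.queue:
                    # hand the unit straight to the longest waiter (FIFO)
                    self.schedule(self.now, arg.queue.popleft())
                else:
                    arg.free += 1
                continue
            raise AssertionError(verb)  # pragma: no cover


def _spawn_streams(seed: int, names: tuple) -> dict:
    """One named, independent random stream per process, from a master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


STREAM_NAMES = ("arrivals",) + PROCESS_NAMES + ("test_decision", "resident_route")


def run_replication(
    pathway: PathwayConfig,
    resources: ResourceConfig,
    profile: ArrivalProfile,
    horizon: float,
    warmup: float = 0.0,
    seed: int = 0,
    pathway_variant: str = "vitals_before_room",
) -> VisitLog:
    """Simulate ``horizon`` days of arrivals and follow every patient out.

    ``warmup`` is the initial slice of the horizon whose arrivals are
    excluded from the returned log (the empty-ED initialisation bias);
    the run itself is drained past the horizon so every recorded patient
    reaches disposition.  Identical arguments give bitwise-identical logs.
    """
    if horizon < 1.0:
        raise ValueError("horizon must be at least 1 day")
    if warmup < 0.0 or warmup > horizon:
        raise ValueError("warmup must lie within [0, horizon]")

    streams = _spawn_streams(seed, STREAM_NAMES)
    times, esi = nhpp_arrivals(profile, horizon, streams["arrivals"])
    n = times.size

    # pre-draw every duration and routing uniform (enables CRN across arms)
    draws = {}
    for name in PROCESS_NAMES:
        sampler = build_sampler(pathway.specs[name], streams[name])
        draws[name] = sampler(n) if n else np.empty(0)
    u_test = streams["test_decision"].random(n)
    u_res = streams["resident_route"].random(n)
    p_test = np.where(esi == 4, pathway.p_test_esi4, pathway.p_test_esi5)
    tested = u_test < p_test
    via_resident = (u_res < resources.resident_fraction) & (resources.n_residents > 0)
    test_dur = np.where(
        esi == 4, draws["testing_treatment_esi4"], draws["testing_treatment_esi5"]
    )

    rooms = _Resource(resources.n_rooms)
    nurses = _Resource(resources.n_nurses)
    providers = _Resource(resources.n_providers)
    residents = _Resource(max(resources.n_residents, 1))

    rec = np.full((n, len(LOG_COLUMNS)), np.nan)
    rec[:, 0] = np.arange(n)
    rec[:, 1] = esi
    rec[:, 2] = times
    rec[:, 8] = tested

    kern = _Kernel()

    vitals_in_room = pathway_variant == "vitals_in_room"
    if pathway_variant not in ("vitals_in_room", "vitals_before_room"):
        raise ValueError(f"unknown pathway_variant {pathway_variant!r}")

    def patient(i: int):
        # triage screening at the front door (nurse)
        yield ("request", nurses)
        rec[i, 3] = kern.now  # screening_start
        d = draws["nurse_screening"][i]
        nurses.busy += d
        yield ("delay", d)
        rec[i, 4] = kern.now  # screening_end
        if not vitals_in_room:
            d = draws["vitals"][i]
            nurses.busy += d
            yield ("delay", d)
            rec[i, 5] = kern.now  # vitals_end
        yield ("release", nurses)

        yield ("request", rooms)
        rec[i, 6] = kern.now  # room_entry; room held until cleaned
        room_entry = kern.now
        yield ("delay", draws["transfer_to_room"][i])

        if vitals_in_room:
            yield ("request", nurses)
            d = draws["vitals"][i]
            nurses.busy += d
            yield ("delay", d)
            rec[i, 5] = kern.now  # vitals_end (taken in the room)
            yield ("release", nurses)

        if via_resident[i]:
            yield ("request", residents)
            rec[i, 7] = kern.now  # provider_start: first clinician contact
            d = draws["resident_eval"][i]
            yield ("delay", d)
            yield ("release", residents)
            yield ("request", providers)
            d = draws["attending_resident_review"][i]
            providers.busy += d
            yield ("delay", d)
            yield ("release", providers)
        else:
            yield ("request", providers)
            rec[i, 7] = kern.now
            d = draws["attending_eval"][i]
            providers.busy += d
            yield ("delay", d)
            yield ("release", providers)

        if tested[i]:
            yield ("delay", test_dur[i])  # holds the room only
            yield ("request", providers)
            d = draws["attending_reassessment"][i]
            providers.busy += d
            yield ("delay", d)
            yield ("release", providers)

        yield ("request", nurses)
        d = draws["nurse_discharge"][i]
        nurses.busy += d
        yield ("delay", d)
        yield ("release", nurses)
        rec[i, 9] = kern.now  # disposition

        d = draws["bed_cleaning"][i]
        yield ("delay", d)
        rooms.busy += kern.now - room_entry
        yield ("release", rooms)

    for i in range(n):
        kern.schedule(times[i], patient(i))
    kern.run()

    rec[:, 10] = rec[:, 9] - rec[:, 2]  # los
    rec[:, 11] = rec[:, 7] - rec[:, 2]  # wait

    df = pd.DataFrame(rec, columns=LOG_COLUMNS)
    df["patient_id"] = df["patient_id"].astype(int)
    df["esi"] = df["esi"].astype(int)
    df["tested"] = df["tested"].astype(bool)
    df = df[df["arrival"] >= warmup * 1440.0].reset_index(drop=True)

    busy = {
        "rooms": rooms.busy,
        "nurses": nurses.busy,
        "providers": providers.busy,
    }
    return VisitLog(records=df, busy_minutes=busy, horizon_days=horizon)


def utilization(log: VisitLog, resources: ResourceConfig, horizon: float) -> dict:
    """Busy fraction per resource pool over the horizon (minutes basis)."""
    if log.records.empty and not log.busy_minutes:
        raise ValueError("empty visit log: no records and no resource accounting")
    total = horizon * 1440.0
    counts = {
        "rooms": resources.n_rooms,
        "nurses": resources.n_nurses,
        "providers": resources.n_providers,
    }
    return {
        name: min(1.0, log.busy_minutes.get(name, 0.0) / (counts[name] * total))
        for name in counts
    }


def write_visit_log(log: VisitLog, path) -> None:
    """CSV with one row per visit; times in minutes to 3 decimals."""
    df = log.records.copy()
    time_cols = [c for c in LOG_COLUMNS if c not in ("patient_id", "esi", "tested")]
    df[time_cols] = df[time_cols].round(3)
    df.to_csv(path, index=False, float_format="%.3f")


def read_visit_log(path) -> VisitLog:
    df = pd.read_csv(path)
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"visit log missing columns: {sorted(missing)}")
    return VisitLog(records=df[LOG_COLUMNS])
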