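"""Minimal process-oriented discrete-event kernel.

Processes are Python generators that yield *commands* (:class:`Timeout`,
:class:`Request`).  The environment keeps a single event heap keyed by
``(time, sequence)`` so that simultaneous events fire in schedule order,
which makes every run bit-reproducible for a fixed random seed.

Resources are counting semaphores with a priority queue; they also
integrate busy-time so utilisation can be reported, and they allow
over-capacity *insertion* of pre-existing occupants (used when a run is
initialised from a live snapshot of a crowded department: the physical
system can hold more patients than its nominal capacity, and ordinary
requests simply wait until occupancy drops below capacity again).
"""

from __future__ import annotations

import heapq
import itertools
from typing import Any, Callable, Generator, Optional


class Environment:
    """Event loop with a virtual clock in simulation minutes."""

    def __init__(self) -> None:
        self.now: float = 0.0
        self._heap: list = []
        self._seq = itertools.count()

    def schedule(self, delay: float, fn: Callable, *args: Any) -> None:
        if delay < 0:
            raise ValueError(f"cannot schedule into the past (delay={delay})")
        heapq.heappush(self._heap, (self.now + delay, next(self._seq), fn, args))

    def process(self, gen: Generator) -> "Process":
        return Process(self, gen)

    def run(self, until: float) -> None:
        heap = self._heap
        while heap and heap[0][0] <= until:
            t, _, fn, args = heapq.heappop(heap)
            self.now = t
            fn(*args)
        self.now = until


class Process:
    """Drives a generator; resumed by the commands it yields."""

    def __init__(self, env: Environment, gen: Generator) -> None:
        self.env = env
        self.gen = gen
        env.schedule(0.0, self._step, None)

    def _step(self, value: Any) -> None:
        try:
            cmd = self.gen.send(value)
        except StopIteration:
            return
        cmd._bind(self)


class Timeout:
    """Resume the yielding process after ``delay`` minutes."""

    __slots__ = ("delay",)

    def __init__(self, delay: float) -> None:
        self.delay = delay

    def _bind(self, proc: Process) -> None:
        proc.env.schedule(self.delay, proc._step, None)


class Request:
    """Acquire one unit of a resource (optionally with priority)."""

    __slots__ = ("resource", "priority")

    def __init__(self, resource: "Resource", priority: Any = 0) -> None:
        self.resource = resource
        self.priority = priority

    def _bind(self, proc: Process) -> None:
        self.resource._enqueue(self, proc)


class Resource:
    """Counting semaphore with a stable priority queue.

    ``priority`` values compare as tuples; lower sorts first.  Ties are
    broken FIFO via an insertion counter.  Busy time is integrated so
    ``utilisation(T)`` = busy-unit-minutes / (capacity * T).
    """

    def __init__(self, env: Environment, capacity: int, name: str = "") -> None:
        if capacity < 1:
            raise ValueError(f"resource capacity must be >= 1, got {capacity}")
        self.env = env
        self.capacity = capacity
        self.name = name
        self.in_use = 0
        self._queue: list = []
        self._tick = itertools.count()
        self._busy_integral = 0.0
        self._last_change = 0.0

    # -- accounting -------------------------------------------------
    def _mark(self) -> None:
        now = self.env.now
        self._busy_integral += self.in_use * (now - self._last_change)
        self._last_change = now

    def busy_minutes(self, until: Optional[float] = None) -> float:
        t = self.env.now if until is None else until
        return self._busy_integral + self.in_use * (t - self._last_change)

    def utilisation(self, run_minutes: float) -> float:
        if run_minutes <= 0:
            return 0.0
        return self.busy_minutes(run_minutes) / (self.capacity * run_minutes)

    # -- acquisition ------------------------------------------------
    def _enqueue(self, req: Request, proc: Process) -> None:
        if self.in_use < self.capacity and not self._queue:
            self._mark()
            self.in_use += 1
            self.env.schedule(0.0, proc._step, None)
        else:
            heapq.heappush(self._queue, (req.priority, next(self._tick), proc))

    def release(self) -> None:
        if self.in_use <= 0:
            raise RuntimeError(f"release of idle resource {self.name!r}")
        self._mark()
        self.in_use -= 1
        self._grant()

    def _grant(self) -> None:
        while self._queue and self.in_use < self.capacity:
            _, _, proc = heapq.heappop(self._queue)
            self._mark()
            self.in_use += 1
            self.env.schedule(0.0, proc._step, None)

    def occupy(self) -> None:
        """Seize a unit unconditionally, even above nominal capacity.

        Used only when seeding initial occupants from a snapshot.
        """
        self._mark()
        self.in_use += 1

    @property
    def queue_length(self) -> int:
        return len(self._queue)
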