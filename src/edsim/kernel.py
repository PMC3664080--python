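"""Minimal process-oriented discrete-event simulation kernel.

The kernel provides the four primitives the patient-flow models are built
from:

* an event calendar with a non-decreasing simulation clock (minutes),
* generator-based processes (``yield`` an event to suspend until it fires),
* capacitated resources with priority-then-FIFO queues and an optional
  hour-of-day capacity schedule, and
* broadcast signal channels with hold-until-signal semantics, used by the
  pseudo-agents to wake on "patient waiting" / "consult requested".

Events scheduled at the same simulated time pop in (time, priority,
insertion sequence) order, so runs are fully deterministic for a fixed
configuration and seed.
"""

from __future__ import annotations

import heapq
import warnings
from collections.abc import Callable, Generator, Iterable, Sequence
from typing import Any

__all__ = [
    "AllOf",
    "AnyOf",
    "Environment",
    "Event",
    "Interrupt",
    "Process",
    "Request",
    "Resource",
    "SignalChannel",
    "SimulationError",
    "Timeout",
]

_PENDING = object()


class SimulationError(RuntimeError):
    """Raised for contract violations inside the simulation kernel."""


class Interrupt(Exception):
    """Thrown into a process that is interrupted while waiting."""


class Event:
    """A one-shot occurrence on the simulation calendar.

    Events start untriggered; :meth:`trigger` places them on the calendar and
    :attr:`callbacks` run when the clock reaches them.  Processes waiting on
    an event are resumed through those callbacks.
    """

    __slots__ = ("env", "callbacks", "_value", "_triggered", "_processed")

    def __init__(self, env: "Environment") -> None:
        self.env = env
        self.callbacks: list[Callable[[Event], None]] = []
        self._value: Any = _PENDING
        self._triggered = False
        self._processed = False

    @property
    def triggered(self) -> bool:
        return self._triggered

    @property
    def processed(self) -> bool:
        return self._processed

    @property
    def value(self) -> Any:
        if self._value is _PENDING:
            raise SimulationError("event value not yet available")
        return self._value

    def trigger(self, value: Any = None, delay: float = 0.0, priority: int = 0) -> "Event":
        if self._triggered:
            raise SimulationError("event already triggered")
        self._triggered = True
        self._value = value
        self.env.schedule(self, delay=delay, priority=priority)
        return self

    # alias matching the conventional succeed/trigger vocabulary
    succeed = trigger


class Timeout(Event):
    """An event that fires ``delay`` minutes after its creation."""

    __slots__ = ()

    def __init__(self, env: "Environment", delay: float, priority: int = 0) -> None:
        super().__init__(env)
        if delay < 0:
            raise ValueError(f"negative delay {delay!r} rejected")
        self._triggered = True
        self._value = None
        env.schedule(self, delay=delay, priority=priority)


class Process(Event):
    """A generator-based process; itself an event that fires on return."""

    __slots__ = ("_generator", "_waiting_on")

    def __init__(self, env: "Environment", generator: Generator[Event, Any, Any]) -> None:
        super().__init__(env)
        self._generator = generator
        self._waiting_on: Event | None = None
        boot = Event(env)
        boot.callbacks.append(self._resume)
        boot.trigger(None)

    @property
    def is_alive(self) -> bool:
        return not self._triggered

    def interrupt(self, cause: Any = None) -> None:
        """Throw :class:`Interrupt` into the process at the current time."""
        if self._triggered:
            return
        wake = Event(self.env)
        wake.callbacks.append(lambda _ev: self._resume(_ev, interrupt=Interrupt(cause)))
        wake.trigger(cause)

    def _resume(self, event: Event, interrupt: Interrupt | None = None) -> None:
        if self._triggered:
            return
        self._waiting_on = None
        try:
            if interrupt is not None:
                nxt = self._generator.throw(interrupt)
            else:
                nxt = self._generator.send(event._value if event._value is not _PENDING else None)
        except StopIteration as stop:
            super().trigger(stop.value)
            return
        except Interrupt:
            super().trigger(None)
            return
        if not isinstance(nxt, Event):
            raise SimulationError(f"process yielded {nxt!r}, expected an Event")
        self._waiting_on = nxt
        if nxt._processed:
            # already fired: resume immediately (keeps zero-delay semantics)
            wake = Event(self.env)
            wake.callbacks.append(self._resume)
            wake.trigger(nxt._value)
        else:
            nxt.callbacks.append(self._resume)


class _Condition(Event):
    __slots__ = ("_events", "_n_needed", "_n_done")

    def __init__(self, env: "Environment", events: Iterable[Event], n_needed: int | None) -> None:
        super().__init__(env)
        self._events = list(events)
        if not self._events:
            raise ValueError("condition over zero events")
        self._n_needed = len(self._events) if n_needed is None else n_needed
        self._n_done = 0
        for ev in self._events:
            if ev._processed:
                self._child_done(ev)
            else:
                ev.callbacks.append(self._child_done)

    def _child_done(self, _ev: Event) -> None:
        if self._triggered:
            return
        self._n_done += 1
        if self._n_done >= self._n_needed:
            self.trigger([e._value for e in self._events if e._processed or e is _ev])


class AnyOf(_Condition):
    """Fires when the first of the given events fires."""

    __slots__ = ()

    def __init__(self, env: "Environment", events: Iterable[Event]) -> None:
        super().__init__(env, events, n_needed=1)


class AllOf(_Condition):
    """Fires when all of the given events have fired."""

    __slots__ = ()

    def __init__(self, env: "Environment", events: Iterable[Event]) -> None:
        super().__init__(env, events, n_needed=None)


class Environment:
    """Event calendar plus simulation clock (minutes since run start)."""

    def __init__(self) -> None:
        self.now: float = 0.0
        self._heap: list[tuple[float, int, int, Event]] = []
        self._seq = 0
        self.n_scheduled = 0
        self.n_executed = 0
        self.n_cancelled = 0

    # -- scheduling ------------------------------------------------------
    def schedule(self, event: Event, delay: float = 0.0, priority: int = 0) -> None:
        if delay < 0:
            raise ValueError(f"negative delay {delay!r} rejected")
        self._seq += 1
        self.n_scheduled += 1
        heapq.heappush(self._heap, (self.now + delay, priority, self._seq, event))

    def timeout(self, delay: float, priority: int = 0) -> Timeout:
        return Timeout(self, delay, priority=priority)

    def event(self) -> Event:
        return Event(self)

    def process(self, generator: Generator[Event, Any, Any]) -> Process:
        return Process(self, generator)

    def any_of(self, events: Iterable[Event]) -> AnyOf:
        return AnyOf(self, events)

    def all_of(self, events: Iterable[Event]) -> AllOf:
        return AllOf(self, events)

    # -- execution -------------------------------------------------------
    def peek(self) -> float:
        return self._heap[0][0] if self._heap else float("inf")

    def run(self, until: float | None = None) -> None:
        """Process events in order until the calendar is empty or ``until``."""
        while self._heap:
            t, _prio, _seq, event = self._heap[0]
            if until is not None and t > until:
                break
            heapq.heappop(self._heap)
            if t < self.now - 1e-12:
                raise SimulationError("event scheduled in the past")
            self.now = max(self.now, t)
            self.n_executed += 1
            event._processed = True
            callbacks, event.callbacks = event.callbacks, []
            for cb in callbacks:
                cb(event)
        if until is not None and self.now < until:
            self.now = until


class Request(Event):
    """A pending or granted claim on one unit of a :class:`Resource`."""

    __slots__ = ("resource", "priority", "seq", "cancelled", "granted_at")

    def __init__(self, resource: "Resource", priority: int) -> None:
        super().__init__(resource.env)
        self.resource = resource
        self.priority = priority
        self.seq = resource._next_seq()
        self.cancelled = False
        self.granted_at: float | None = None

    def cancel(self) -> None:
        """Withdraw a request that has not been granted yet."""
        if self._triggered:
            raise SimulationError("cannot cancel a granted request; release it")
        self.cancelled = True
        self.env.n_cancelled += 1


class Resource:
    """Capacitated server pool with a priority-then-FIFO queue.

    ``capacity`` is either a constant integer or a 24-element hour-of-day
    schedule.  Capacity reductions never preempt work in progress: they only
    gate new grants.  Busy time is integrated continuously so utilization can
    be recovered exactly from ``busy_integral``.
    """

    def __init__(self, env: Environment, name: str, capacity: int | Sequence[int]) -> None:
        self.env = env
        self.name = name
        if isinstance(capacity, int):
            if capacity < 0:
                raise ValueError("capacity must be non-negative")
            self._schedule: tuple[int, ...] | None = None
            self._capacity = capacity
        else:
            sched = tuple(int(c) for c in capacity)
            if len(sched) != 24:
                raise ValueError("capacity schedule must have 24 hourly entries")
            if any(c < 0 for c in sched):
                raise ValueError("capacity must be non-negative")
            self._schedule = sched
            self._capacity = sched[0]
            env.process(self._ticker())
        if self.capacity_at(0.0) == 0 and (self._schedule is None or max(self._schedule) == 0):
            warnings.warn(f"resource {name!r} has zero capacity for the whole horizon", stacklevel=2)
        self.users = 0
        self.queue: list[tuple[int, int, Request]] = []
        self._seq = 0
        self.busy_integral = 0.0
        self.capacity_integral = 0.0
        self._last_t = env.now

    def _next_seq(self) -> int:
        self._seq += 1
        return self._seq

    def capacity_at(self, t: float) -> int:
        if self._schedule is None:
            return self._capacity
        return self._schedule[int(t // 60.0) % 24]

    @property
    def capacity(self) -> int:
        return self.capacity_at(self.env.now)

    def _ticker(self) -> Generator[Event, Any, None]:
        while True:
            gap = 60.0 - (self.env.now % 60.0)
            yield self.env.timeout(gap if gap > 0 else 60.0)
            self._grant()

    def _account(self) -> None:
        dt = self.env.now - self._last_t
        if dt > 0:
            self.busy_integral += self.users * dt
            self.capacity_integral += self.capacity_at(self._last_t) * dt
            self._last_t = self.env.now

    def request(self, priority: int = 0) -> Request:
        req = Request(self, priority)
        heapq.heappush(self.queue, (priority, req.seq, req))
        self._grant()
        return req

    def release(self, _req: Request | None = None) -> None:
        if self.users <= 0:
            raise SimulationError(f"release of idle resource {self.name!r}")
        self._account()
        self.users -= 1
        self._grant()

    def _grant(self) -> None:
        cap = self.capacity
        while self.queue and self.users < cap:
            _prio, _seq, req = heapq.heappop(self.queue)
            if req.cancelled:
                continue
            self._account()
            self.users += 1
            req.granted_at = self.env.now
            req.trigger(req)

    def finalize(self) -> None:
        """Close the busy-time integral at the current clock."""
        self._account()

    @property
    def queue_length(self) -> int:
        return sum(1 for _p, _s, r in self.queue if not r.cancelled)

    def utilization(self) -> float:
        """Time-average busy units over time-average scheduled capacity."""
        self._account()
        if self.capacity_integral == 0:
            return 0.0
        return self.busy_integral / self.capacity_integral


class SignalChannel:
    """Broadcast wake-up channel with hold-until-signal semantics.

    A ``send`` wakes every process holding at that instant exactly once;
    processes not holding when the signal fires are unaffected.  The optional
    sort key of :meth:`send` controls the order in which waiters resume at
    the same simulated time, which is how claim tie-break rules are applied.
    """

    def __init__(self, env: Environment, name: str) -> None:
        self.env = env
        self.name = name
        self._waiters: list[tuple[Event, Any]] = []

    def hold(self, owner: Any = None) -> Event:
        ev = Event(self.env)
        self._waiters.append((ev, owner))
        return ev

    def attach(self, event: Event, owner: Any = None) -> Event:
        """Register an existing event as a waiter (one event may hold on
        several channels at once; the first send wins, later sends are
        no-ops on an already-triggered event)."""
        self._waiters.append((event, owner))
        return event

    def send(self, value: Any = None, sort_key: Callable[[Any], Any] | None = None) -> int:
        """Wake all current waiters; returns the number woken."""
        waiters, self._waiters = self._waiters, []
        if sort_key is not None:
            waiters.sort(key=lambda pair: sort_key(pair[1]))
        for ev, _owner in waiters:
            if not ev._triggered:
                ev.trigger(value)
        return len(waiters)

    @property
    def n_waiting(self) -> int:
        return len(self._waiters)
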