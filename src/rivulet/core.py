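"""Push-based observable sequences on a deterministic virtual-time scheduler.

An *observable sequence* is a stream of timed notifications: zero or more
NEXT values followed by at most one terminal (COMPLETED or ERROR).  All
timing in the engine is virtual: integer ticks advanced explicitly through a
:class:`VirtualScheduler`, which executes queued actions in ``(time,
sequence-number)`` order so that every run of a pipeline is bit-for-bit
reproducible.  Real-time execution is a deployment concern, not an engine
one; nothing here touches a wall clock.

Sources come in two flavors.  *Cold* sources replay their script relative to
each subscription's start time.  *Hot* sources (subjects) broadcast to all
current subscribers; a late subscriber to a terminated subject receives the
terminal notification immediately.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Any, Callable, Iterable, Optional, Sequence


class Kind(Enum):
    """The three notification kinds of the stream grammar ``NEXT* (COMPLETED|ERROR)?``."""

    NEXT = "N"
    COMPLETED = "C"
    ERROR = "E"


@dataclass(frozen=True)
class Notification:
    """One event on a stream: a value, a completion, or an error, at a virtual time."""

    time: int
    kind: Kind
    payload: Any = None
    error_info: Optional[str] = None

    @staticmethod
    def next_(time: int, payload: Any) -> "Notification":
        return Notification(time, Kind.NEXT, payload)

    @staticmethod
    def completed(time: int) -> "Notification":
        return Notification(time, Kind.COMPLETED)

    @staticmethod
    def error(time: int, info: str = "") -> "Notification":
        return Notification(time, Kind.ERROR, error_info=info)

    def __repr__(self) -> str:  # compact marble-ish form, eases test diffs
        if self.kind is Kind.NEXT:
            return f"N({self.payload!r}@{self.time})"
        if self.kind is Kind.COMPLETED:
            return f"C(@{self.time})"
        return f"E({self.error_info!r}@{self.time})"


class ContractError(RuntimeError):
    """Violation of the engine contract (clock moved backwards, bad configuration)."""


class VirtualScheduler:
    """Deterministic virtual-time action queue.

    Actions are executed in ``(time, sequence-number)`` order where the
    sequence number is assignment order; two actions queued for the same tick
    therefore run in the order they were scheduled.  The clock never moves
    backwards.
    """

    def __init__(self) -> None:
        self.clock: int = 0
        self._queue: list[tuple[int, int, Callable[[], None]]] = []
        self._seq = itertools.count()

    def schedule(self, action: Callable[[], None], time: Optional[int] = None,
                 delay: Optional[int] = None) -> None:
        """Queue ``action`` at absolute ``time``, or ``clock + delay``, or now."""
        if time is None:
            time = self.clock + (delay or 0)
        if time < self.clock:
            raise ContractError(f"cannot schedule at {time} before clock {self.clock}")
        heapq.heappush(self._queue, (time, next(self._seq), action))

    def advance_to(self, t: int) -> None:
        """Execute all actions queued at times <= ``t``; leave the clock at ``t``."""
        if t < self.clock:
            raise ContractError(f"cannot advance to {t} before clock {self.clock}")
        while self._queue and self._queue[0][0] <= t:
            time, _, action = heapq.heappop(self._queue)
            self.clock = time
            action()
        self.clock = t

    def advance_by(self, dt: int) -> None:
        self.advance_to(self.clock + dt)

    def run(self) -> None:
        """Drain the queue completely (actions may enqueue more actions)."""
        while self._queue:
            time, _, action = heapq.heappop(self._queue)
            self.clock = time
            action()


class Observer:
    """Receiver of stream notifications.  Subclass or pass callbacks to subscribe()."""

    def on_next(self, value: Any) -> None:  # pragma: no cover - interface
        pass

    def on_completed(self) -> None:  # pragma: no cover - interface
        pass

    def on_error(self, info: str) -> None:  # pragma: no cover - interface
        pass


class _CallbackObserver(Observer):
    def __init__(self, on_next=None, on_completed=None, on_error=None):
        self._n, self._c, self._e = on_next, on_completed, on_error

    def on_next(self, value):
        if self._n:
            self._n(value)

    def on_completed(self):
        if self._c:
            self._c()

    def on_error(self, info):
        if self._e:
            self._e(info)


class Subscription:
    """Handle to an active subscription; dispose() stops delivery and frees upstream."""

    def __init__(self) -> None:
        self._disposed = False
        self._upstream: list[Callable[[], None]] = []

    @property
    def disposed(self) -> bool:
        return self._disposed

    def add(self, teardown: Callable[[], None]) -> None:
        if self._disposed:
            teardown()
        else:
            self._upstream.append(teardown)

    def dispose(self) -> None:
        if self._disposed:
            return
        self._disposed = True
        for teardown in self._upstream:
            teardown()
        self._upstream.clear()


class _Guard(Observer):
    """Enforces the notification grammar per subscription and auto-detaches.

    After a terminal notification (or dispose) nothing more is delivered.  An
    exception raised by the downstream observer converts the subscription to
    ERROR, per the engine contract.
    """

    def __init__(self, downstream: Observer, subscription: Subscription) -> None:
        self._down = downstream
        self._sub = subscription
        self._stopped = False

    @property
    def stopped(self) -> bool:
        return self._stopped or self._sub.disposed

    def on_next(self, value: Any) -> None:
        if self.stopped:
            return
        try:
            self._down.on_next(value)
        except ContractError:
            raise
        except Exception as exc:  # observer fault -> ERROR for this subscription
            self.on_error(f"observer raised: {exc!r}")

    def on_completed(self) -> None:
        if self.stopped:
            return
        self._stopped = True
        try:
            self._down.on_completed()
        finally:
            self._sub.dispose()

    def on_error(self, info: str) -> None:
        if self.stopped:
            return
        self._stopped = True
        try:
            self._down.on_error(info)
        finally:
            self._sub.dispose()


class Observable:
    """A push-based stream bound to a scheduler.

    ``on_subscribe(observer) -> teardown`` wires one subscription; the
    returned teardown releases upstream resources when the subscription is
    disposed.
    """

    def __init__(self, scheduler: VirtualScheduler,
                 on_subscribe: Callable[[Observer], Optional[Callable[[], None]]]) -> None:
        self.scheduler = scheduler
        self._on_subscribe = on_subscribe

    def subscribe(self, observer: Optional[Observer] = None, *,
                  on_next=None, on_completed=None, on_error=None) -> Subscription:
        if observer is None:
            observer = _CallbackObserver(on_next, on_completed, on_error)
        sub = Subscription()
        guard = _Guard(observer, sub)
        teardown = self._on_subscribe(guard)
        if teardown is not None:
            sub.add(teardown)
        return sub


class Subject(Observable, Observer):
    """Hot source: broadcasts pushed notifications to all current subscribers.

    Remembers its terminal state so that a subscriber arriving after
    completion immediately receives the terminal notification (at its own
    subscription tick).
    """

    def __init__(self, scheduler: VirtualScheduler) -> None:
        self._observers: list[_Guard] = []
        self._terminal: Optional[tuple[Kind, str]] = None
        super().__init__(scheduler, self._attach)

    def _attach(self, guard: _Guard):
        if self._terminal is not None:
            kind, info = self._terminal
            if kind is Kind.COMPLETED:
                guard.on_completed()
            else:
                guard.on_error(info)
            return None
        self._observers.append(guard)
        return lambda: self._observers.remove(guard) if guard in self._observers else None

    def on_next(self, value: Any) -> None:
        if self._terminal is not None:
            return
        for guard in list(self._observers):
            guard.on_next(value)

    def on_completed(self) -> None:
        if self._terminal is not None:
            return
        self._terminal = (Kind.COMPLETED, "")
        observers, self._observers = self._observers, []
        for guard in observers:
            guard.on_completed()

    def on_error(self, info: str) -> None:
        if self._terminal is not None:
            return
        self._terminal = (Kind.ERROR, info)
        observers, self._observers = self._observers, []
        for guard in observers:
            guard.on_error(info)


def _deliver(guard: _Guard, notif: Notification) -> None:
    if notif.kind is Kind.NEXT:
        guard.on_next(notif.payload)
    elif notif.kind is Kind.COMPLETED:
        guard.on_completed()
    else:
        guard.on_error(notif.error_info or "")


def cold(scheduler: VirtualScheduler, notifications: Sequence[Notification]) -> Observable:
    """Cold source: replays the script relative to each subscription's tick.

    The script is taken literally: a script without a terminal notification
    yields a stream that never terminates.
    """
    script = list(notifications)

    def on_subscribe(guard: _Guard):
        t0 = scheduler.clock
        for notif in script:
            scheduler.schedule(
                (lambda n: (lambda: _deliver(guard, n)))(notif), time=t0 + notif.time)
        return None

    return Observable(scheduler, on_subscribe)


def from_values(scheduler: VirtualScheduler, values: Iterable[Any],
                times: Optional[Sequence[int]] = None) -> Observable:
    """Cold source of ``values`` completing at the last value's tick.

    With no explicit ``times``, value k is emitted k+1 ticks after
    subscription.  An empty value list completes at the subscription tick.
    """
    values = list(values)
    if times is None:
        times = list(range(1, len(values) + 1))
    if len(times) != len(values):
        raise ContractError("times and values must have equal length")
    script = [Notification.next_(t, v) for t, v in zip(times, values)]
    script.append(Notification.completed(times[-1] if values else 0))
    return cold(scheduler, script)


def hot(scheduler: VirtualScheduler, notifications: Sequence[Notification]) -> Subject:
    """Hot source: pushes the script at absolute times to whoever is subscribed."""
    subject = Subject(scheduler)
    for notif in notifications:
        scheduler.schedule(
            (lambda n: (lambda: _deliver(subject, n)))(notif), time=notif.time)
    return subject


def timer(scheduler: VirtualScheduler, delay: int, payload: Any = 0) -> Observable:
    """Cold one-shot: emits ``payload`` then completes, ``delay`` ticks after subscription."""
    return cold(scheduler, [Notification.next_(delay, payload),
                            Notification.completed(delay)])


def never(scheduler: VirtualScheduler) -> Observable:
    """A stream that never emits and never terminates."""
    return Observable(scheduler, lambda guard: None)


class Recorder(Observer):
    """Observer that logs every notification with the scheduler clock at delivery."""

    def __init__(self, scheduler: VirtualScheduler) -> None:
        self._sched = scheduler
        self.log: list[Notification] = []

    def on_next(self, value):
        self.log.append(Notification.next_(self._sched.clock, value))

    def on_completed(self):
        self.log.append(Notification.completed(self._sched.clock))

    def on_error(self, info):
        self.log.append(Notification.error(self._sched.clock, info))


def record(stream: Observable, until: Optional[int] = None) -> list[Notification]:
    """Subscribe a fresh Recorder, advance time, and return the notification log."""
    rec = Recorder(stream.scheduler)
    stream.subscribe(rec)
    if until is None:
        stream.scheduler.run()
    else:
        stream.scheduler.advance_to(until)
    return rec.log
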