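"""Single- and multi-stream operators: map, filter, sink, sample, take,
repeat, merge, timestamp, and externalized-property binding.

Every operator preserves the notification grammar and never shifts an
element in time: transforms, conditions and sinks re-emit at the input's
tick, and multi-stream combinators order simultaneous events by the
creation/subscription order of their sources (deterministic tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

from .core import (ContractError, Observable, Observer, Subscription,
                   VirtualScheduler)


@dataclass(frozen=True)
class TimestampedValue:
    """A payload wrapped with the virtual clock reading at its emission."""

    payload: Any
    time: int


@dataclass
class PropertyBinding:
    """An externalized node property driven by a stream.

    ``current_value`` always equals the last NEXT of the bound property
    stream, or ``default`` before any NEXT arrives.  Operators read the
    binding at each element they process, so an update at tick t is visible
    to every element at ticks > t (and to later same-tick elements, since
    same-tick delivery follows scheduling order).
    """

    target_node: Any
    property_name: str
    default: Any = None
    current_value: Any = field(init=False)

    def __post_init__(self) -> None:
        self.current_value = self.default


def map_(src: Observable, fn: Callable[[Any], Any]) -> Observable:
    """Transform each element; order and timing unchanged.  fn raising -> ERROR."""

    def on_subscribe(guard):
        def forward(value):
            try:
                mapped = fn(value)
            except Exception as exc:
                guard.on_error(f"map function raised: {exc!r}")
                return
            guard.on_next(mapped)

        sub = src.subscribe(on_next=forward, on_completed=guard.on_completed,
                            on_error=guard.on_error)
        return sub.dispose

    return Observable(src.scheduler, on_subscribe)


def filter_(src: Observable, pred: Callable[[Any], bool]) -> Observable:
    """Forward elements satisfying ``pred`` at their original times."""

    def on_subscribe(guard):
        def forward(value):
            try:
                keep = pred(value)
            except Exception as exc:
                guard.on_error(f"filter predicate raised: {exc!r}")
                return
            if keep:
                guard.on_next(value)

        sub = src.subscribe(on_next=forward, on_completed=guard.on_completed,
                            on_error=guard.on_error)
        return sub.dispose

    return Observable(src.scheduler, on_subscribe)


def sink(src: Observable, effect: Callable[[Any], None]) -> Observable:
    """Run a side effect per element, forwarding the stream unchanged."""

    def on_subscribe(guard):
        def forward(value):
            try:
                effect(value)
            except Exception as exc:
                guard.on_error(f"sink effect raised: {exc!r}")
                return
            guard.on_next(value)

        sub = src.subscribe(on_next=forward, on_completed=guard.on_completed,
                            on_error=guard.on_error)
        return sub.dispose

    return Observable(src.scheduler, on_subscribe)


def sample(src: Observable, trigger: Observable) -> Observable:
    """Emit the latest ``src`` element at each ``trigger`` element.

    Nothing is emitted for triggers arriving before the first source value.
    The latest value is re-emitted on every trigger even if unchanged
    (every trigger acts, e.g. every key press saves a snapshot).  The output
    completes when the data source completes; trigger completion only stops
    sampling.  An error on either input propagates.
    """

    def on_subscribe(guard):
        state = {"seen": False, "latest": None}

        def remember(value):
            state["seen"], state["latest"] = True, value

        def fire(_):
            if state["seen"]:
                guard.on_next(state["latest"])

        sub_src = src.subscribe(on_next=remember, on_completed=guard.on_completed,
                                on_error=guard.on_error)
        sub_trig = trigger.subscribe(on_next=fire, on_error=guard.on_error)

        def teardown():
            sub_src.dispose()
            sub_trig.dispose()

        return teardown

    return Observable(src.scheduler, on_subscribe)


def take(src: Observable, n: int) -> Observable:
    """Forward the first ``n`` elements, completing at the nth element's tick."""
    if n <= 0:
        raise ContractError(f"take requires n >= 1, got {n}")

    def on_subscribe(guard):
        state = {"left": n}

        def forward(value):
            state["left"] -= 1
            guard.on_next(value)
            if state["left"] == 0:
                guard.on_completed()

        sub = src.subscribe(on_next=forward, on_completed=guard.on_completed,
                            on_error=guard.on_error)
        return sub.dispose

    return Observable(src.scheduler, on_subscribe)


def repeat(scheduler: VirtualScheduler,
           factory: Callable[[], Observable]) -> Observable:
    """Resubscribe a stream blueprint whenever it completes.

    Iteration k+1 starts at the tick iteration k completed.  ERROR is not
    restarted.  A blueprint completing at its own subscription tick twice in
    a row trips a zero-time-loop guard (ERROR), preventing the scheduler
    from spinning forever at one tick.
    """

    def on_subscribe(guard):
        state = {"sub": None, "zero_streak": 0, "disposed": False}

        def start():
            if state["disposed"]:
                return
            started_at = scheduler.clock

            def done():
                if scheduler.clock == started_at:
                    state["zero_streak"] += 1
                else:
                    state["zero_streak"] = 0
                if state["zero_streak"] >= 2:
                    guard.on_error("zero-time loop: blueprint completed "
                                   "instantly twice in a row")
                    return
                start()

            state["sub"] = factory().subscribe(
                on_next=guard.on_next, on_completed=done, on_error=guard.on_error)

        start()

        def teardown():
            state["disposed"] = True
            if state["sub"] is not None:
                state["sub"].dispose()

        return teardown

    return Observable(scheduler, on_subscribe)


def merge(scheduler: VirtualScheduler,
          sources: Sequence[Observable]) -> Observable:
    """Interleave all sources by time (ties by source order).

    Completes when every source has completed; the first ERROR wins.  An
    empty source list completes immediately.
    """
    sources = list(sources)

    def on_subscribe(guard):
        if not sources:
            guard.on_completed()
            return None
        state = {"remaining": len(sources)}

        def one_done():
            state["remaining"] -= 1
            if state["remaining"] == 0:
                guard.on_completed()

        subs = [src.subscribe(on_next=guard.on_next, on_completed=one_done,
                              on_error=guard.on_error)
                for src in sources]

        def teardown():
            for sub in subs:
                sub.dispose()

        return teardown

    return Observable(scheduler, on_subscribe)


def timestamp(src: Observable) -> Observable:
    """Wrap each payload with the shared virtual clock at its emission."""
    return map_(src, lambda v: TimestampedValue(v, src.scheduler.clock))


def bind_property(prop_stream: Observable, binding: PropertyBinding) -> Subscription:
    """Drive an externalized property from a stream.

    Each NEXT overwrites ``binding.current_value`` before any later-tick
    element reaches the target node; two updates at one tick resolve to the
    last writer in script order.
    """
    return prop_stream.subscribe(
        on_next=lambda v: setattr(binding, "current_value", v))


def rescale(x: float, lo: float, hi: float,
            range_lo: float = 0.0, range_hi: float = 1.0) -> float:
    """Affine rescaling of ``x`` from [lo, hi] onto [range_lo, range_hi].

    The canonical user-defined transform: a pure scalar function dropped
    into a pipeline with :func:`map_`.
    """
    return (x - lo) / (hi - lo) * (range_hi - range_lo) + range_lo
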