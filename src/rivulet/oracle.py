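"""Brute-force reference semantics for the stream operators.

Each function here applies an operator's *declarative* definition to fully
materialized, time-sorted notification lists — no scheduler, no push
machinery, no shared code with the engine's operator implementations.  The
engine is correct exactly when, for any scripted input, its recorded output
equals the oracle's.  The random-script agreement suite at the bottom is
the executable form of that statement.

Conventions mirrored from the engine: simultaneous events across streams
order by stream creation order (stream 0 first); within a stream, script
order.  A global merged order is therefore (time, stream index, index in
stream).
"""

from __future__ import annotations

import string
from typing import Any, Callable, Optional, Sequence

import numpy as np

from .core import (Kind, Notification, Recorder, VirtualScheduler, hot,
                   record)
from . import combinators as cb
from . import windows as wd

Events = list[Notification]


def _split_terminal(events: Events) -> tuple[Events, Optional[Notification]]:
    nexts = [e for e in events if e.kind is Kind.NEXT]
    terminals = [e for e in events if e.kind is not Kind.NEXT]
    return nexts, (terminals[0] if terminals else None)


def oracle_map(events: Events, fn: Callable) -> Events:
    out = []
    for e in events:
        if e.kind is Kind.NEXT:
            out.append(Notification.next_(e.time, fn(e.payload)))
        else:
            out.append(e)
    return out


def oracle_filter(events: Events, pred: Callable) -> Events:
    return [e for e in events if e.kind is not Kind.NEXT or pred(e.payload)]


def oracle_take(events: Events, n: int) -> Events:
    nexts, terminal = _split_terminal(events)
    if len(nexts) >= n:
        kept = nexts[:n]
        return kept + [Notification.completed(kept[-1].time)]
    return nexts + ([terminal] if terminal else [])


def oracle_timestamp(events: Events) -> Events:
    return [Notification.next_(e.time, cb.TimestampedValue(e.payload, e.time))
            if e.kind is Kind.NEXT else e for e in events]


def _global_order(streams: Sequence[Events]) -> list[tuple[Notification, int]]:
    tagged = [(e, si, ei) for si, events in enumerate(streams)
              for ei, e in enumerate(events)]
    tagged.sort(key=lambda t: (t[0].time, t[1], t[2]))
    return [(e, si) for e, si, _ in tagged]


def oracle_merge(streams: Sequence[Events]) -> Events:
    if not streams:
        return [Notification.completed(0)]
    out: Events = []
    open_count = len(streams)
    for event, _si in _global_order(streams):
        if event.kind is Kind.NEXT:
            out.append(event)
        elif event.kind is Kind.ERROR:
            out.append(event)
            return out
        else:
            open_count -= 1
            if open_count == 0:
                out.append(event)
    return out


def oracle_sample(src: Events, trigger: Events) -> Events:
    out: Events = []
    latest: Optional[Any] = None
    seen = False
    for event, si in _global_order([src, trigger]):
        if si == 0:
            if event.kind is Kind.NEXT:
                latest, seen = event.payload, True
            else:  # src terminal ends the output
                out.append(event)
                return out
        else:
            if event.kind is Kind.NEXT:
                if seen:
                    out.append(Notification.next_(event.time, latest))
            elif event.kind is Kind.ERROR:
                out.append(event)
                return out
            # trigger completion just stops sampling
    return out


def oracle_window_count(events: Events, count: int,
                        skip: int) -> list[list[Any]]:
    nexts, _ = _split_terminal(events)
    payloads = [e.payload for e in nexts]
    return [payloads[start:start + count]
            for start in range(0, len(payloads), skip)]


def oracle_window_time(events: Events, duration: int) -> list[list[Any]]:
    """floor(t/duration) bucketing; trailing empty intervals up to the
    terminal's interval are kept."""
    nexts, terminal = _split_terminal(events)
    end_time = max(0, terminal.time - 1) if terminal else 0
    if nexts:
        end_time = max(end_time, nexts[-1].time)
    n_windows = end_time // duration + 1
    buckets: list[list[Any]] = [[] for _ in range(n_windows)]
    for e in nexts:
        buckets[e.time // duration].append(e.payload)
    return buckets


def oracle_window_trigger(events: Events,
                          boundaries: Events) -> list[list[Any]]:
    nexts, terminal = _split_terminal(events)
    # a boundary at the terminal's tick loses the tie (source is stream 0)
    cut_times = sorted(b.time for b in boundaries if b.kind is Kind.NEXT
                       and (terminal is None or b.time < terminal.time))
    buckets: list[list[Any]] = [[] for _ in range(len(cut_times) + 1)]
    for e in nexts:
        # a source element at a boundary tick precedes the cut (stream 0
        # is created first), so strict inequality assigns it left
        k = sum(1 for t in cut_times if t < e.time)
        buckets[k].append(e.payload)
    return buckets


def oracle_moving_average(values: Sequence[float], k: int) -> np.ndarray:
    return np.convolve(np.asarray(values, dtype=float),
                       np.ones(k) / k, mode="valid")


# ---------------------------------------------------------------------------
# Random-script agreement suite
# ---------------------------------------------------------------------------

_SYMBOLS = string.ascii_lowercase


def random_script(rng: np.random.Generator, max_events: int = 30,
                  max_time: int = 60, terminal: str = "maybe") -> Events:
    """A random well-formed notification script (payloads are small ints)."""
    n = int(rng.integers(0, max_events + 1))
    times = np.sort(rng.integers(0, max_time, n))
    events = [Notification.next_(int(t), int(rng.integers(0, 10)))
              for t in times]
    close = {"always": True, "never": False,
             "maybe": bool(rng.random() < 0.8)}[terminal]
    if close:
        t_end = int(times[-1] if n else 0) + int(rng.integers(0, 5))
        if rng.random() < 0.1:
            events.append(Notification.error(t_end, "scripted error"))
        else:
            events.append(Notification.completed(t_end))
    return events


def run_engine(streams: Sequence[Events],
               pipeline: Callable[..., Any]) -> Events:
    """Replay scripts through the live engine and record the output."""
    scheduler = VirtualScheduler()
    sources = [hot(scheduler, events) for events in streams]
    recorder = Recorder(scheduler)
    pipeline(scheduler, *sources).subscribe(recorder)
    scheduler.run()
    return recorder.log


def _events_equal(a: Events, b: Events) -> bool:
    if len(a) != len(b):
        return False
    for x, y in zip(a, b):
        if (x.time, x.kind) != (y.time, y.kind):
            return False
        if x.kind is Kind.NEXT and x.payload != y.payload:
            return False
    return True


def agreement_suite(seed: int, n_scripts: int = 500,
                    max_events: int = 30) -> dict[str, Any]:
    """Engine-vs-oracle agreement over random scripts, for every combinator.

    Returns per-operator and overall agreement fractions; a correct engine
    scores exactly 1.0 everywhere.
    """
    rng = np.random.default_rng(seed)
    double = lambda v: v * 2
    even = lambda v: v % 2 == 0
    cases: dict[str, tuple[int, Callable, Callable]] = {
        "map": (1, lambda s, a: cb.map_(a, double),
                lambda xs: oracle_map(xs[0], double)),
        "filter": (1, lambda s, a: cb.filter_(a, even),
                   lambda xs: oracle_filter(xs[0], even)),
        "take": (1, lambda s, a: cb.take(a, 3),
                 lambda xs: oracle_take(xs[0], 3)),
        "timestamp": (1, lambda s, a: cb.timestamp(a),
                      lambda xs: oracle_timestamp(xs[0])),
        "merge": (3, lambda s, a, b, c: cb.merge(s, [a, b, c]),
                  lambda xs: oracle_merge(xs)),
        "sample": (2, lambda s, a, b: cb.sample(a, b),
                   lambda xs: oracle_sample(xs[0], xs[1])),
    }
    results: dict[str, Any] = {}
    total = hits = 0
    for name, (arity, pipeline, oracle) in cases.items():
        ok = 0
        for _ in range(n_scripts):
            scripts = [random_script(rng, max_events) for _ in range(arity)]
            if _events_equal(run_engine(scripts, pipeline), oracle(scripts)):
                ok += 1
        results[name] = ok / n_scripts
        hits += ok
        total += n_scripts
    results["overall"] = hits / total
    results["n_scripts"] = total
    return results
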